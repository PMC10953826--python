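"""Segmentation, shape features, duct/cluster classification and viability.

This stage fills, with transparent and testable code, the role that an
Ilastik pixel classifier + CellProfiler pipeline + CellProfiler Analyst
model typically plays in high-content organoid screens: find organoids in
the morphology channel, measure their shapes, call each one duct-like or
cluster-like, and score per-object viability from the green (calcein)
channel.

Design notes. Touching organoids are NOT declumped: segmentation is plain
connected components above an intensity threshold, so two overlapping
organoids count as one object. The default classifier is a fixed,
inspectable rule on the lumen ratio (ducts have a hole), with object area +
solidity as a fallback for ducts whose lumen closed during imaging; a small
trainable decision tree is available for parity with learned classifiers.
Coordinates are 0-based, row-major, origin top-left; thresholds apply as >=.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import remove_small_holes, remove_small_objects
from skimage.segmentation import clear_border
from skimage.filters import threshold_otsu

__all__ = [
    "OrganoidObject",
    "SegmentationParams",
    "RuleClassifier",
    "segment_objects",
    "extract_features",
    "classify_objects",
    "score_viability",
    "objects_to_frame",
    "train_tree_classifier",
    "analyze_well_image",
]

FEATURE_NAMES = ("area", "perimeter", "form_factor", "solidity",
                 "eccentricity", "lumen_ratio")


@dataclass
class OrganoidObject:
    """One segmented organoid and its measurements.

    ``lumen_ratio`` = (filled_area - area) / filled_area: the hole fraction
    of the hole-filled footprint, ~0.25 for a duct whose lumen radius is
    half the outer radius, ~0 for a compact cluster. ``form_factor`` is
    4*pi*A/P^2 (1 for a perfect circle, up to small discretization excess).
    """

    object_id: int
    centroid: tuple[float, float]  # (row, col), 0-based
    area: float = math.nan         # px^2
    perimeter: float = math.nan    # px
    form_factor: float = math.nan
    solidity: float = math.nan
    eccentricity: float = math.nan
    lumen_ratio: float = math.nan
    mean_green: float = math.nan
    predicted_class: str | None = None  # "duct" | "cluster"
    live: bool | None = None

    def features(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def has_features(self) -> bool:
        return not any(math.isnan(v) for v in self.features().values())


@dataclass(frozen=True)
class SegmentationParams:
    smoothing_sigma: float = 1.0       # px
    threshold_method: str = "otsu"     # "otsu" | "fixed"
    fixed_threshold: float | None = None
    min_object_area: int = 60          # px^2
    hole_fill_max: int = 16            # px^2; real lumens are larger
    border_policy: str = "keep"        # "keep" | "drop"

    def __post_init__(self) -> None:
        if self.min_object_area <= 0:
            raise ValueError("min_object_area must be positive")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method "
                             f"{self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required with method 'fixed'")
        if self.border_policy not in ("keep", "drop"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")


def _robust_background(img: np.ndarray) -> tuple[float, float]:
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    return med, 1.4826 * mad


def segment_objects(
    image: np.ndarray,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, list[OrganoidObject]]:
    """Segment the morphology channel into labeled organoids.

    Gaussian smoothing, global threshold (Otsu by default), removal of
    objects below ``min_object_area`` and of holes below ``hole_fill_max``
    (lumens survive), then connected-component labeling. An Otsu threshold
    that does not clear the background distribution (median + 3 robust SD)
    is treated as "nothing in the well" and yields an empty result instead
    of thresholding noise.

    Returns (label image with background 0, objects with only ``object_id``
    and ``centroid``/``area`` filled; run :func:`extract_features` next).
    """
    params = params or SegmentationParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D channel, got shape {img.shape}")

    smooth = (ndimage.gaussian_filter(img, params.smoothing_sigma)
              if params.smoothing_sigma > 0 else img)
    if params.threshold_method == "fixed":
        thr = float(params.fixed_threshold)
    else:
        thr = float(threshold_otsu(smooth))
        med, sd = _robust_background(smooth)
        if thr < med + 3.0 * sd:
            return np.zeros(img.shape, dtype=np.int32), []

    fg = smooth >= thr
    # keep objects with area >= min_object_area (max_size removes <=)
    fg = remove_small_objects(fg, max_size=params.min_object_area - 1)
    if params.hole_fill_max > 0:
        fg = remove_small_holes(fg, max_size=params.hole_fill_max)
    if params.border_policy == "drop":
        fg = clear_border(fg)
    labels = sk_label(fg, connectivity=2).astype(np.int32)

    objects = [
        OrganoidObject(object_id=int(p.label),
                       centroid=(float(p.centroid[0]), float(p.centroid[1])),
                       area=float(p.area))
        for p in regionprops(labels)
    ]
    return labels, objects


def extract_features(
    labels: np.ndarray,
    channels: np.ndarray | Sequence[np.ndarray],
) -> list[OrganoidObject]:
    """Measure shape and intensity features for every labeled object.

    ``channels`` is the (2, H, W) rendered stack or any sequence whose last
    element is the green channel. Never changes the object count.
    """
    channels = np.asarray(channels, dtype=float)
    if channels.ndim == 2:
        channels = channels[None]
    green = channels[-1]
    if green.shape != labels.shape:
        raise ValueError(
            f"label image {labels.shape} and channels {green.shape} disagree")

    objects = []
    for p in regionprops(labels, intensity_image=green):
        area = float(p.area)
        filled = float(p.area_filled)
        # Crofton estimate: nearly unbiased on digital disks, so a circle's
        # form factor stays ~1 instead of drifting down with size
        perim = float(p.perimeter_crofton)
        objects.append(OrganoidObject(
            object_id=int(p.label),
            centroid=(float(p.centroid[0]), float(p.centroid[1])),
            area=area,
            perimeter=perim,
            form_factor=4.0 * math.pi * area / perim**2 if perim > 0 else math.nan,
            solidity=float(p.solidity),
            eccentricity=float(p.eccentricity),
            lumen_ratio=(filled - area) / filled if filled > 0 else 0.0,
            mean_green=float(p.intensity_mean),
        ))
    return objects


@dataclass(frozen=True)
class RuleClassifier:
    """Transparent duct/cluster rule.

    duct  iff  lumen_ratio >= tau_lumen
          or  (area >= tau_area and solidity <= tau_solidity)

    The lumen test does nearly all the work (ducts are annuli); the
    area+solidity fallback catches large ring-like objects whose lumen was
    blurred or filled. Thresholds were fixed once on the packaged synthetic
    training wells.
    """

    tau_lumen: float = 0.08
    tau_area: float = 1200.0
    tau_solidity: float = 0.80

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        duct = (frame["lumen_ratio"] >= self.tau_lumen) | (
            (frame["area"] >= self.tau_area)
            & (frame["solidity"] <= self.tau_solidity))
        return np.where(duct, "duct", "cluster")


def classify_objects(objects: list[OrganoidObject],
                     classifier=None) -> list[OrganoidObject]:
    """Assign ``predicted_class`` ("duct" or "cluster") to every object.

    ``classifier`` must expose ``predict(feature_frame) -> labels``;
    defaults to the packaged :class:`RuleClassifier`. Raises if any object
    is missing features.
    """
    classifier = classifier or RuleClassifier()
    if not objects:
        return objects
    unfilled = [o.object_id for o in objects if not o.has_features()]
    if unfilled:
        raise ValueError(
            f"objects missing features (run extract_features first): "
            f"{unfilled[:5]}")
    frame = pd.DataFrame([o.features() for o in objects])
    predicted = classifier.predict(frame)
    for obj, cls in zip(objects, predicted):
        cls = str(cls)
        if cls not in ("duct", "cluster"):
            raise ValueError(f"classifier produced unknown class {cls!r}")
        obj.predicted_class = cls
    return objects


def train_tree_classifier(objects: list[OrganoidObject],
                          labels: Sequence[str], max_depth: int = 3):
    """Fit a small decision tree on the standard feature set.

    Returns an object with the same ``predict(feature_frame)`` surface as
    :class:`RuleClassifier`, for parity with learned-classifier workflows.
    """
    from sklearn.tree import DecisionTreeClassifier

    frame = pd.DataFrame([o.features() for o in objects])
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=0)
    tree.fit(frame[list(FEATURE_NAMES)], list(labels))

    class _TreeClassifier:
        feature_names = FEATURE_NAMES

        def predict(self, feature_frame: pd.DataFrame) -> np.ndarray:
            return tree.predict(feature_frame[list(FEATURE_NAMES)])

    return _TreeClassifier()


def score_viability(
    objects: list[OrganoidObject],
    labels: np.ndarray,
    green: np.ndarray,
    live_threshold_fraction: float = 0.5,
    green_cut: float | None = None,
) -> list[OrganoidObject]:
    """Call each object live or dead from the green (calcein) channel.

    An object is live when >= ``live_threshold_fraction`` of its pixels
    exceed ``green_cut``. By default the cut is background median + 5 robust
    SD of the whole green channel, which stays meaningful even in wells
    where every object is dead (no Otsu bimodality to lean on).
    """
    if not 0.0 < live_threshold_fraction < 1.0:
        raise ValueError("live_threshold_fraction must be in (0, 1)")
    green = np.asarray(green, dtype=float)
    if green.shape != labels.shape:
        raise ValueError("green channel and label image shapes disagree")
    if green_cut is None:
        med, sd = _robust_background(green)
        # a perfectly flat background (sd 0) must not count as signal
        green_cut = med + 5.0 * sd if sd > 0 else med + 1e-9
    for obj in objects:
        pix = green[labels == obj.object_id]
        frac = float(np.mean(pix >= green_cut)) if pix.size else 0.0
        obj.live = bool(frac >= live_threshold_fraction)
    return objects


def objects_to_frame(objects: list[OrganoidObject]) -> pd.DataFrame:
    """Object table (one row per organoid) for screenstats and CSV export."""
    rows = []
    for o in objects:
        rows.append({
            "object_id": o.object_id,
            "centroid_row": o.centroid[0],
            "centroid_col": o.centroid[1],
            **o.features(),
            "mean_green": o.mean_green,
            "organoid_class": o.predicted_class,
            "live": o.live,
        })
    cols = ["object_id", "centroid_row", "centroid_col", *FEATURE_NAMES,
            "mean_green", "organoid_class", "live"]
    return pd.DataFrame(rows, columns=cols)


def analyze_well_image(
    image: np.ndarray,
    seg_params: SegmentationParams | None = None,
    classifier=None,
    live_threshold_fraction: float = 0.5,
) -> tuple[np.ndarray, list[OrganoidObject]]:
    """Full imaging pass on a (2, H, W) stack: segment, measure, classify,
    score viability. Returns (label image, finished objects)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[0] < 2:
        raise ValueError("expected a (2, H, W) two-channel stack")
    labels, _ = segment_objects(image[0], seg_params)
    objects = extract_features(labels, image)
    classify_objects(objects, classifier)
    score_viability(objects, labels, image[1],
                    live_threshold_fraction=live_threshold_fraction)
    return labels, objects
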