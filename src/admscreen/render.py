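"""Render simulated wells into two-channel 16-bit images.

Channel 0 is the morphology (brightfield-like) channel: every organoid is
drawn, cluster-like objects as compact berry-shaped unions of disks and
duct-like objects as annuli with a visible lumen. Channel 1 is the green
viability channel: only live objects carry signal, emulating calcein AM
staining. Pixel convention: 0-based, row-major, origin at the top-left.
The 15 imaged fields of a real well are collapsed into one pre-stitched
frame per well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk

from .simgen import SimWellTruth

__all__ = ["RenderParams", "render_well_image"]

_N_LOBES = 6  # berry lobes per cluster


@dataclass(frozen=True)
class RenderParams:
    """Optics of the synthetic microscope.

    Intensities are in native 16-bit counts; ``blur_sigma`` (px) stands in
    for the point-spread function and ``noise_sd`` for combined shot/read
    noise, per channel (morphology, green).
    """

    background: tuple[float, float] = (100.0, 50.0)
    foreground: tuple[float, float] = (600.0, 800.0)
    blur_sigma: float = 1.2
    noise_sd: tuple[float, float] = (20.0, 15.0)

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


def _paint_object(mask: np.ndarray, row: float, col: float, radius: float,
                  lumen_radius: float, is_cluster: bool,
                  rng: np.random.Generator) -> None:
    shape = mask.shape
    if is_cluster:
        # compact berry: central disk plus overlapping lobes
        rr, cc = draw_disk((row, col), 0.8 * radius, shape=shape)
        mask[rr, cc] = True
        angles = np.linspace(0, 2 * np.pi, _N_LOBES, endpoint=False)
        angles = angles + rng.uniform(0, 2 * np.pi / _N_LOBES)
        for ang in angles:
            lr = row + 0.55 * radius * np.sin(ang)
            lc = col + 0.55 * radius * np.cos(ang)
            rr, cc = draw_disk((lr, lc), 0.5 * radius, shape=shape)
            mask[rr, cc] = True
    else:
        outer = np.zeros(shape, dtype=bool)
        rr, cc = draw_disk((row, col), radius, shape=shape)
        outer[rr, cc] = True
        if lumen_radius > 0:
            rr, cc = draw_disk((row, col), lumen_radius, shape=shape)
            outer[rr, cc] = False
        mask |= outer


def render_well_image(
    truth: SimWellTruth,
    params: RenderParams | None = None,
    rng_seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Render one well to a (2, H, W) uint16 array.

    Page/channel 0 = morphology, 1 = green viability. Objects whose
    footprint would leave the frame are moved back inside with a warning
    (never silently dropped). Identical seed and parameters give an
    identical image.
    """
    params = params or RenderParams()
    h, w = truth.frame_shape
    if h < 256 or w < 256:
        raise ValueError("frame must be at least 256x256")
    rng = np.random.default_rng(rng_seed)

    morph = np.zeros((h, w), dtype=float)
    green = np.zeros((h, w), dtype=float)
    for obj in truth.objects.itertuples():
        is_cluster = obj.true_class == "cluster"
        extent = 1.15 * obj.radius if is_cluster else obj.radius
        row, col = float(obj.row), float(obj.col)
        if (row - extent < 0 or col - extent < 0
                or row + extent > h - 1 or col + extent > w - 1):
            new_row = float(np.clip(row, extent + 1, h - 2 - extent))
            new_col = float(np.clip(col, extent + 1, w - 2 - extent))
            warnings.warn(
                f"object at ({row:.0f}, {col:.0f}) extends outside the "
                f"frame; repositioned to ({new_row:.0f}, {new_col:.0f})",
                stacklevel=2)
            row, col = new_row, new_col
        mask = np.zeros((h, w), dtype=bool)
        _paint_object(mask, row, col, float(obj.radius),
                      float(obj.lumen_radius), is_cluster, rng)
        morph[mask] = params.foreground[0]
        if obj.true_live:
            green[mask] = params.foreground[1]

    channels = []
    for img, bg, sd in zip((morph, green), params.background, params.noise_sd):
        img = gaussian_filter(img, params.blur_sigma) + bg
        if sd > 0:
            img = img + rng.normal(0.0, sd, size=img.shape)
        channels.append(np.clip(img, 0, 65535))
    return np.stack(channels).astype(np.uint16)
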