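"""Benchmark the imaging stage against generator ground truth.

Only meaningful for simulated wells: detected objects are matched to truth
objects by nearest centroid, and classification / viability calls are scored
against the truth table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .imaging import OrganoidObject
from .simgen import SimWellTruth

__all__ = ["RoundTripMetrics", "match_objects_to_truth", "roundtrip_metrics"]


@dataclass(frozen=True)
class RoundTripMetrics:
    n_truth: int
    n_detected: int
    n_matched: int
    count_error: float       # |detected - truth| / truth
    class_accuracy: float    # duct/cluster agreement on matched objects
    live_accuracy: float     # live/dead agreement on matched objects


def match_objects_to_truth(
    truth: SimWellTruth,
    objects: list[OrganoidObject],
    max_dist: float = 25.0,
) -> pd.DataFrame:
    """Greedy one-to-one centroid matching of detections to truth objects.

    Returns one row per matched pair with true/predicted class and
    viability. Detections farther than ``max_dist`` px from any unclaimed
    truth object stay unmatched.
    """
    if truth.n_objects == 0 or not objects:
        return pd.DataFrame(columns=["true_class", "predicted_class",
                                     "true_live", "live"])
    centers = truth.objects[["row", "col"]].to_numpy(dtype=float)
    tree = cKDTree(centers)
    detections = sorted(objects, key=lambda o: o.object_id)
    coords = np.array([o.centroid for o in detections])
    dists, idx = tree.query(coords)
    order = np.argsort(dists)
    claimed: set[int] = set()
    rows = []
    for k in order:
        if dists[k] > max_dist or int(idx[k]) in claimed:
            continue
        claimed.add(int(idx[k]))
        t = truth.objects.iloc[int(idx[k])]
        o = detections[k]
        rows.append({
            "true_class": t["true_class"],
            "predicted_class": o.predicted_class,
            "true_live": bool(t["true_live"]),
            "live": o.live,
        })
    return pd.DataFrame(rows)


def roundtrip_metrics(
    pairs: list[tuple[SimWellTruth, list[OrganoidObject]]],
    max_dist: float = 25.0,
) -> RoundTripMetrics:
    """Aggregate render->segment->classify recovery over several wells."""
    n_truth = sum(t.n_objects for t, _ in pairs)
    n_detected = sum(len(o) for _, o in pairs)
    matched = pd.concat(
        [match_objects_to_truth(t, o, max_dist) for t, o in pairs],
        ignore_index=True)
    if n_truth == 0:
        raise ValueError("no truth objects to evaluate against")
    class_ok = (matched["true_class"] == matched["predicted_class"]).mean() \
        if len(matched) else float("nan")
    live_ok = (matched["true_live"] == matched["live"]).mean() \
        if len(matched) else float("nan")
    return RoundTripMetrics(
        n_truth=n_truth, n_detected=n_detected, n_matched=len(matched),
        count_error=abs(n_detected - n_truth) / n_truth,
        class_accuracy=float(class_ok), live_accuracy=float(live_ok))
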