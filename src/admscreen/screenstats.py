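"""Plate statistics and hit selection for the duct/cluster morphology screen.

Readout: per well, the percentage of live duct-like and live cluster-like
organoids among all live (calcein-positive) objects; viability is the live
fraction of all objects. A compound is a hit when it passes three gates
against the plate's vehicle wells:

  i)   higher mean % live clusters, two-tailed Welch p <= alpha;
  ii)  higher mean % total clusters (live + dead, of all objects), same test;
  iii) mean within-well viability >= viability_floor (<= 50% cytotoxicity).

p-values are raw (no multiplicity correction across the library), and
significance is direction-gated: a low p only counts when the treated mean
exceeds the vehicle mean. Assay quality is summarized by the Z'-factor
computed from vehicle and strong-positive control wells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simgen import (
    VEHICLE,
    CompoundRecord,
    NoiseParams,
    WellSpec,
    generate_library_fixture,
    positive_control_record,
    simulate_well_objects,
    truth_to_objects,
    well_seed,
)

__all__ = [
    "WellSummary",
    "AssayQC",
    "HitRecord",
    "ScreenResult",
    "summarize_well",
    "welch_test",
    "z_prime",
    "apply_selection_criteria",
    "run_screen",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WellSummary:
    """Per-well readout.

    Percentages of ducts/clusters are over live objects only and sum to 100
    for any well with at least one live object; ``pct_total_clusters`` (over
    all objects, live + dead) feeds selection criterion ii. A well with no
    live objects is flagged ``valid=False`` and excluded from group means.
    """

    spec: WellSpec | None
    n_objects: int
    n_live: int
    pct_live_ducts: float
    pct_live_clusters: float
    pct_total_clusters: float
    viability_frac: float
    valid: bool = True


@dataclass(frozen=True)
class AssayQC:
    """Z'-factor and the control summary statistics behind it (% readout)."""

    z_prime: float
    mu_pos: float
    sd_pos: float
    mu_neg: float
    sd_neg: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class HitRecord:
    compound_id: str
    mode: str
    mean_pct_live_clusters: float
    vehicle_mean_pct_live_clusters: float
    p_live_clusters: float      # criterion i
    p_total_clusters: float     # criterion ii
    viability_frac: float       # mean within-well live fraction
    viability_vs_vehicle: float  # diagnostic: mean viability / vehicle mean
    pass_i: bool
    pass_ii: bool
    pass_iii: bool
    is_hit: bool
    n_wells: int


@dataclass
class ScreenResult:
    mode: str
    well_summaries: list[WellSummary]
    hits: list[HitRecord]
    qc: AssayQC

    def hit_ids(self) -> set[str]:
        return {h.compound_id for h in self.hits if h.is_hit}


# ---------------------------------------------------------------------------
# Well summaries
# ---------------------------------------------------------------------------

def summarize_well(objects: pd.DataFrame,
                   spec: WellSpec | None = None) -> WellSummary:
    """Collapse a classified object table into the per-well readout.

    ``objects`` needs columns ``organoid_class`` ({"duct", "cluster"}) and
    ``live`` (bool). A well with no live objects yields a flagged summary
    (percentages NaN) rather than an error.
    """
    for col in ("organoid_class", "live"):
        if col not in objects.columns:
            raise ValueError(f"object table is missing column {col!r}")
    n = len(objects)
    live = objects["live"].astype(bool)
    n_live = int(live.sum())
    is_cluster = objects["organoid_class"] == "cluster"
    pct_total_clusters = 100.0 * float(is_cluster.mean()) if n else float("nan")
    viability = n_live / n if n else float("nan")
    if n_live == 0:
        logger.warning("well %s has no live objects; summary flagged",
                       spec if spec is not None else "<unspecified>")
        return WellSummary(spec, n, 0, float("nan"), float("nan"),
                           pct_total_clusters, viability, valid=False)
    pct_clusters = 100.0 * float((is_cluster & live).sum()) / n_live
    return WellSummary(spec, n, n_live, 100.0 - pct_clusters, pct_clusters,
                       pct_total_clusters, viability, valid=True)


# ---------------------------------------------------------------------------
# Tests and QC
# ---------------------------------------------------------------------------

def welch_test(sample_a: Sequence[float],
               sample_b: Sequence[float]) -> tuple[float, float, float]:
    """Two-tailed Welch (unequal-variance) t-test.

    Returns (t, Welch-Satterthwaite df, two-tailed p). Both samples need
    n >= 2. If both variances are zero: p = 1 when the means agree (no
    evidence of a difference, by convention), p = 0 with t = +-inf otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_test requires n >= 2 in each sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        t = math.inf if a.mean() > b.mean() else -math.inf
        return t, float(a.size + b.size - 2), 0.0
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(df), float(res.pvalue)


def z_prime(pos: Sequence[float], neg: Sequence[float]) -> AssayQC:
    """Z'-factor of a control pair: 1 - 3(sd_pos + sd_neg)/|mu_pos - mu_neg|.

    Z' <= 1 always; > 0.5 is the conventional screen-ready bar. Raises when
    the control means coincide (separation undefined).
    """
    p = np.asarray(pos, dtype=float)
    n = np.asarray(neg, dtype=float)
    if p.size < 2 or n.size < 2:
        raise ValueError("z_prime requires n >= 2 in each control group")
    mu_p, mu_n = float(p.mean()), float(n.mean())
    if mu_p == mu_n:
        raise ValueError("control means are equal; Z' undefined")
    sd_p, sd_n = float(p.std(ddof=1)), float(n.std(ddof=1))
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return AssayQC(z_prime=z, mu_pos=mu_p, sd_pos=sd_p, mu_neg=mu_n,
                   sd_neg=sd_n, n_pos=int(p.size), n_neg=int(n.size))


# ---------------------------------------------------------------------------
# Hit selection
# ---------------------------------------------------------------------------

def _valid(summaries: Iterable[WellSummary]) -> list[WellSummary]:
    kept = []
    for s in summaries:
        if s.valid:
            kept.append(s)
        else:
            logger.debug("excluding flagged well %s", s.spec)
    return kept


def apply_selection_criteria(
    compound_summaries: Mapping[str, Sequence[WellSummary]],
    vehicle_summaries: Sequence[WellSummary],
    mode: str,
    alpha: float = 0.05,
    viability_floor: float = 0.5,
) -> list[HitRecord]:
    """Apply the three-gate hit selection against vehicle wells.

    Both morphology criteria use the two-tailed Welch test with direction
    gating (significant only when the treated mean exceeds the vehicle
    mean); p-values are reported raw. Criterion iii is within-well:
    mean live fraction >= ``viability_floor``. Flagged (no-live-object)
    wells are excluded from every mean.
    """
    veh = _valid(vehicle_summaries)
    if len(veh) < 2:
        raise ValueError("need at least 2 valid vehicle wells")
    veh_live = [s.pct_live_clusters for s in veh]
    veh_total = [s.pct_total_clusters for s in veh]
    veh_viab = float(np.mean([s.viability_frac for s in veh]))

    records = []
    for compound_id in sorted(compound_summaries):
        wells = _valid(compound_summaries[compound_id])
        if len(wells) < 2:
            logger.warning("compound %s has < 2 valid wells; skipped",
                           compound_id)
            continue
        live = [s.pct_live_clusters for s in wells]
        total = [s.pct_total_clusters for s in wells]
        viab = float(np.mean([s.viability_frac for s in wells]))

        _, _, p_i = welch_test(live, veh_live)
        _, _, p_ii = welch_test(total, veh_total)
        mean_live = float(np.mean(live))
        pass_i = bool(p_i <= alpha and mean_live > np.mean(veh_live))
        pass_ii = bool(p_ii <= alpha and np.mean(total) > np.mean(veh_total))
        pass_iii = bool(viab >= viability_floor)
        rec = HitRecord(
            compound_id=compound_id, mode=mode,
            mean_pct_live_clusters=mean_live,
            vehicle_mean_pct_live_clusters=float(np.mean(veh_live)),
            p_live_clusters=p_i, p_total_clusters=p_ii,
            viability_frac=viab,
            viability_vs_vehicle=viab / veh_viab if veh_viab else float("nan"),
            pass_i=pass_i, pass_ii=pass_ii, pass_iii=pass_iii,
            is_hit=pass_i and pass_ii and pass_iii, n_wells=len(wells))
        logger.debug("criteria %s: i=%s ii=%s iii=%s", compound_id,
                     pass_i, pass_ii, pass_iii)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Full simulated screen
# ---------------------------------------------------------------------------

_COMPOUNDS_PER_PLATE = 72
_VEHICLE_WELLS_PER_PLATE = 4
_CONTROL_WELLS_PER_PLATE = 4
_VEHICLE_KEY = 100000   # compound-slot keys reserved for control streams
_CONTROL_KEY = 200000
_PLATE_COLS = 24        # 384-well layout


def run_screen(
    library: Sequence[CompoundRecord] | None = None,
    mode: str = "inhibition",
    replicates: int = 4,
    seed: int = 0,
    noise: NoiseParams | None = None,
    screen_dose: float = 1.0,
    control_dose: float = 10.0,
    alpha: float = 0.05,
    viability_floor: float = 0.5,
) -> ScreenResult:
    """Simulate and analyze a full library screen at the object level.

    Wells are laid out on 384-well plates (72 compounds x ``replicates``
    wells per plate, plus 4 vehicle and 4 TSA-like positive-control wells on
    every plate). Compounds are tested against their own plate's vehicle
    wells; the Z'-factor pools control wells across plates. Per-well random
    streams are keyed by (seed, mode, compound slot, replicate), so the run
    is reproducible and insensitive to well ordering.
    """
    library = list(library) if library is not None else generate_library_fixture()
    noise = noise or NoiseParams()
    control = positive_control_record()

    well_summaries: list[WellSummary] = []
    compound_summaries: dict[str, list[WellSummary]] = {}
    vehicle_by_plate: dict[str, list[WellSummary]] = {}
    pos_readout: list[float] = []
    neg_readout: list[float] = []

    def simulate(spec: WellSpec, record: CompoundRecord | None,
                 key: int) -> WellSummary:
        truth = simulate_well_objects(
            spec, record, noise=noise,
            rng_seed=well_seed(seed, mode, key, spec.replicate_index))
        summary = summarize_well(truth_to_objects(truth), spec=spec)
        well_summaries.append(summary)
        return summary

    n_plates = math.ceil(len(library) / _COMPOUNDS_PER_PLATE)
    for plate_idx in range(n_plates):
        plate_id = f"P{plate_idx + 1}"
        plate_lib = library[plate_idx * _COMPOUNDS_PER_PLATE:
                            (plate_idx + 1) * _COMPOUNDS_PER_PLATE]
        well_no = 0

        def next_rc():
            nonlocal well_no
            rc = divmod(well_no, _PLATE_COLS)
            well_no += 1
            return rc

        for rep in range(_VEHICLE_WELLS_PER_PLATE):
            r, c = next_rc()
            spec = WellSpec(plate_id, r, c, VEHICLE, 0.0, mode, rep)
            s = simulate(spec, None, _VEHICLE_KEY + plate_idx)
            vehicle_by_plate.setdefault(plate_id, []).append(s)
            if s.valid:
                neg_readout.append(s.pct_live_clusters)
        for rep in range(_CONTROL_WELLS_PER_PLATE):
            r, c = next_rc()
            spec = WellSpec(plate_id, r, c, control.compound_id,
                            control_dose, mode, rep)
            s = simulate(spec, control, _CONTROL_KEY + plate_idx)
            if s.valid:
                pos_readout.append(s.pct_live_clusters)
        for j, record in enumerate(plate_lib):
            key = plate_idx * _COMPOUNDS_PER_PLATE + j
            for rep in range(replicates):
                r, c = next_rc()
                spec = WellSpec(plate_id, r, c, record.compound_id,
                                screen_dose, mode, rep)
                s = simulate(spec, record, key)
                compound_summaries.setdefault(record.compound_id, []).append(s)

    qc = z_prime(pos_readout, neg_readout)

    hits: list[HitRecord] = []
    for plate_idx in range(n_plates):
        plate_id = f"P{plate_idx + 1}"
        plate_lib = library[plate_idx * _COMPOUNDS_PER_PLATE:
                            (plate_idx + 1) * _COMPOUNDS_PER_PLATE]
        plate_compounds = {r.compound_id: compound_summaries[r.compound_id]
                           for r in plate_lib}
        hits.extend(apply_selection_criteria(
            plate_compounds, vehicle_by_plate[plate_id], mode=mode,
            alpha=alpha, viability_floor=viability_floor))
    hits.sort(key=lambda h: h.compound_id)
    return ScreenResult(mode=mode, well_summaries=well_summaries,
                        hits=hits, qc=qc)
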