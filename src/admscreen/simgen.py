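"""Synthetic inputs for the organoid ADM screen.

Everything downstream of the microscope is testable without real data: this
module fabricates the 144-compound epigenetic library with ground-truth effect
parameters, object-level well contents (duct-like vs cluster-like organoids
with per-object viability), qPCR cycle-threshold tables and differential
expression tables. Rendering of the object tables into two-channel images
lives in :mod:`admscreen.render`.

The generator's defaults encode the study conditions: ~50 organoids seeded per
well, vehicle baselines of ~10% clusters in inhibition mode (naive acini that
mostly transdifferentiate into ducts) and ~5% in reversal mode (ADM already
complete), a well-to-well replicate SD of ~3 percentage points on the
%-clusters readout, and designed compound effects sized for Cohen's d ≥ 4 so
that true effects are detected with power ≈ 1 at n = 4 replicate wells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VEHICLE",
    "REFERENCE_GENE",
    "TARGET_CLASSES",
    "BASELINE_CLUSTER_PCT",
    "CompoundRecord",
    "WellSpec",
    "NoiseParams",
    "SimWellTruth",
    "generate_library_fixture",
    "positive_control_record",
    "simulate_well_objects",
    "truth_to_objects",
    "simulate_qpcr",
    "simulate_de_table",
    "well_seed",
]

VEHICLE = "VEHICLE"
REFERENCE_GENE = "18S"

TARGET_CLASSES = (
    "BET", "DMT", "HDM", "HMT", "HAT", "HDAC_Zn", "HDAC_NAD", "PARP", "other",
)

#: Expected % cluster-like organoids in vehicle wells, per assay mode.
#: Inhibition assays start from naive acini that mostly form ducts by 72 h;
#: reversal assays start from organoids that have already completed ADM.
BASELINE_CLUSTER_PCT = {"inhibition": 10.0, "reversal": 5.0}


@dataclass(frozen=True)
class CompoundRecord:
    """One library entry: annotation plus ground-truth simulation effects.

    Effects are parameterized directly on the readout scale: percentage
    points added to the expected % (live) clusters in each assay mode.
    ``cytotox_frac`` is the probability that any given organoid in a treated
    well is dead at 72 h; ``duct_size_factor`` scales rendered duct radii
    (cosmetic classes of compounds enlarge or shrink ducts without changing
    the duct:cluster ratio).
    """

    compound_id: str
    name: str
    target_class: str
    cluster_shift_inh: float = 0.0
    cluster_shift_rev: float = 0.0
    cytotox_frac: float = 0.0
    duct_size_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.target_class not in TARGET_CLASSES:
            raise ValueError(f"unknown target_class {self.target_class!r}")
        if not 0.0 <= self.cytotox_frac <= 1.0:
            raise ValueError("cytotox_frac must be in [0, 1]")
        if self.duct_size_factor <= 0:
            raise ValueError("duct_size_factor must be positive")
        for mode, shift in (("inhibition", self.cluster_shift_inh),
                            ("reversal", self.cluster_shift_rev)):
            expected = BASELINE_CLUSTER_PCT[mode] + shift
            if not 0.0 <= expected <= 100.0:
                raise ValueError(
                    f"{self.compound_id}: expected % clusters {expected} in "
                    f"{mode} mode falls outside [0, 100]")

    def shift_for(self, mode: str) -> float:
        if mode == "inhibition":
            return self.cluster_shift_inh
        if mode == "reversal":
            return self.cluster_shift_rev
        raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class WellSpec:
    """Location and treatment of one well."""

    plate_id: str
    row: int
    col: int
    compound_id: str
    dose: float  # µM; 0 for vehicle
    mode: str
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if self.mode not in BASELINE_CLUSTER_PCT:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.compound_id == VEHICLE and self.dose != 0:
            raise ValueError("vehicle wells must have dose 0")
        if self.compound_id != VEHICLE and self.dose <= 0:
            raise ValueError("compound wells must have dose > 0")


@dataclass(frozen=True)
class NoiseParams:
    """Replicate-noise model for object-level well simulation.

    ``cluster_pct_sd`` is the well-to-well SD (percentage points) added to
    the expected % clusters before objects are drawn; near the 0/100
    boundaries the SD is shrunk (to distance/3) so saturated expectations
    stay unbiased instead of being clipped.
    """

    n_objects_mean: float = 50.0
    cluster_pct_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_objects_mean < 0 or self.cluster_pct_sd < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class SimWellTruth:
    """Ground truth for one simulated well.

    ``objects`` has one row per organoid with columns ``true_class``
    ({"duct", "cluster"}), ``true_live`` (0/1), ``row``/``col`` (pixel
    centers, 0-based, origin top-left), ``radius`` and ``lumen_radius``
    (pixels; lumen_radius 0 for clusters).
    """

    spec: WellSpec
    frame_shape: tuple[int, int]
    objects: pd.DataFrame

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def pct_true_clusters(self) -> float:
        """% cluster-like among all objects (NaN for an empty well)."""
        if self.n_objects == 0:
            return float("nan")
        return 100.0 * float((self.objects["true_class"] == "cluster").mean())

    def dead_fraction(self) -> float:
        if self.n_objects == 0:
            return float("nan")
        return 1.0 - float(self.objects["true_live"].mean())


# ---------------------------------------------------------------------------
# Library fixture
# ---------------------------------------------------------------------------

# Designed ground-truth effects. The inhibition screen is designed so that
# six compounds raise % live clusters, four of which are strongly cytotoxic
# and therefore fail the viability gate, leaving apicidin and chaetocin as
# the two hits. The reversal screen adds tubastatin A as a cytotoxic
# near-miss that passes the morphology criteria but fails viability.
# Shifts are sized so every designed effect carries Cohen's d >= 4 on the
# per-well % live clusters readout under the full noise model. For the
# cytotoxic decoys only ~40% of the ~50 objects are live, which roughly
# doubles the counting noise of the readout (SD ~11 points), so their shifts
# are +50 rather than the +25 minimum that suffices at full viability.
_DESIGNED = {
    #  name                     class       shift_inh  shift_rev  cytotox  dsf
    "chaetocin":              ("HMT",        60.0, 60.0, 0.05, 1.0),
    "apicidin":               ("HDAC_Zn",    55.0, 50.0, 0.05, 1.0),
    "IBET151":                ("BET",        50.0,  0.0, 0.60, 1.4),
    "OTX015":                 ("BET",        50.0,  0.0, 0.60, 1.0),
    "3-deazaneplanocin A":    ("HMT",        50.0,  0.0, 0.60, 1.0),
    "B32B3":                  ("other",      50.0,  0.0, 0.60, 1.0),
    "tubastatin A":           ("HDAC_Zn",     0.0, 50.0, 0.60, 1.0),
}

# Null compounds with non-default annotation flavor (no readout effect).
_FLAVOR = {
    "IBET762":     ("BET",     0.20, 1.4),
    "(+)-JQ1":     ("BET",     0.10, 1.4),
    "PFI-1":       ("BET",     0.05, 1.4),
    "LAQ824":      ("HDAC_Zn", 0.10, 0.7),
    "vorinostat":  ("HDAC_Zn", 0.15, 1.0),
    "lestaurtinib": ("other",  0.05, 0.7),
}

# Class composition of the 144-compound library: 43 HDAC inhibitors split
# 34 Zn2+-dependent / 9 NAD+-dependent, remainder spread over the other
# epigenetic target classes.
_CLASS_COUNTS = {
    "BET": 12, "DMT": 12, "HDM": 20, "HMT": 16, "HAT": 12,
    "HDAC_Zn": 34, "HDAC_NAD": 9, "PARP": 12, "other": 17,
}


def generate_library_fixture() -> list[CompoundRecord]:
    """Build the deterministic 144-compound library fixture.

    Returns the same ordered list on every call: named compounds carry the
    designed ground-truth effects above; all remaining slots are zero-effect
    fillers with low cytotoxicity (0.05).
    """
    assert sum(_CLASS_COUNTS.values()) == 144
    per_class_names: dict[str, list[tuple[str, float, float, float, float]]] = {
        cls: [] for cls in TARGET_CLASSES}
    for name, (cls, sh_i, sh_r, tox, dsf) in _DESIGNED.items():
        per_class_names[cls].append((name, sh_i, sh_r, tox, dsf))
    for name, (cls, tox, dsf) in _FLAVOR.items():
        per_class_names[cls].append((name, 0.0, 0.0, tox, dsf))

    records: list[CompoundRecord] = []
    for cls in TARGET_CLASSES:
        entries = list(per_class_names[cls])
        n_fill = _CLASS_COUNTS[cls] - len(entries)
        if n_fill < 0:
            raise RuntimeError(f"class {cls} over-subscribed")
        entries.extend(
            (f"{cls} inhibitor {i + 1:02d}", 0.0, 0.0, 0.05, 1.0)
            for i in range(n_fill))
        records.extend(
            CompoundRecord(
                compound_id="",  # placeholder, replaced below
                name=name, target_class=cls, cluster_shift_inh=sh_i,
                cluster_shift_rev=sh_r, cytotox_frac=tox,
                duct_size_factor=dsf)
            for name, sh_i, sh_r, tox, dsf in entries)

    out = [
        CompoundRecord(
            compound_id=f"ESL-{i + 1:03d}", name=r.name,
            target_class=r.target_class,
            cluster_shift_inh=r.cluster_shift_inh,
            cluster_shift_rev=r.cluster_shift_rev,
            cytotox_frac=r.cytotox_frac,
            duct_size_factor=r.duct_size_factor)
        for i, r in enumerate(records)
    ]
    assert len(out) == 144
    return out


def positive_control_record() -> CompoundRecord:
    """TSA-like positive control: near-complete inhibition/reversal.

    Not part of the 144-compound library; dosed at 10 µM it drives >80% of
    organoids to the cluster morphology in both assay modes.
    """
    return CompoundRecord(
        compound_id="TSA", name="trichostatin A", target_class="HDAC_Zn",
        cluster_shift_inh=80.0, cluster_shift_rev=85.0,
        cytotox_frac=0.05, duct_size_factor=1.0)


# ---------------------------------------------------------------------------
# Object-level well simulation
# ---------------------------------------------------------------------------

# Rendered geometry (pixels, at the default frame size).
_CLUSTER_RADIUS_MEAN, _CLUSTER_RADIUS_SD = 10.0, 1.5
_DUCT_RADIUS_MEAN, _DUCT_RADIUS_SD = 16.0, 2.0
_MIN_RADIUS = 6.0
_LUMEN_FRACTION = 0.5  # lumen_radius / radius for ducts
_PLACEMENT_MARGIN = 8  # px of clearance added to the placement grid cell


def well_seed(base_seed: int, mode: str, compound_key: int,
              replicate_index: int) -> np.random.SeedSequence:
    """Per-well seed substream.

    Counter-based: each well's stream is keyed by (base seed, mode, compound
    slot, replicate), so adding wells or reordering the loop never perturbs
    the draws of existing wells.
    """
    mode_code = {"inhibition": 0, "reversal": 1}[mode]
    return np.random.SeedSequence(
        entropy=int(base_seed) % (2**31),
        spawn_key=(mode_code, int(compound_key), int(replicate_index)))


def _place_objects(rng: np.random.Generator, extents: np.ndarray,
                   frame_shape: tuple[int, int]) -> np.ndarray:
    """Non-overlapping centers on a jittered grid. Returns (n, 2) row/col."""
    n = len(extents)
    if n == 0:
        return np.empty((0, 2))
    cell = int(2 * float(np.max(extents))) + _PLACEMENT_MARGIN
    ny, nx = frame_shape[0] // cell, frame_shape[1] // cell
    if ny * nx < n:
        raise ValueError(
            f"cannot place {n} objects of extent {np.max(extents):.0f} px in a "
            f"{frame_shape} frame without overlap")
    cells = rng.choice(ny * nx, size=n, replace=False)
    rows = (cells // nx) * cell + cell / 2.0
    cols = (cells % nx) * cell + cell / 2.0
    slack = np.maximum(cell / 2.0 - extents - 2.0, 0.0)
    rows = rows + rng.uniform(-1, 1, n) * slack
    cols = cols + rng.uniform(-1, 1, n) * slack
    return np.column_stack([rows, cols])


def simulate_well_objects(
    spec: WellSpec,
    record: CompoundRecord | None,
    noise: NoiseParams | None = None,
    rng_seed: int | np.random.SeedSequence = 0,
    frame_shape: tuple[int, int] = (768, 768),
) -> SimWellTruth:
    """Draw the ground-truth object table for one well.

    The expected class mix is the mode baseline plus the compound's designed
    shift; a per-well Gaussian jitter (``noise.cluster_pct_sd`` points,
    boundary-shrunk) models replicate variability, and each object is then an
    independent class/viability Bernoulli draw. Identical seed and parameters
    give identical output.

    ``record`` may be None for vehicle wells.
    """
    noise = noise or NoiseParams()
    rng = np.random.default_rng(rng_seed)

    if spec.compound_id == VEHICLE or record is None:
        if spec.compound_id != VEHICLE:
            raise ValueError(f"no compound record for {spec.compound_id}")
        shift, cytotox, dsf = 0.0, 0.0, 1.0
    else:
        if record.compound_id != spec.compound_id:
            raise ValueError(
                f"record {record.compound_id} does not match well "
                f"{spec.compound_id}")
        shift = record.shift_for(spec.mode)
        cytotox = record.cytotox_frac
        dsf = record.duct_size_factor

    expected = BASELINE_CLUSTER_PCT[spec.mode] + shift
    if not 0.0 <= expected <= 100.0:
        raise ValueError(
            f"expected % clusters {expected} outside [0, 100] for "
            f"{spec.compound_id}")

    sd_eff = min(noise.cluster_pct_sd, min(expected, 100.0 - expected) / 3.0)
    p_well = float(np.clip(expected + rng.normal(0.0, sd_eff), 0.0, 100.0)) / 100.0

    n = int(rng.poisson(noise.n_objects_mean)) if noise.n_objects_mean > 0 else 0
    is_cluster = rng.random(n) < p_well
    live = (rng.random(n) >= cytotox).astype(int)

    radius = np.where(
        is_cluster,
        rng.normal(_CLUSTER_RADIUS_MEAN, _CLUSTER_RADIUS_SD, n),
        rng.normal(_DUCT_RADIUS_MEAN, _DUCT_RADIUS_SD, n) * dsf)
    radius = np.maximum(radius, _MIN_RADIUS)
    lumen = np.where(is_cluster, 0.0, radius * _LUMEN_FRACTION)

    # clusters are rendered as berry-like disk unions that extend ~10% past r
    extent = np.where(is_cluster, 1.15 * radius, radius)
    centers = _place_objects(rng, extent, frame_shape)

    objects = pd.DataFrame({
        "true_class": np.where(is_cluster, "cluster", "duct"),
        "true_live": live,
        "row": centers[:, 0],
        "col": centers[:, 1],
        "radius": radius,
        "lumen_radius": lumen,
    })
    return SimWellTruth(spec=spec, frame_shape=tuple(frame_shape),
                        objects=objects)


def truth_to_objects(truth: SimWellTruth) -> pd.DataFrame:
    """Object-level fast path: the truth table as a classified object table.

    Produces the same columns the imaging stage would (``organoid_class``,
    ``live``) so :mod:`admscreen.screenstats` can consume simulated wells
    without rendering and re-segmenting images.
    """
    return pd.DataFrame({
        "organoid_class": truth.objects["true_class"].to_numpy(copy=True),
        "live": truth.objects["true_live"].to_numpy(dtype=bool),
    })


# ---------------------------------------------------------------------------
# qPCR CT tables
# ---------------------------------------------------------------------------

#: Baseline CT values (cycles) used by the generator; the abundant 18S rRNA
#: reference amplifies ~14 cycles earlier than a typical mRNA target.
DEFAULT_BASELINE_CT = {REFERENCE_GENE: 10.0}
_DEFAULT_TARGET_CT = 24.0


def _effect_at(effects: Mapping, gene: str, dose: float) -> float:
    val = effects[gene]
    if isinstance(val, Mapping):
        return float(val[dose])
    return float(val)


def simulate_qpcr(
    effects: Mapping[str, float] | Mapping[str, Mapping[float, float]],
    doses: Sequence[float],
    replicates: int = 2,
    rng_seed: int | np.random.SeedSequence = 0,
    compound_id: str = "CMPD",
    ct_noise_sd: float = 0.15,
    sample_offset_sd: float = 0.5,
    baseline_ct: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Generate a long-format CT table under the 2^-ddCT model, inverted.

    For each gene, CT = baseline_ct(gene) - log2_effect(gene, dose)
    + per-sample offset + N(0, ct_noise_sd). The per-sample offset (loading /
    RT-efficiency variation) is identical across genes of a sample, so it
    cancels in dCT. ``effects`` maps gene -> log2 fold change (scalar, or
    {dose: value}); it must include the 18S reference gene (effect 0).
    Vehicle samples (treatment "VEHICLE") are always generated.

    Returns a DataFrame with columns sample_id, treatment, gene, ct.
    """
    if REFERENCE_GENE not in effects:
        raise ValueError(
            f"effect map must include the reference gene {REFERENCE_GENE!r}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(rng_seed)
    base = dict(DEFAULT_BASELINE_CT)
    if baseline_ct:
        base.update(baseline_ct)
    genes = list(effects)

    rows = []
    conditions: list[tuple[str, float | None]] = [(VEHICLE, None)]
    conditions += [(f"{compound_id}:{dose}", dose) for dose in doses]
    for treatment, dose in conditions:
        for rep in range(replicates):
            sample_id = f"{treatment}#r{rep + 1}"
            offset = rng.normal(0.0, sample_offset_sd) if sample_offset_sd else 0.0
            for gene in genes:
                eff = 0.0 if dose is None else _effect_at(effects, gene, dose)
                ct = (base.get(gene, _DEFAULT_TARGET_CT) - eff + offset
                      + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0))
                rows.append((sample_id, treatment, gene, ct))
    return pd.DataFrame(rows, columns=["sample_id", "treatment", "gene", "ct"])


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

def simulate_de_table(
    panel,
    reversal_strength: float,
    n_background_genes: int = 1000,
    rng_seed: int | np.random.SeedSequence = 0,
    effect_sd: float = 0.3,
    log2fc_se: float = 0.25,
) -> pd.DataFrame:
    """Emulate the bulk-expression signature of ADM reversal.

    Acinar panel genes are drawn with mean +``reversal_strength`` log2 fold
    change, ductal/PDAC panel genes with mean -``reversal_strength`` and
    background genes around 0 (all with SD ``effect_sd``). FDR values are
    derived from the effect sizes themselves: a z-statistic log2fc/log2fc_se
    gives a two-sided p, Benjamini-Hochberg-adjusted across the table, so
    larger effects always carry smaller FDR on average.

    Returns a DataFrame with columns gene, log2fc, fdr.
    """
    if reversal_strength < 0:
        raise ValueError("reversal_strength must be >= 0")
    rng = np.random.default_rng(rng_seed)
    genes, means = [], []
    for g in panel.acinar:
        genes.append(g); means.append(+reversal_strength)
    for g in panel.ductal_pdac:
        genes.append(g); means.append(-reversal_strength)
    for i in range(n_background_genes):
        genes.append(f"BG{i + 1:04d}"); means.append(0.0)
    if not genes:
        return pd.DataFrame(columns=["gene", "log2fc", "fdr"])

    log2fc = rng.normal(np.asarray(means, dtype=float), effect_sd)
    z = np.abs(log2fc) / log2fc_se
    # two-sided normal p-value, floored to avoid exact zeros
    from scipy.stats import norm
    p = np.maximum(2.0 * norm.sf(z), 1e-300)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"gene": genes, "log2fc": log2fc, "fdr": fdr})
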