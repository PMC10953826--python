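"""Molecular endpoints: 2^-ddCT fold changes, the ADM Reversal Index, and
gene-panel annotation of differential-expression tables.

The ADM Reversal Index (ADMRI) quantifies how strongly a treatment pushes
duct-like (metaplastic) pancreatic cultures back toward the acinar state:

    ADMRI = mean fold change of acinar genes (Amy2a, Cela1, Cpa2)
            / mean fold change of ductal genes (Krt19, Krt7, Sox9)

with fold changes computed by relative qPCR quantification (2^-ddCT against a
vehicle control, normalized to 18S rRNA). Higher values mean stronger
reversal; the index is driven by both acinar re-expression and ductal
suppression, so a large value can also arise from a large change on one side
only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simgen import REFERENCE_GENE, VEHICLE

__all__ = [
    "QPCR_ACINAR_GENES",
    "QPCR_DUCTAL_GENES",
    "GenePanel",
    "FoldChange",
    "AdmriRecord",
    "default_gene_panel",
    "load_gene_panel",
    "save_gene_panel",
    "delta_delta_ct",
    "admri_value",
    "admri",
    "rank_admri",
    "annotate_volcano",
]

#: The six-gene qPCR readout of acinar vs ductal identity.
QPCR_ACINAR_GENES = ("Amy2a", "Cela1", "Cpa2")
QPCR_DUCTAL_GENES = ("Krt19", "Krt7", "Sox9")

# 27 acinar-identity genes (digestive-enzyme program and its transcriptional
# drivers) and 23 ductal/PDAC-associated genes used for volcano annotation.
_DEFAULT_ACINAR = (
    "Amy2a", "Cela1", "Cpa2", "Cpa1", "Cpb1", "Prss1", "Prss2", "Ctrb1",
    "Ctrc", "Ctrl", "Cel", "Pnlip", "Pnliprp1", "Pnliprp2", "Clps", "Cuzd1",
    "Sycn", "Serpini2", "Zg16", "Gp2", "Dmbt1", "Reg1", "Bhlha15", "Ptf1a",
    "Rbpjl", "Nr5a2", "Gata4",
)
_DEFAULT_DUCTAL_PDAC = (
    "Krt19", "Krt7", "Sox9", "Krt8", "Krt18", "Hnf1b", "Onecut1", "Onecut2",
    "Gata6", "Pdx1", "Muc1", "Cftr", "Car2", "Spp1", "Tff1", "Tff2", "Agr2",
    "Mmp7", "Ceacam1", "Aqp1", "Slc4a4", "S100a4", "Id2",
)


@dataclass(frozen=True)
class GenePanel:
    """Disjoint acinar and ductal/PDAC gene sets for volcano annotation."""

    acinar: tuple[str, ...]
    ductal_pdac: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.acinar) & set(self.ductal_pdac)
        if overlap:
            raise ValueError(f"panel sets overlap: {sorted(overlap)}")

    def set_of(self, gene: str) -> str:
        if gene in self.acinar:
            return "acinar"
        if gene in self.ductal_pdac:
            return "ductal_pdac"
        return "background"


def default_gene_panel() -> GenePanel:
    """Packaged 27-acinar / 23-ductal panel (includes the six qPCR genes)."""
    return GenePanel(acinar=_DEFAULT_ACINAR, ductal_pdac=_DEFAULT_DUCTAL_PDAC)


def load_gene_panel(path: str | Path) -> GenePanel:
    """Read a panel file: gene symbols one per line under ``[acinar]`` /
    ``[ductal_pdac]`` section headers; blank lines and ``#`` comments ignored."""
    sections: dict[str, list[str]] = {"acinar": [], "ductal_pdac": []}
    current: list[str] | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            key = line[1:-1].strip()
            if key not in sections:
                raise ValueError(f"{path}:{lineno}: unknown section [{key}]")
            current = sections[key]
        elif current is None:
            raise ValueError(f"{path}:{lineno}: gene outside any section")
        else:
            current.append(line)
    return GenePanel(acinar=tuple(sections["acinar"]),
                     ductal_pdac=tuple(sections["ductal_pdac"]))


def save_gene_panel(panel: GenePanel, path: str | Path) -> None:
    lines = ["[acinar]", *panel.acinar, "", "[ductal_pdac]", *panel.ductal_pdac, ""]
    Path(path).write_text("\n".join(lines))


@dataclass(frozen=True)
class FoldChange:
    treatment: str
    gene: str
    fc: float  # linear 2^-ddCT fold change, > 0
    n_replicates: int


@dataclass(frozen=True)
class AdmriRecord:
    compound_id: str
    dose: float  # µM
    mean_acinar_fc: float
    mean_ductal_fc: float
    admri: float
    rank: int | None = None


# ---------------------------------------------------------------------------
# 2^-ddCT
# ---------------------------------------------------------------------------

_CT_COLUMNS = ("sample_id", "treatment", "gene", "ct")


def delta_delta_ct(
    ct_table: pd.DataFrame,
    reference_gene: str = REFERENCE_GENE,
    vehicle_label: str = VEHICLE,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Relative quantification of a long-format CT table.

    Per sample, dCT = CT_gene - CT_reference; per gene,
    ddCT = mean dCT(treated) - mean dCT(vehicle) and fc = 2^-ddCT
    (the standard presentation: average on the CT scale, then exponentiate).
    With ``per_replicate=True`` each treated replicate is exponentiated
    against the vehicle mean first and the linear fold changes are averaged.

    Returns a DataFrame with columns treatment, gene, fc, n_replicates,
    one row per non-vehicle treatment and non-reference gene.
    """
    missing = [c for c in _CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"CT table is missing columns: {missing}")

    ref = (ct_table[ct_table["gene"] == reference_gene]
           .set_index("sample_id")["ct"])
    samples = ct_table["sample_id"].unique()
    without_ref = [s for s in samples if s not in ref.index]
    if without_ref:
        raise ValueError(
            f"samples missing reference gene {reference_gene!r}: "
            f"{without_ref[:5]}")
    if not (ct_table["treatment"] == vehicle_label).any():
        raise ValueError(f"no vehicle samples labeled {vehicle_label!r}")

    tbl = ct_table[ct_table["gene"] != reference_gene].copy()
    tbl["dct"] = tbl["ct"].to_numpy() - ref.loc[tbl["sample_id"]].to_numpy()

    veh = tbl[tbl["treatment"] == vehicle_label]
    veh_mean = veh.groupby("gene")["dct"].mean()

    out = []
    treated = tbl[tbl["treatment"] != vehicle_label]
    for (treatment, gene), grp in treated.groupby(["treatment", "gene"],
                                                  sort=True):
        if gene not in veh_mean.index:
            raise ValueError(
                f"gene {gene!r} has no vehicle measurements")
        if per_replicate:
            fc = float(np.mean(2.0 ** -(grp["dct"] - veh_mean[gene])))
        else:
            fc = float(2.0 ** -(grp["dct"].mean() - veh_mean[gene]))
        out.append((treatment, gene, fc, len(grp)))
    return pd.DataFrame(out, columns=["treatment", "gene", "fc",
                                      "n_replicates"])


# ---------------------------------------------------------------------------
# ADMRI
# ---------------------------------------------------------------------------

def admri_value(acinar_fcs: Iterable[float],
                ductal_fcs: Iterable[float]) -> float:
    """mean(acinar fold changes) / mean(ductal fold changes)."""
    acinar = np.asarray(list(acinar_fcs), dtype=float)
    ductal = np.asarray(list(ductal_fcs), dtype=float)
    if acinar.size == 0 or ductal.size == 0:
        raise ValueError("both gene sets must be non-empty")
    if np.any(acinar <= 0) or np.any(ductal <= 0):
        raise ValueError("fold changes must be positive")
    return float(acinar.mean() / ductal.mean())


def admri(
    fold_changes: pd.DataFrame | Mapping[str, float],
    compound_id: str = "",
    dose: float = float("nan"),
    acinar: Sequence[str] = QPCR_ACINAR_GENES,
    ductal: Sequence[str] = QPCR_DUCTAL_GENES,
    treatment: str | None = None,
) -> AdmriRecord:
    """Compute the ADM Reversal Index for one treatment.

    ``fold_changes`` is either a mapping gene -> linear fc, or a
    :func:`delta_delta_ct` table (optionally filtered with ``treatment``).
    All six panel genes must be present; a missing gene raises rather than
    silently subsetting.
    """
    if isinstance(fold_changes, pd.DataFrame):
        tbl = fold_changes
        if treatment is not None:
            tbl = tbl[tbl["treatment"] == treatment]
        fc_map = dict(zip(tbl["gene"], tbl["fc"]))
    else:
        fc_map = dict(fold_changes)
    missing = [g for g in (*acinar, *ductal) if g not in fc_map]
    if missing:
        raise KeyError(f"fold changes missing for genes: {missing}")
    a = [fc_map[g] for g in acinar]
    d = [fc_map[g] for g in ductal]
    value = admri_value(a, d)
    return AdmriRecord(compound_id=compound_id, dose=dose,
                       mean_acinar_fc=float(np.mean(a)),
                       mean_ductal_fc=float(np.mean(d)), admri=value)


def rank_admri(records: Sequence[AdmriRecord]) -> list[AdmriRecord]:
    """Dense descending rank within each dose group.

    Rank 1 is the largest ADMRI; equal values share a rank and the next
    distinct value gets the next integer. Output is sorted by
    (dose, rank, compound_id); ties are listed in compound_id order.
    """
    out: list[AdmriRecord] = []
    by_dose: dict[float, list[AdmriRecord]] = {}
    for rec in records:
        by_dose.setdefault(rec.dose, []).append(rec)
    for dose in sorted(by_dose):
        group = sorted(by_dose[dose], key=lambda r: (-r.admri, r.compound_id))
        distinct = sorted({r.admri for r in group}, reverse=True)
        rank_of = {v: i + 1 for i, v in enumerate(distinct)}
        out.extend(
            AdmriRecord(r.compound_id, r.dose, r.mean_acinar_fc,
                        r.mean_ductal_fc, r.admri, rank_of[r.admri])
            for r in group)
    return out


# ---------------------------------------------------------------------------
# Volcano annotation
# ---------------------------------------------------------------------------

def annotate_volcano(
    de_table: pd.DataFrame,
    panel: GenePanel,
    fc_cut: float = 1.5,
    fdr_cut: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Label a DE table against the acinar/ductal panel.

    Significance uses the linear fold change (|FC| > fc_cut in either
    direction, i.e. 2^log2fc > fc_cut or < 1/fc_cut) together with
    fdr < fdr_cut. Concordance with the reversal signature is
    (acinar up-significant + ductal down-significant) / panel size;
    NaN (flagged) for an empty table.

    Returns (annotated copy of the table, summary dict).
    """
    for col in ("gene", "log2fc", "fdr"):
        if col not in de_table.columns:
            raise ValueError(f"DE table is missing column {col!r}")
    tbl = de_table.copy()
    log2_cut = np.log2(fc_cut)
    sig = tbl["fdr"] < fdr_cut
    up = sig & (tbl["log2fc"] > log2_cut)
    down = sig & (tbl["log2fc"] < -log2_cut)
    tbl["gene_set"] = [panel.set_of(g) for g in tbl["gene"]]
    tbl["significance"] = np.select(
        [up, down], ["up-significant", "down-significant"], default="ns")

    n_panel = len(panel.acinar) + len(panel.ductal_pdac)
    acinar_up = int(((tbl["gene_set"] == "acinar") & up).sum())
    ductal_down = int(((tbl["gene_set"] == "ductal_pdac") & down).sum())
    concordance = (acinar_up + ductal_down) / n_panel if len(tbl) else float("nan")
    summary = {
        "n_genes": int(len(tbl)),
        "acinar_up_significant": acinar_up,
        "ductal_down_significant": ductal_down,
        "panel_size": n_panel,
        "concordance": concordance,
    }
    return tbl, summary
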