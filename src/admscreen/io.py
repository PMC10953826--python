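"""Typed readers and writers for every table and image the pipeline touches.

All tables are UTF-8 CSV with a mandatory header row, comma separator and
"." decimal; floats are written with 6 significant digits so that identical
runs produce byte-identical files. Images are 16-bit multi-page TIFF
(page 0 morphology, page 1 green) with a JSON sidecar recording the render
parameters and seed. Schema mismatches raise errors naming the missing
columns and the offending file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import SegmentationParams
from .render import RenderParams
from .screenstats import AssayQC, HitRecord, WellSummary
from .simgen import CompoundRecord, NoiseParams

__all__ = [
    "FLOAT_FORMAT",
    "read_table",
    "write_table",
    "write_library",
    "read_library",
    "write_well_summaries",
    "write_hit_table",
    "read_hit_table",
    "write_qc_json",
    "write_well_tiff",
    "read_well_tiff",
    "RunConfig",
]

FLOAT_FORMAT = "%.6g"

LIBRARY_COLUMNS = ["compound_id", "name", "target_class", "cluster_shift_inh",
                   "cluster_shift_rev", "cytotox_frac", "duct_size_factor"]
CT_COLUMNS = ["sample_id", "treatment", "gene", "ct"]
DE_COLUMNS = ["gene", "log2fc", "fdr"]
HIT_COLUMNS = [f.name for f in dataclasses.fields(HitRecord)]
WELL_SUMMARY_COLUMNS = [
    "plate_id", "row", "col", "compound_id", "dose", "mode",
    "replicate_index", "n_objects", "n_live", "pct_live_ducts",
    "pct_live_clusters", "pct_total_clusters", "viability_frac", "valid"]


def _require_columns(df: pd.DataFrame, columns: Sequence[str],
                     path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_table(path: str | Path,
               columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, optionally enforcing a schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path)
    if columns is not None:
        _require_columns(df, columns, path)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


# ---------------------------------------------------------------------------
# Library fixture
# ---------------------------------------------------------------------------

def write_library(records: Sequence[CompoundRecord], path: str | Path) -> Path:
    df = pd.DataFrame([asdict(r) for r in records], columns=LIBRARY_COLUMNS)
    return write_table(df, path)


def read_library(path: str | Path) -> list[CompoundRecord]:
    df = read_table(path, LIBRARY_COLUMNS)
    return [CompoundRecord(**{c: row[c] for c in LIBRARY_COLUMNS})
            for row in df.to_dict("records")]


# ---------------------------------------------------------------------------
# Screen outputs
# ---------------------------------------------------------------------------

def write_well_summaries(summaries: Sequence[WellSummary],
                         path: str | Path) -> Path:
    rows = []
    for s in summaries:
        spec = s.spec
        rows.append({
            "plate_id": spec.plate_id if spec else "",
            "row": spec.row if spec else -1,
            "col": spec.col if spec else -1,
            "compound_id": spec.compound_id if spec else "",
            "dose": spec.dose if spec else float("nan"),
            "mode": spec.mode if spec else "",
            "replicate_index": spec.replicate_index if spec else -1,
            "n_objects": s.n_objects, "n_live": s.n_live,
            "pct_live_ducts": s.pct_live_ducts,
            "pct_live_clusters": s.pct_live_clusters,
            "pct_total_clusters": s.pct_total_clusters,
            "viability_frac": s.viability_frac, "valid": s.valid,
        })
    return write_table(pd.DataFrame(rows, columns=WELL_SUMMARY_COLUMNS), path)


def write_hit_table(hits: Sequence[HitRecord], path: str | Path) -> Path:
    df = pd.DataFrame([asdict(h) for h in hits], columns=HIT_COLUMNS)
    return write_table(df, path)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    return read_table(path, HIT_COLUMNS)


def write_qc_json(qc: AssayQC, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(asdict(qc), indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def write_well_tiff(image: np.ndarray, path: str | Path,
                    render_params: RenderParams | None = None,
                    seed: int | None = None) -> Path:
    """Write a (2, H, W) uint16 stack as a two-page TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    image = np.asarray(image)
    if image.ndim != 3 or image.dtype != np.uint16:
        raise ValueError("expected a (C, H, W) uint16 image stack")
    tifffile.imwrite(path, image)
    sidecar = {
        "channels": ["morphology", "green_viability"],
        "pixel_convention": "0-based, row-major, origin top-left",
        "render_params": asdict(render_params) if render_params else None,
        "seed": seed,
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


def read_well_tiff(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    image = tifffile.imread(path)
    if image.ndim == 2:
        image = image[None]
    return image


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Complete, serializable description of a reproducible run.

    A run re-executed from its emitted config and seed is bit-identical at
    the object-table level (per-well streams are keyed by the seed and the
    well's slot, never by execution order).
    """

    mode: str = "inhibition"
    seed: int = 0
    replicates: int = 4
    alpha: float = 0.05
    viability_floor: float = 0.5
    screen_dose: float = 1.0
    control_dose: float = 10.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    render: RenderParams = field(default_factory=RenderParams)
    dose_series_top: float = 10.0
    dose_series_points: int = 6
    dose_series_factor: float = 3.162
    library_path: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("noise", "segmentation", "render"):
            d[key] = {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in d[key].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseParams(**d["noise"])
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if "render" in d and isinstance(d["render"], dict):
            r = {k: (tuple(v) if isinstance(v, list) else v)
                 for k, v in d["render"].items()}
            d["render"] = RenderParams(**r)
        return cls(**d)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        text = (json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=True))
        path.write_text(text)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"no such file: {path}")
        data = (json.loads(path.read_text()) if path.suffix == ".json"
                else yaml.safe_load(path.read_text()))
        return cls.from_dict(data)
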