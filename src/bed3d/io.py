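"""File formats and run configuration.

Open formats stand in for the planning system's proprietary ones:

* profile tables — CSV with columns ``collimator_mm, axis, offset_mm, rel_dose``
* plans — CSV with columns ``shot_index, collimator_mm, x_mm, y_mm, z_mm,
  dose_rate_gy_min, duration_min, gap_after_min`` (or JSON with the same
  field names)
* fitted collimator models — JSON
* dose / BED grids and masks — ASCII NRRD (see :mod:`bed3d.nrrdio`)
* histograms — CSV ``edge, differential_mm3, cumulative_mm3``
* meshes — text OBJ

Every grid output gets a JSON sidecar carrying the config hash, seed, and
library version, so byte-identical inputs are checkable downstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bed import RepairParams
from .dose import GridSpec, Plan, Shot
from .errors import ValidationError, VersionMismatchError
from .metrics import Histogram, IsoSurfaceMesh, StructureMask
from .nrrdio import read_nrrd, write_nrrd
from .profiles import COLLIMATOR_LABELS, CollimatorModel, DoseProfileTable

__all__ = [
    "read_profile_tables",
    "write_profile_tables",
    "read_plan",
    "write_plan",
    "save_models",
    "load_models",
    "save_grid",
    "load_grid",
    "save_mask",
    "load_mask",
    "save_histogram",
    "save_mesh_obj",
    "RunConfig",
    "config_hash",
    "write_sidecar",
    "read_sidecar",
]

FORMAT_VERSION = 1

PROFILE_COLUMNS = ["collimator_mm", "axis", "offset_mm", "rel_dose"]
PLAN_COLUMNS = [
    "shot_index", "collimator_mm", "x_mm", "y_mm", "z_mm",
    "dose_rate_gy_min", "duration_min", "gap_after_min",
]


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValidationError(
            f"{path}: line {line}: cannot parse {col}={df[col][bad.idxmax()]!r}"
        )
    if vals.isna().any():
        line = int(vals.isna().idxmax()) + 2
        raise ValidationError(f"{path}: line {line}: missing value in {col}")
    return vals.to_numpy()


# ---------------------------------------------------------------------------
# profile tables
# ---------------------------------------------------------------------------

def read_profile_tables(path) -> dict:
    """Read one profile CSV -> {collimator_label: {axis: DoseProfileTable}}."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    coll = _numeric_column(df, "collimator_mm", path).astype(int)
    offs = _numeric_column(df, "offset_mm", path)
    dose = _numeric_column(df, "rel_dose", path)
    axes = df["axis"].str.strip()
    out: dict = {}
    for label in sorted(set(coll)):
        if label not in COLLIMATOR_LABELS:
            raise ValidationError(f"{path}: unknown collimator {label}")
        out[label] = {}
        for axis in ("x", "y", "z"):
            sel = (coll == label) & (axes == axis).to_numpy()
            if not sel.any():
                continue
            order = np.argsort(offs[sel])
            table = DoseProfileTable(
                collimator_label=int(label), axis=axis,
                offsets_mm=offs[sel][order], rel_dose=dose[sel][order],
            )
            table.validate()
            out[label][axis] = table
    return out


def read_profiles_dir(directory) -> dict:
    """Merge all ``*.csv`` profile tables in a directory."""
    directory = Path(directory)
    merged: dict = {}
    files = sorted(directory.glob("*.csv"))
    if not files:
        raise ValidationError(f"no profile CSV files in {directory}")
    for f in files:
        for label, axes in read_profile_tables(f).items():
            merged.setdefault(label, {}).update(axes)
    return merged


def write_profile_tables(path, tables: dict) -> None:
    """Write {label: {axis: table}} (or {axis: table}) to one CSV."""
    if tables and isinstance(next(iter(tables.values())), DoseProfileTable):
        tables = {next(iter(tables.values())).collimator_label: tables}
    rows = []
    for label in sorted(tables):
        for axis in ("x", "y", "z"):
            if axis not in tables[label]:
                continue
            tb = tables[label][axis]
            for t, y in zip(tb.offsets_mm, tb.rel_dose):
                rows.append((label, axis, t, y))
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------

def _plan_from_frame(df: pd.DataFrame, path, name: str) -> Plan:
    missing = set(PLAN_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    cols = {c: _numeric_column(df, c, path) for c in PLAN_COLUMNS}
    order = np.argsort(cols["shot_index"])
    shots = [
        Shot(
            index=int(cols["shot_index"][k]),
            collimator_label=int(cols["collimator_mm"][k]),
            isocenter=(float(cols["x_mm"][k]), float(cols["y_mm"][k]),
                       float(cols["z_mm"][k])),
            dose_rate=float(cols["dose_rate_gy_min"][k]),
            duration=float(cols["duration_min"][k]),
            gap_after=float(cols["gap_after_min"][k]),
        )
        for k in order
    ]
    plan = Plan(shots=tuple(shots), name=name)
    plan.validate()
    return plan


def read_plan(path) -> Plan:
    """Read a plan from CSV or JSON (by extension)."""
    path = Path(path)
    name = path.stem
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["shots"] if "shots" in payload else payload)
        df = df.astype(str)
        return _plan_from_frame(df, path, payload.get("name", name)
                                if isinstance(payload, dict) else name)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    return _plan_from_frame(df, path, name)


def write_plan(path, plan: Plan) -> None:
    path = Path(path)
    rows = [
        {
            "shot_index": s.index, "collimator_mm": s.collimator_label,
            "x_mm": s.isocenter[0], "y_mm": s.isocenter[1], "z_mm": s.isocenter[2],
            "dose_rate_gy_min": s.dose_rate, "duration_min": s.duration,
            "gap_after_min": s.gap_after,
        }
        for s in plan.shots
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"name": plan.name, "shots": rows}, indent=1))
    else:
        pd.DataFrame(rows, columns=PLAN_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fitted models, grids, masks, histograms, meshes
# ---------------------------------------------------------------------------

def save_models(path, models: dict) -> None:
    """Serialize {label: CollimatorModel} to JSON (sorted, reproducible)."""
    payload = {
        "format_version": FORMAT_VERSION,
        "models": {str(k): models[k].to_dict() for k in sorted(models)},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_models(path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != FORMAT_VERSION:
        raise VersionMismatchError(
            f"{path}: format version {payload.get('format_version')} != "
            f"{FORMAT_VERSION}"
        )
    return {int(k): CollimatorModel.from_dict(v)
            for k, v in payload["models"].items()}


def save_grid(path, values: np.ndarray, spec: GridSpec) -> None:
    write_nrrd(path, values, spec)


def load_grid(path) -> tuple[np.ndarray, GridSpec]:
    return read_nrrd(path)


def save_mask(path, mask: StructureMask) -> None:
    write_nrrd(path, mask.voxels.astype(np.uint8), mask.spec)


def load_mask(path, label: str = "structure") -> StructureMask:
    values, spec = read_nrrd(path)
    return StructureMask(spec=spec, voxels=values > 0, label=label)


def save_histogram(path, hist: Histogram) -> None:
    hist.to_frame().to_csv(path, index=False)


def save_mesh_obj(path, mesh: IsoSurfaceMesh) -> None:
    with open(path, "w") as fh:
        fh.write(f"# iso-surface at {mesh.iso_level} ({mesh.quantity})\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in mesh.faces + 1:  # OBJ is 1-based
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")


# ---------------------------------------------------------------------------
# run configuration and sidecars
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one compute run needs, loadable from JSON."""

    profiles_dir: str
    plan_file: str
    output_dir: str
    masks: dict = field(default_factory=dict)  # label -> NRRD path
    grid: GridSpec = field(default_factory=GridSpec)
    repair: RepairParams = None
    fit: dict = field(default_factory=lambda: {"max_terms": 4, "rmse_tol": 0.005})
    histogram: dict = field(default_factory=lambda: {"bin_width": 0.5})
    prescription_level: float | None = None
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        cfg = json.loads(Path(path).read_text())
        grid = GridSpec(**cfg.get("grid", {}))
        repair = RepairParams.from_config(cfg["repair"]) if "repair" in cfg else None
        return cls(
            profiles_dir=cfg["profiles_dir"],
            plan_file=cfg["plan_file"],
            output_dir=cfg["output_dir"],
            masks=cfg.get("masks", {}),
            grid=grid,
            repair=repair,
            fit=cfg.get("fit", {"max_terms": 4, "rmse_tol": 0.005}),
            histogram=cfg.get("histogram", {"bin_width": 0.5}),
            prescription_level=cfg.get("prescription_level"),
            seed=int(cfg.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "profiles_dir": str(self.profiles_dir),
            "plan_file": str(self.plan_file),
            "output_dir": str(self.output_dir),
            "masks": {k: str(v) for k, v in self.masks.items()},
            "grid": {"n_per_axis": self.grid.n_per_axis,
                     "spacing": self.grid.spacing},
            "repair": self.repair.to_config() if self.repair else None,
            "fit": self.fit,
            "histogram": self.histogram,
            "prescription_level": self.prescription_level,
            "seed": self.seed,
        }

    def validate(self) -> None:
        for p in [self.profiles_dir, self.plan_file, *self.masks.values()]:
            if not Path(p).exists():
                raise ValidationError(f"configured path does not exist: {p}")


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_sidecar(artifact_path, cfg_hash: str, seed: int, extra: dict | None = None) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "library_version": __version__,
        "config_hash": cfg_hash,
        "seed": seed,
    }
    if extra:
        payload.update(extra)
    Path(str(artifact_path) + ".json").write_text(
        json.dumps(payload, indent=1, sort_keys=True)
    )


def read_sidecar(artifact_path) -> dict:
    payload = json.loads(Path(str(artifact_path) + ".json").read_text())
    if payload.get("format_version") != FORMAT_VERSION:
        raise VersionMismatchError(
            f"sidecar of {artifact_path}: format version mismatch"
        )
    return payload
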