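"""Dose-grid files, packaged reference tables, comparison arithmetic, pipeline.

Dose grids are stored as NRRD (raw little-endian float32) with the full
simulation provenance embedded as key-value pairs and mirrored in a JSON
sidecar; reading requires voxel spacing and complete provenance so any
grid on disk can be regenerated bit-identically from its recorded seed.

The packaged reference tables hold the published simulation-vs-formula
values for the lateral shift (percentage differences per energy) and the
depth retraction (mm per energy and field), plus the energy-selection
worked example; they are read-only and checksummed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from . import __version__ as _pkg_version
from .analytic import predict, predictions_to_frame
from .errors import FixtureError, FormatError
from .physics import StoppingModel
from .simulate import BeamSpec, DoseGrid, FieldSpec, PhantomGrid, simulate_dose_grid
from .analysis import measure_shifts

__all__ = [
    "ComparisonTable",
    "PaperFixture",
    "build_comparison",
    "compare_fixture",
    "load_fixture",
    "read_dose_grid",
    "write_dose_grid",
    "run_pipeline",
    "load_config",
]

_PROVENANCE_KEY = "braggshift_provenance"
_REQUIRED_PROVENANCE = (
    "mode",
    "energy_mev",
    "spot_sigma_cm",
    "field_t",
    "grid_voxel_cm",
    "grid_origin_cm",
    "histories",
    "seed",
)

# ---------------------------------------------------------------------------
# NRRD dose grids


def write_dose_grid(grid: DoseGrid, path: Union[str, Path]) -> Path:
    """Write a dose grid as raw float32 NRRD plus a JSON provenance sidecar."""
    path = Path(path)
    arr = np.ascontiguousarray(np.transpose(grid.values.astype(np.float32), (2, 1, 0)))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(v) for v in grid.grid.voxel))
    img.SetOrigin(tuple(float(o) for o in grid.grid.origin))
    img.SetMetaData(_PROVENANCE_KEY, json.dumps(grid.provenance, sort_keys=True))
    sitk.WriteImage(img, str(path), useCompression=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(grid.provenance, indent=1, sort_keys=True) + "\n")
    return path


def _check_nrrd_header(path: Path) -> None:
    """Require an explicit voxel-spacing field in the NRRD header."""
    with open(path, "rb") as fh:
        header = fh.read(4096).decode("ascii", errors="replace")
    head = header.split("\n\n", 1)[0]
    if "space directions" not in head and "spacings" not in head:
        raise FormatError(f"{path}: NRRD header lacks voxel spacing "
                          "('space directions' or 'spacings')")


def read_dose_grid(path: Union[str, Path]) -> DoseGrid:
    """Read a dose grid written by :func:`write_dose_grid` (lossless)."""
    path = Path(path)
    _check_nrrd_header(path)
    img = sitk.ReadImage(str(path))
    prov: Optional[dict] = None
    if img.HasMetaDataKey(_PROVENANCE_KEY):
        prov = json.loads(img.GetMetaData(_PROVENANCE_KEY))
    else:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            prov = json.loads(sidecar.read_text())
    if prov is None:
        raise FormatError(f"{path}: missing provenance (key {_PROVENANCE_KEY!r} "
                          "and no JSON sidecar)")
    for key in _REQUIRED_PROVENANCE:
        if key not in prov:
            raise FormatError(f"{path}: provenance lacks required key {key!r}")
    values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    voxel = tuple(img.GetSpacing())
    origin = tuple(img.GetOrigin())
    extent = tuple(v * n for v, n in zip(voxel, values.shape))
    phantom = PhantomGrid(extent=extent, voxel=voxel, origin=origin)
    return DoseGrid(values=values.astype(np.float32), grid=phantom, provenance=prov)


# ---------------------------------------------------------------------------
# Packaged reference tables


@dataclass(frozen=True)
class PaperFixture:
    """A read-only packaged reference table (checksummed at load time)."""

    identifier: str
    data: Union[pd.DataFrame, dict]
    units: str


def _data_bytes(name: str) -> bytes:
    ref = resources.files("braggshift.data").joinpath(name)
    return ref.read_bytes()


def load_fixture(identifier: str) -> PaperFixture:
    """Load one of the packaged tables: 'table1', 'table2', 'worked_example'."""
    files = {
        "table1": ("table1.csv", "percent"),
        "table2": ("table2.csv", "mm"),
        "worked_example": ("worked_example.json", "mixed"),
    }
    if identifier not in files:
        raise FixtureError(f"unknown fixture {identifier!r}; known: {sorted(files)}")
    name, units = files[identifier]
    raw = _data_bytes(name)
    sums = json.loads(_data_bytes("checksums.json"))
    digest = hashlib.sha256(raw).hexdigest()
    if digest != sums[name]:
        raise FixtureError(f"fixture {name} failed its checksum "
                           f"(got {digest[:12]}..., expected {sums[name][:12]}...)")
    if name.endswith(".json"):
        data: Union[pd.DataFrame, dict] = json.loads(raw)
    else:
        import io as _io

        data = pd.read_csv(_io.BytesIO(raw))
    return PaperFixture(identifier=identifier, data=data, units=units)


# ---------------------------------------------------------------------------
# Comparison arithmetic


@dataclass
class ComparisonTable:
    """Per-(energy, field) simulated-vs-analytic differences with a summary.

    ``rows`` carries columns energy_mev, field_t, simulated, analytic,
    abs_diff_mm and percent_diff (percent of the simulated value);
    ``summary`` holds the mean percent difference and the maximum absolute
    difference, and is exactly recomputable from the rows.
    """

    rows: pd.DataFrame
    value_unit: str = "cm"
    summary: dict = dc_field(default_factory=dict)

    def recompute_summary(self) -> dict:
        out = {}
        pct = self.rows["percent_diff"].dropna()
        if len(pct):
            out["mean_percent_diff"] = float(pct.mean())
        diffs = self.rows["abs_diff_mm"].dropna()
        if len(diffs):
            out["max_abs_diff_mm"] = float(diffs.max())
        return out


def build_comparison(
    simulated: pd.DataFrame, analytic: pd.DataFrame, value_unit: str = "cm"
) -> ComparisonTable:
    """Align simulated and analytic rows on (energy, field) and difference them.

    Both frames need columns energy_mev, field_t, value (in ``value_unit``).
    The percent difference uses the simulated value as denominator.
    """
    key = ["energy_mev", "field_t"]
    for name, df in (("simulated", simulated), ("analytic", analytic)):
        missing = [c for c in key + ["value"] if c not in df.columns]
        if missing:
            raise ValueError(f"{name} frame lacks columns {missing}")
    merged = simulated.merge(analytic, on=key, how="outer", suffixes=("_sim", "_ana"),
                             indicator=True)
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        pairs = bad[key].to_records(index=False).tolist()
        raise ValueError(f"unmatched (energy, field) pairs: {pairs}")
    to_mm = {"cm": 10.0, "mm": 1.0}[value_unit]
    rows = pd.DataFrame(
        {
            "energy_mev": merged["energy_mev"],
            "field_t": merged["field_t"],
            "simulated": merged["value_sim"],
            "analytic": merged["value_ana"],
        }
    )
    rows["abs_diff_mm"] = (rows["analytic"] - rows["simulated"]).abs() * to_mm
    rows["percent_diff"] = 100.0 * (rows["analytic"] - rows["simulated"]).abs() / rows[
        "simulated"
    ]
    table = ComparisonTable(rows=rows, value_unit=value_unit)
    table.summary = table.recompute_summary()
    return table


def compare_fixture(identifier: str) -> ComparisonTable:
    """Comparison arithmetic over a packaged table.

    'table2' differences the simulation and formula columns (mm).  'table1'
    already stores percentage differences; its summary is the mean of each
    formula column.
    """
    fx = load_fixture(identifier)
    if identifier == "table2":
        df = fx.data
        sim = df.rename(columns={"simulation_mm": "value"})[
            ["energy_mev", "field_t", "value"]
        ]
        ana = df.rename(columns={"formula_mm": "value"})[
            ["energy_mev", "field_t", "value"]
        ]
        return build_comparison(sim, ana, value_unit="mm")
    if identifier == "table1":
        df = fx.data
        rows = pd.DataFrame(
            {
                "energy_mev": df["energy_mev"],
                "field_t": np.nan,
                "simulated": np.nan,
                "analytic": np.nan,
                "abs_diff_mm": np.nan,
                "percent_diff": np.nan,
            }
        )
        table = ComparisonTable(rows=rows, value_unit="percent")
        table.summary = {
            "formula1_mean_percent": float(df["formula1_percent"].mean()),
            "formula2_mean_percent": float(df["formula2_percent"].mean()),
        }
        return table
    raise FixtureError(f"no comparison defined for fixture {identifier!r}")


# ---------------------------------------------------------------------------
# Configuration and end-to-end pipeline


_DEFAULT_CONFIG = {
    "energies": [141.0, 148.0],
    "fields": [3.0],
    "mode": "pencil",
    "histories": 200_000,
    "seed": 20210803,
    "relativistic": False,
    "out_dir": "braggshift_run",
    "grid": {},
    "model": {},
}


def load_config(path: Union[str, Path]) -> dict:
    """Read a YAML (or JSON-equivalent) run configuration, applying defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(_DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def _model_from_config(cfg: dict) -> StoppingModel:
    m = cfg.get("model", {}) or {}
    return StoppingModel(
        alpha=m.get("alpha", 2.43e-3),
        p=m.get("p", 1.75),
        rest_energy=m.get("rest_energy_mev", 938.272),
        cutoff_energy=m.get("cutoff_mev", 0.1),
    )


def run_pipeline(config: dict) -> dict:
    """Simulate, analyze and compare for every (energy, field) in the config.

    For each energy a field-free reference grid and one grid per nonzero
    field are scored and written as NRRD; measured shifts, analytic
    predictions and their comparison are written as CSV, together with a
    JSON run log.  Re-running with the same config reproduces every CSV
    byte-for-byte.
    """
    cfg = dict(_DEFAULT_CONFIG)
    cfg.update(config)
    energies = list(cfg["energies"])
    fields = [b for b in cfg["fields"] if b > 0]
    if not energies:
        raise ValueError("config lists no energies")
    if not fields:
        raise ValueError("config lists no nonzero fields")
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    model = _model_from_config(cfg)
    grid_cfg = cfg.get("grid", {}) or {}
    grid = PhantomGrid(
        extent=tuple(grid_cfg.get("extent", (20.0, 20.0, 35.0))),
        voxel=tuple(grid_cfg.get("voxel", (0.05, 0.05, 0.1))),
        origin=tuple(grid_cfg.get("origin", (-10.0, -10.0, 0.0))),
    )

    shift_rows = []
    pred_rows = []
    for energy in energies:
        beam = BeamSpec(energy=energy)
        ref = simulate_dose_grid(
            beam, FieldSpec(0.0), grid, mode=cfg["mode"],
            histories=cfg["histories"], seed=cfg["seed"], model=model,
            relativistic=cfg["relativistic"],
        )
        write_dose_grid(ref, out_dir / f"dose_E{energy:g}_B0.nrrd")
        for b in fields:
            dg = simulate_dose_grid(
                beam, FieldSpec(b), grid, mode=cfg["mode"],
                histories=cfg["histories"], seed=cfg["seed"], model=model,
                relativistic=cfg["relativistic"],
            )
            write_dose_grid(dg, out_dir / f"dose_E{energy:g}_B{b:g}.nrrd")
            sm = measure_shifts(dg, ref)
            shift_rows.append(
                {
                    "energy_mev": energy,
                    "field_t": b,
                    "wd_cm": sm.wd,
                    "ddd_cm": sm.ddd,
                    "angle_deg": sm.angle_def,
                }
            )
            pred_rows.append(predict(energy, b, relativistic=cfg["relativistic"], model=model))

    shifts = pd.DataFrame(shift_rows)
    preds = predictions_to_frame(pred_rows)
    sim_wd = shifts.rename(columns={"wd_cm": "value"})[["energy_mev", "field_t", "value"]]
    ana_wd = preds.rename(columns={"wd_cm": "value"})[["energy_mev", "field_t", "value"]]
    comparison = build_comparison(sim_wd, ana_wd, value_unit="cm")

    paths = {
        "shifts": out_dir / "shifts.csv",
        "predictions": out_dir / "predictions.csv",
        "comparison": out_dir / "comparison_wd.csv",
        "log": out_dir / "run_log.json",
    }
    shifts.to_csv(paths["shifts"], index=False, float_format="%.9g")
    preds.to_csv(paths["predictions"], index=False, float_format="%.9g")
    comparison.rows.to_csv(paths["comparison"], index=False, float_format="%.9g")
    log = {
        "config": {k: v for k, v in cfg.items() if k != "out_dir"},
        "package_version": _pkg_version,
        "comparison_summary": comparison.summary,
    }
    paths["log"].write_text(json.dumps(log, indent=1, sort_keys=True) + "\n")
    return {
        "shifts": shifts,
        "predictions": preds,
        "comparison": comparison,
        "paths": {k: str(v) for k, v in paths.items()},
    }
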