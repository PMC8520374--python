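"""File formats: NIfTI volumes, CSV curves/tables, YAML/JSON configs.

Volumes are written as NIfTI (via nibabel) with an affine encoding the
voxel size in mm and, for 4D series, the frame spacing in the time zoom.
Paths ending in ``.npz`` use a documented numpy-archive fallback (arrays
stored under the key ``data`` plus ``voxel_size``/``dt``).  Curves and
tables are plain CSV with header rows; configs are YAML (JSON is a YAML
subset and is accepted transparently).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Dict, Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import (
    AIFCurve,
    AIFParams,
    LesionSpec,
    PhantomSpec,
    TimeGrid,
    TissueClass,
)
from .perfusion import ConversionConstants
from .solvers import SolveResult, SolverConfig


class ConfigError(ValueError):
    """Invalid run configuration (maps to CLI exit code 2)."""


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------


def save_volume(path, data: np.ndarray, voxel_size: float = 1.0, dt: Optional[float] = None) -> None:
    path = Path(path)
    data = np.asarray(data)
    if path.suffix == ".npz":
        np.savez(path, data=data, voxel_size=voxel_size, dt=np.nan if dt is None else dt)
        return
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    zooms = [voxel_size] * min(3, data.ndim)
    if data.ndim == 4:
        zooms.append(dt if dt is not None else 1.0)
        img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(tuple(zooms))
    nib.save(img, str(path))


def load_volume(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as npz:
            return np.asarray(npz["data"])
    return np.asarray(nib.load(str(path)).get_fdata())


# ---------------------------------------------------------------------------
# Curves and traces
# ---------------------------------------------------------------------------


def save_aif_csv(path, aif: AIFCurve) -> None:
    pd.DataFrame({"time_s": aif.grid.times, "value_hu": aif.values}).to_csv(path, index=False)


def load_aif_csv(path) -> AIFCurve:
    df = pd.read_csv(path)
    for col in ("time_s", "value_hu"):
        if col not in df.columns:
            raise ConfigError(f"AIF table {path} is missing column {col!r}")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ConfigError("AIF table needs at least two samples")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0]):
        raise ConfigError("AIF table must be sampled on a uniform time grid")
    grid = TimeGrid(n_frames=len(t), dt=float(dts[0]), t0=float(t[0]))
    return AIFCurve(values=df["value_hu"].to_numpy(float), grid=grid)


def save_trace_csv(path, result: SolveResult) -> None:
    n = len(result.objective_trace)
    pd.DataFrame(
        {
            "iteration": np.arange(n),
            "objective": result.objective_trace,
            "fidelity": result.fidelity_trace or [np.nan] * n,
            "prior": result.prior_trace or [np.nan] * n,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Phantom spec <-> dict / YAML
# ---------------------------------------------------------------------------


def spec_to_dict(spec: PhantomSpec) -> Dict[str, Any]:
    d = dataclasses.asdict(spec)
    d["shape"] = list(spec.shape)
    d["lesions"] = [dataclasses.asdict(l) for l in spec.lesions]
    return _plain(d)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, float) and np.isinf(obj):
        return None
    return obj


def spec_from_dict(d: Dict[str, Any]) -> PhantomSpec:
    d = dict(d or {})
    kwargs: Dict[str, Any] = {}
    if "shape" in d:
        kwargs["shape"] = tuple(int(v) for v in d.pop("shape"))
    if "time" in d:
        kwargs["time"] = TimeGrid(**d.pop("time"))
    if "aif" in d:
        kwargs["aif"] = AIFParams(**d.pop("aif"))
    for tissue in ("gray", "white"):
        if tissue in d:
            kwargs[tissue] = TissueClass(**d.pop(tissue))
    if "consts" in d:
        kwargs["consts"] = ConversionConstants(**d.pop("consts"))
    if "lesions" in d:
        lesions = []
        for l in d.pop("lesions"):
            l = dict(l)
            l.pop("rcbv", None)  # derived property, tolerated on input
            l["center"] = tuple(float(v) for v in l["center"])
            l["radii"] = tuple(float(v) for v in l["radii"])
            lesions.append(LesionSpec(**l))
        kwargs["lesions"] = tuple(lesions)
    for key in ("brain_radii", "white_radii"):
        if key in d:
            v = d.pop(key)
            kwargs[key] = None if v is None else tuple(np.inf if x is None else float(x) for x in v)
    kwargs.update(d)
    try:
        return PhantomSpec(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid phantom spec: {exc}") from exc


def solver_config_from_dict(d: Dict[str, Any]) -> SolverConfig:
    d = dict(d or {})
    if "lambda" in d:  # accept the field's mathematical name in configs
        d["lam"] = d.pop("lambda")
    try:
        return SolverConfig(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid solver config: {exc}") from exc


def load_config(path) -> Dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def write_manifest(path, entries: Dict[str, Any]) -> None:
    with open(path, "w") as fh:
        json.dump(_plain(entries), fh, indent=2)
        fh.write("\n")


def read_manifest(path) -> Dict[str, Any]:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"manifest not found: {p} (run the phantom step first)")
    with open(p) as fh:
        return json.load(fh)
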