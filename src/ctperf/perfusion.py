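"""Perfusion parameter maps from residue estimates and tissue curves.

Implements the standard CT-perfusion estimators:

* CBF (mL/100g/min): peak of the flow-scaled residue function.
* CBV (mL/100g): ratio of tissue-curve to arterial-curve areas (trapezoid
  rule on the acquisition grid).
* MTT (s): central-volume theorem, ``MTT = 60 * CBV / CBF``.
* TTP (s): time of the tissue-curve maximum, ties broken toward the
  earliest frame.

and the affected/contralateral relative maps (percent of the voxel mirrored
across the mid-sagittal plane), mirroring what clinical perfusion software
reports for core-infarct and penumbra assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .kinetics import ConvolutionSystem, forward

PARAMETERS = ("cbf", "cbv", "mtt", "ttp")

#: Region label coding shared with the phantom module.
LABEL_BACKGROUND, LABEL_NORMAL, LABEL_PENUMBRA, LABEL_CORE = 0, 1, 2, 3
LABEL_NAMES = {LABEL_NORMAL: "normal", LABEL_PENUMBRA: "PI", LABEL_CORE: "CIA"}


@dataclass(frozen=True)
class ConversionConstants:
    """Unit-conversion constants for the flow/volume estimators.

    rho is the brain tissue density in g/mL; k is a dimensionless
    calibration factor (hematocrit correction), kept at 1 by default.
    """

    rho: float = 1.04
    k: float = 1.0


@dataclass
class PerfusionMaps:
    """CBF/CBV/MTT/TTP volumes plus the conversion constants used."""

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    ttp: np.ndarray
    consts: ConversionConstants = field(default_factory=ConversionConstants)

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class RelativeMaps:
    """Percent-of-contralateral maps, defined on the affected hemisphere.

    Voxels where the ratio is undefined (mirror outside the mask, zero or
    non-finite denominator, or voxel on the contralateral side) hold NaN.
    The mirror axis is the mid-sagittal plane x = (nx - 1) / 2.
    """

    rcbf: np.ndarray
    rcbv: np.ndarray
    rmtt: np.ndarray
    rttp: np.ndarray
    affected_side: str = "right"

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name)


def compute_cbf(
    G_hat: np.ndarray, consts: ConversionConstants = ConversionConstants()
) -> np.ndarray:
    """CBF map (mL/100g/min) from a residue estimate ``(..., T)``.

    ``CBF = k * 100 * 60 * max_t G / rho``; the residue peak equals the flow
    because the residue function is 1 at the arrival of an ideal bolus.
    """
    G_hat = np.asarray(G_hat, dtype=float)
    if not np.all(np.isfinite(G_hat)):
        raise ValueError("residue estimate contains non-finite values")
    return consts.k * 6000.0 * np.max(G_hat, axis=-1) / consts.rho


def compute_cbv(
    C: np.ndarray,
    B: np.ndarray,
    dt: float,
    consts: ConversionConstants = ConversionConstants(),
) -> np.ndarray:
    """CBV map (mL/100g) as the area ratio of tissue to arterial curves.

    ``CBV = k * 100 * (trapz C / trapz B) / rho``, trapezoid rule on the
    acquisition grid; linear in ``C``.
    """
    C = np.asarray(C, dtype=float)
    B = np.asarray(B, dtype=float).ravel()
    aif_area = float(np.trapezoid(B, dx=dt))
    if aif_area <= 0:
        raise ValueError(f"AIF integral must be positive, got {aif_area}")
    tissue_area = np.trapezoid(C, dx=dt, axis=-1)
    return consts.k * 100.0 * tissue_area / (aif_area * consts.rho)


def compute_mtt(cbf: np.ndarray, cbv: np.ndarray) -> np.ndarray:
    """MTT map (s) by the central-volume theorem, NaN where CBF <= 0."""
    cbf = np.asarray(cbf, dtype=float)
    cbv = np.asarray(cbv, dtype=float)
    if cbf.shape != cbv.shape:
        raise ValueError("CBF and CBV maps are not conformable")
    out = np.full(cbf.shape, np.nan)
    ok = cbf > 0
    out[ok] = 60.0 * cbv[ok] / cbf[ok]
    return out


def compute_ttp(C: np.ndarray, dt: float, t0: float = 0.0) -> np.ndarray:
    """TTP map (s): ``t0 + dt * argmax_k C_k``; all-zero curves give NaN.

    ``np.argmax`` returns the first maximum, which realizes the
    earliest-frame tie rule.
    """
    C = np.asarray(C, dtype=float)
    ttp = t0 + dt * np.argmax(C, axis=-1).astype(float)
    invalid = np.all(C == 0.0, axis=-1)
    if np.ndim(ttp) == 0:
        return np.nan if invalid else float(ttp)
    ttp[invalid] = np.nan
    return ttp


def compute_maps(
    G_hat: np.ndarray,
    sys: ConvolutionSystem,
    t0: float = 0.0,
    consts: ConversionConstants = ConversionConstants(),
    curves: Optional[np.ndarray] = None,
) -> PerfusionMaps:
    """Full parameter-map pipeline from a residue estimate.

    CBV and TTP need tissue curves; by default the model-consistent
    reconstruction ``C_hat = A @ G_hat`` is used so that all four maps
    reflect the deconvolution result (this is what makes per-solver map
    comparisons meaningful on noisy data).  Pass ``curves`` explicitly to
    score the measured curves instead, e.g. the clinical TTP convention.
    """
    if curves is None:
        curves = forward(sys, G_hat)
    cbf = compute_cbf(G_hat, consts)
    cbv = compute_cbv(curves, sys.B, sys.dt, consts)
    mtt = compute_mtt(cbf, cbv)
    ttp = compute_ttp(curves, sys.dt, t0)
    return PerfusionMaps(cbf=cbf, cbv=cbv, mtt=mtt, ttp=ttp, consts=consts)


def mirror_index(nx: int) -> np.ndarray:
    """Index array flipping voxels across the mid-sagittal plane x=(nx-1)/2."""
    if nx % 2 != 0:
        raise ValueError(f"mirror requires an even grid width, got nx={nx}")
    return np.arange(nx)[::-1]


def _affected_mask(shape: tuple, affected_side: str) -> np.ndarray:
    nx = shape[0]
    x = np.arange(nx)
    if affected_side == "right":
        half = x >= nx // 2
    elif affected_side == "left":
        half = x < nx // 2
    else:
        raise ValueError(f"affected_side must be 'left' or 'right', got {affected_side!r}")
    return np.broadcast_to(half.reshape((nx,) + (1,) * (len(shape) - 1)), shape)


def compute_relative_maps(
    maps: PerfusionMaps,
    brain_mask: np.ndarray,
    affected_side: str = "right",
) -> RelativeMaps:
    """Affected/contralateral percent ratios by mirror line symmetry.

    For every affected-side voxel v, ``rX(v) = 100 * X(v) / X(mirror(v))``
    for X in CBF/CBV/MTT/TTP.  Undefined (NaN) where the mirror voxel is
    outside the brain mask or its value is not strictly positive.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    shape = brain_mask.shape
    affected = _affected_mask(shape, affected_side)
    flip = mirror_index(shape[0])

    out = {}
    for name in PARAMETERS:
        X = np.asarray(maps[name], dtype=float)
        if X.shape != shape:
            raise ValueError(f"map {name} shape {X.shape} != mask shape {shape}")
        Xm = X[flip]
        mask_m = brain_mask[flip]
        ok = affected & brain_mask & mask_m & np.isfinite(X) & np.isfinite(Xm) & (Xm > 0)
        r = np.full(shape, np.nan)
        r[ok] = 100.0 * X[ok] / Xm[ok]
        out["r" + name] = r
    return RelativeMaps(affected_side=affected_side, **out)


def classify_regions(
    rel: RelativeMaps, cia_cut: float = 30.0, pi_cut: float = 70.0
) -> np.ndarray:
    """Threshold rCBF into core-infarct / penumbra / normal labels.

    Core infarct where ``rCBF < cia_cut``, penumbra where
    ``cia_cut <= rCBF < pi_cut``, normal otherwise; voxels with undefined
    rCBF are labelled background (0).
    """
    if not cia_cut < pi_cut and not (cia_cut == pi_cut == 0):
        raise ValueError(f"thresholds must satisfy cia_cut < pi_cut, got {cia_cut}, {pi_cut}")
    r = rel.rcbf
    labels = np.zeros(r.shape, dtype=np.int8)
    defined = np.isfinite(r)
    labels[defined] = LABEL_NORMAL
    labels[defined & (r < pi_cut)] = LABEL_PENUMBRA
    labels[defined & (r < cia_cut)] = LABEL_CORE
    return labels


def region_summary(
    rel: RelativeMaps, labels: np.ndarray, phase: str = "pre"
) -> pd.DataFrame:
    """Per-region mean +- SD of the relative parameters.

    Returns one row per (region, parameter) with columns
    region, parameter, phase, mean, sd, n_voxels.
    """
    labels = np.asarray(labels)
    rows = []
    for code, region in LABEL_NAMES.items():
        region_mask = labels == code
        for name in PARAMETERS:
            vals = rel["r" + name][region_mask]
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "region": region,
                    "parameter": "r" + name.upper(),
                    "phase": phase,
                    "mean": float(np.mean(vals)) if vals.size else np.nan,
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0 if vals.size else np.nan,
                    "n_voxels": int(vals.size),
                }
            )
    return pd.DataFrame(rows)
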