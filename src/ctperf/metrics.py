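"""Reconstruction-quality metrics and the solver-comparison harness.

PSNR, MSE and MAE score a reconstructed map against the reference
("standard dose") map over a region of interest of Q pixels:

    MSE  = (1/Q) sum (X - X_true)^2
    MAE  = (1/Q) sum |X - X_true|
    PSNR = 10 log10(peak^2 / MSE)

with the PSNR peak taken as the maximum of the reference map on the mask
(perfusion maps are physical quantities, not 8-bit images).  The mean of
the reference, X_bar_true, is carried as report metadata but enters no
default metric.  The harness runs several solvers on bit-identical noisy
realizations of one phantom (paired by seed) and scores the four perfusion
maps of each solver against the phantom's ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import perfusion
from .perfusion import PARAMETERS, compute_maps
from .phantom import PhantomData, add_noise
from .solvers import SolverConfig, SolverFailure, solve


def _as_mask(X: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
    if mask is None:
        mask = np.ones(np.shape(X), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("evaluation mask is empty")
    return mask


def mse(X: np.ndarray, X_true: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Mean squared error over the mask."""
    X, X_true = np.asarray(X, float), np.asarray(X_true, float)
    m = _as_mask(X, mask)
    d = X[m] - X_true[m]
    return float(np.mean(d * d))


def mae(X: np.ndarray, X_true: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Mean absolute error over the mask."""
    X, X_true = np.asarray(X, float), np.asarray(X_true, float)
    m = _as_mask(X, mask)
    return float(np.mean(np.abs(X[m] - X_true[m])))


def psnr(
    X: np.ndarray,
    X_true: np.ndarray,
    mask: Optional[np.ndarray] = None,
    peak: Optional[float] = None,
) -> float:
    """Peak signal-to-noise ratio in dB; ``+inf`` when the maps coincide.

    ``peak`` defaults to the maximum of the reference on the mask.
    """
    X, X_true = np.asarray(X, float), np.asarray(X_true, float)
    m = _as_mask(X, mask)
    if peak is None:
        peak = float(np.max(X_true[m]))
    if peak <= 0:
        raise ValueError(f"PSNR peak must be positive, got {peak}")
    e = mse(X, X_true, m)
    if e == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / e))


@dataclass
class MetricReport:
    """Per-(solver, parameter, seed) metric records plus aggregation helpers.

    ``records`` columns: solver, parameter, seed, psnr, mse, mae, q, peak,
    ref_mean (the mean of the reference map on the mask).
    """

    records: pd.DataFrame
    seeds: Sequence[int] = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        """Mean +- SD per (solver, parameter, metric) cell across seeds."""
        long = self.records.melt(
            id_vars=["solver", "parameter", "seed"],
            value_vars=["psnr", "mse", "mae"],
            var_name="metric",
        )
        g = long.groupby(["solver", "parameter", "metric"])["value"]
        out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        out["n_seeds"] = g.size()
        return out.reset_index()

    def cell_mean(self, solver: str, parameter: str, metric: str) -> float:
        r = self.records
        vals = r.loc[(r.solver == solver) & (r.parameter == parameter), metric]
        return float(vals.mean())

    def to_csv(self, path) -> None:
        self.aggregate().to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.aggregate().to_json(path, orient="records", indent=2)


def evaluate_solvers(
    phantom: PhantomData,
    solvers: Mapping[str, SolverConfig],
    seeds: Sequence[int],
    sigma: Optional[float] = None,
) -> MetricReport:
    """Score solvers on paired noisy realizations of one phantom.

    For each seed, Gaussian noise of SD ``sigma`` (default: the phantom
    spec's ``noise_sigma``) is added once, every solver sees that identical
    noisy series, the four perfusion maps are computed from each solver's
    residue estimate (CBV/TTP from the model-consistent reconstruction
    ``A @ G_hat``), and each map is scored against the phantom's
    ground-truth maps over the brain mask.  A failing solver yields NaN
    records for that seed rather than aborting the run.
    """
    if len(seeds) < 1:
        raise ValueError("need at least one seed")
    if sigma is None:
        sigma = phantom.spec.noise_sigma
    grid = phantom.spec.time
    truth = phantom.truth
    brain = phantom.brain_mask
    rows = []
    for seed in seeds:
        noisy = add_noise(phantom.series, sigma, seed)
        for name, cfg in solvers.items():
            try:
                res = solve(noisy, phantom.system, cfg)
                maps = compute_maps(
                    res.G_hat, phantom.system, t0=grid.t0, consts=phantom.spec.consts
                )
            except SolverFailure as exc:
                warnings.warn(f"solver {name!r} failed on seed {seed}: {exc}", stacklevel=2)
                for param in PARAMETERS:
                    rows.append(
                        dict(solver=name, parameter=param, seed=seed, psnr=np.nan,
                             mse=np.nan, mae=np.nan, q=0, peak=np.nan, ref_mean=np.nan)
                    )
                continue
            for param in PARAMETERS:
                ref = np.asarray(truth.as_perfusion_maps(phantom.spec.consts)[param], float)
                rec = np.asarray(maps[param], float)
                m = brain & np.isfinite(ref) & np.isfinite(rec)
                peak = float(np.max(ref[m]))
                rows.append(
                    dict(
                        solver=name,
                        parameter=param,
                        seed=seed,
                        psnr=psnr(rec, ref, m, peak),
                        mse=mse(rec, ref, m),
                        mae=mae(rec, ref, m),
                        q=int(m.sum()),
                        peak=peak,
                        ref_mean=float(np.mean(ref[m])),
                    )
                )
    return MetricReport(records=pd.DataFrame(rows), seeds=list(seeds))
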