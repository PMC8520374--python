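"""Regularized deconvolution of the tracer-kinetic convolution model.

The flow-scaled residue G is recovered from tissue curves C by minimizing

    F(G) = 0.5 * sum_v ||A g_v - c_v||^2  +  lambda * R(G)

with four choices of R / algorithm:

``tsvd``
    Truncated-SVD pseudo-inverse: singular values below a fraction of
    sigma_max are discarded.  The classic baseline for this ill-posed
    problem.
``tikhonov``
    Ridge solution ``(A.T A + lam I)^-1 A.T C``.
``tv`` / ``wa_tv``
    R(G) = sum over time-frames of the (weighted) isotropic total
    variation of the spatial residue map, minimized by an iterative
    shrinkage-thresholding (proximal-gradient) scheme: a gradient step on
    the data term with step 1/L, followed by a weighted-TV proximal step
    solved with Chambolle-type dual projected-gradient iterations.

The weighted-adaptive variant (``wa_tv``) uses Perona-Malik-type weights

    w = 1 / (1 + (||grad G|| / delta)^2)

recomputed from the current iterate every outer iteration, so strong local
gradients (edges) are regularized less and fine structure survives the
denoising.  The scale factor delta controls how sensitive the weights are
to local intensity changes; with delta -> inf the method degenerates to
plain TV.  The exact weight formula and iteration internals of the method
this package models are reconstructions (the available description states
only their qualitative behaviour); docs/methods.md spells out every choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.linalg import svd as _dense_svd

from .kinetics import ConvolutionSystem, lipschitz_bound

METHODS = ("tsvd", "tikhonov", "tv", "wa_tv")

_DESCENT_SLACK = 1e-10

#: relative objective increase beyond which a stalled iteration counts as
#: genuine divergence rather than inexact-prox noise at the numerical floor
_DIVERGENCE_TOL = 1e-3

#: fraction of the iterate's max gradient magnitude used for the default
#: WA-TV scale factor delta (see docs/methods.md for the calibration story)
_DELTA_FRACTION = 0.5


class SolverFailure(RuntimeError):
    """Raised when an iterative solve diverges (objective increases)."""


@dataclass
class SolverConfig:
    """Configuration of one deconvolution run.

    Parameters
    ----------
    method : {"tsvd", "tikhonov", "tv", "wa_tv"}
    lam : float, optional
        Regularization weight.  ``None`` selects the default:
        ``0.6 * sigma_noise * ||A||_2`` for tv / wa_tv (with sigma_noise
        estimated from the data unless ``noise_sigma`` is given) and
        ``(0.1 * ||A||_2)**2`` for tikhonov.
    delta : float, optional
        WA-TV weight scale.  ``None`` re-derives it every outer iteration
        as half the maximum aggregated gradient magnitude of the current
        iterate, so the scale tracks the growing estimate.
    max_iter, tol :
        Outer-iteration budget and relative objective-change stopping
        threshold of the shrinkage-thresholding loop.
    nonnegativity : bool
        Project the residue onto G >= 0 (residues are physically
        nonnegative).  Direct methods clip their linear solution.
    tsvd_threshold : float
        Singular-value cutoff as a fraction of sigma_max.
    inner_prox_iters : int
        Dual projected-gradient iterations per TV proximal step.
    noise_sigma : float, optional
        Known noise SD (HU) used by the automatic lambda rule.
    weight_smoothing : float
        Optional Gaussian SD (voxels) applied to the iterate *only* when
        computing the adaptive weight field and its scale delta.  The
        temporal RMS aggregation of the edge detector already suppresses
        its noise response, so the default is 0 (off); a light smoothing
        trades edge localization for extra detector robustness.
    freeze_weights : bool
        Ablation flag: compute the WA-TV weights once and keep them fixed.
    seed : int, optional
        Reserved; the solvers here are deterministic.
    """

    method: str = "wa_tv"
    lam: Optional[float] = None
    delta: Optional[float] = None
    max_iter: int = 200
    tol: float = 1e-6
    nonnegativity: bool = True
    tsvd_threshold: float = 0.1
    inner_prox_iters: int = 20
    noise_sigma: Optional[float] = None
    weight_smoothing: float = 0.0
    freeze_weights: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.lam is not None and self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.delta is not None and self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.tsvd_threshold < 0 or self.tol < 0:
            raise ValueError("thresholds must be >= 0")
        if self.max_iter < 1 or self.inner_prox_iters < 1:
            raise ValueError("iteration counts must be >= 1")


@dataclass
class SolveResult:
    """Residue estimate plus the solver's convergence record."""

    G_hat: np.ndarray
    objective_trace: List[float]
    fidelity_trace: List[float] = field(default_factory=list)
    prior_trace: List[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def soft_threshold(x: np.ndarray, theta: float) -> np.ndarray:
    """Shrinkage operator ``sign(x) * max(|x| - theta, 0)``, elementwise."""
    if theta < 0:
        raise ValueError(f"threshold must be >= 0, got {theta}")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - theta, 0.0)


def _grad_axes(u: np.ndarray, axes: Tuple[int, ...]) -> np.ndarray:
    """Forward differences with Neumann boundary along ``axes``, stacked on axis 0."""
    comps = []
    for ax in axes:
        d = np.zeros_like(u)
        sl_lo = [slice(None)] * u.ndim
        sl_hi = [slice(None)] * u.ndim
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        d[tuple(sl_lo)] = u[tuple(sl_hi)] - u[tuple(sl_lo)]
        comps.append(d)
    return np.stack(comps)


def _div_axes(p: np.ndarray, axes: Tuple[int, ...]) -> np.ndarray:
    """Negative adjoint of :func:`_grad_axes`: <grad u, p> = -<u, div p>."""
    out = np.zeros(p.shape[1:])
    for k, ax in enumerate(axes):
        pk = p[k]
        term = np.zeros_like(pk)
        sl_int = [slice(None)] * pk.ndim
        sl_int[ax] = slice(None, -1)
        term[tuple(sl_int)] = pk[tuple(sl_int)]
        sl_hi = [slice(None)] * pk.ndim
        sl_hi[ax] = slice(1, None)
        sl_lo = [slice(None)] * pk.ndim
        sl_lo[ax] = slice(None, -1)
        term[tuple(sl_hi)] -= pk[tuple(sl_lo)]
        out += term
    return out


def spatial_gradient(u: np.ndarray) -> np.ndarray:
    """Forward-difference gradient of a spatial field, all axes, Neumann boundary.

    Returns an array of shape ``(ndim, *u.shape)``; the last difference
    along each axis is zero, so constant fields map to zero exactly.
    """
    u = np.asarray(u, dtype=float)
    return _grad_axes(u, tuple(range(u.ndim)))


def divergence(p: np.ndarray) -> np.ndarray:
    """Discrete divergence, the negative adjoint of :func:`spatial_gradient`."""
    p = np.asarray(p, dtype=float)
    return _div_axes(p, tuple(range(p.ndim - 1)))


def _grad_norm(g: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum(g * g, axis=0))


def wa_weights(field_: np.ndarray, delta: float) -> np.ndarray:
    """Adaptive per-voxel TV weights ``w = 1 / (1 + (||grad||/delta)^2)``.

    Weights lie in (0, 1], equal 1 on constant fields, and decay where the
    local gradient magnitude exceeds the scale factor delta (w = 0.5 at
    ``||grad|| = delta``), so edges are regularized less.
    """
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    mag = _grad_norm(spatial_gradient(field_))
    return 1.0 / (1.0 + (mag / delta) ** 2)


def wa_tv_value(frame: np.ndarray, weights: Optional[np.ndarray] = None) -> float:
    """Weighted isotropic total variation ``sum_v w_v ||grad frame(v)||``."""
    frame = np.asarray(frame, dtype=float)
    mag = _grad_norm(spatial_gradient(frame))
    if weights is None:
        return float(np.sum(mag))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != frame.shape:
        raise ValueError(f"weights shape {weights.shape} != frame shape {frame.shape}")
    return float(np.sum(weights * mag))


# ---------------------------------------------------------------------------
# Weighted-TV proximal operator (Chambolle-type dual projected gradient)
# ---------------------------------------------------------------------------


def _batched_tv_prox(
    frames: np.ndarray,
    alpha: np.ndarray,
    n_iter: int,
    p: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Prox of ``u -> sum_v alpha_v ||grad u(v)||`` for a stack of frames.

    ``frames`` has shape (F, *spatial); the first axis is a batch, spatial
    differences act on the remaining axes.  ``alpha`` broadcasts against
    ``frames``.  Returns the proximal point and the final dual variable
    (for warm starts).  Dual update: ``p <- Pi_{||p_v|| <= alpha_v}(p + tau
    grad(f + div p))`` with tau = 1/(4 d) for d active spatial axes.
    """
    axes = tuple(ax for ax in range(1, frames.ndim) if frames.shape[ax] > 1)
    if not axes:
        return frames.copy(), np.zeros((0,) + frames.shape)
    tau = 1.0 / (4.0 * len(axes))
    if p is None:
        p = np.zeros((len(axes),) + frames.shape)
    alpha = np.broadcast_to(alpha, frames.shape)
    for _ in range(n_iter):
        u = frames + _div_axes(p, axes)
        g = _grad_axes(u, axes)
        p = p + tau * g
        norm = _grad_norm(p)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(norm > alpha, np.where(norm > 0, alpha / norm, 0.0), 1.0)
        p = p * scale
    return frames + _div_axes(p, axes), p


def tv_prox(
    frame: np.ndarray,
    weights: Optional[np.ndarray] = None,
    theta: float = 0.0,
    inner_iters: int = 20,
) -> np.ndarray:
    """Approximate ``argmin_u 0.5||u - frame||^2 + theta * sum w ||grad u||``.

    Computed by a fixed number of dual projected-gradient iterations;
    ``theta = 0`` returns the frame unchanged, and for large theta the
    output approaches the frame's mean (the TV-ball limit).
    """
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    frame = np.asarray(frame, dtype=float)
    if theta == 0:
        return frame.copy()
    w = np.ones_like(frame) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != frame.shape:
        raise ValueError("weights and frame are not conformable")
    u, _ = _batched_tv_prox(frame[None], (theta * w)[None], inner_iters)
    return u[0]


# ---------------------------------------------------------------------------
# Noise / default-parameter helpers
# ---------------------------------------------------------------------------


def _weight_field(frames: np.ndarray, smoothing: float) -> np.ndarray:
    """Lightly smoothed copy of the frames used for the adaptive edge detector."""
    if smoothing <= 0:
        return frames
    from scipy.ndimage import gaussian_filter

    sigma = [0.0] + [smoothing if n > 1 else 0.0 for n in frames.shape[1:]]
    return gaussian_filter(frames, sigma=sigma, mode="nearest")


def estimate_noise_sigma(C: np.ndarray) -> float:
    """Robust noise-SD estimate from temporal second differences (MAD-based).

    For i.i.d. noise the second difference has variance ``6 sigma^2``; the
    median absolute deviation makes the estimate insensitive to the smooth
    enhancement signal.
    """
    C = np.asarray(C, dtype=float)
    d2 = C[..., 2:] - 2.0 * C[..., 1:-1] + C[..., :-2]
    mad = np.median(np.abs(d2 - np.median(d2)))
    return float(1.4826 * mad / np.sqrt(6.0))


def default_lambda(method: str, sys: ConvolutionSystem, sigma_noise: float) -> float:
    """Default regularization weight for each method (engineering rule)."""
    sigma_max = np.sqrt(lipschitz_bound(sys))
    if method == "tikhonov":
        return float((0.1 * sigma_max) ** 2)
    return float(0.6 * sigma_noise * sigma_max)


# ---------------------------------------------------------------------------
# Direct solvers
# ---------------------------------------------------------------------------


def _solve_tsvd(Cf: np.ndarray, sys: ConvolutionSystem, cfg: SolverConfig) -> np.ndarray:
    U, s, Vt = _dense_svd(sys.A)
    if s[0] == 0:
        return np.zeros_like(Cf)
    # zero singular values below the cutoff; exact zeros are always dropped
    cut = max(cfg.tsvd_threshold * s[0], s[0] * 1e-13)
    keep = s > cut
    inv = np.zeros_like(s)
    inv[keep] = 1.0 / s[keep]
    pinv = (Vt.T * inv) @ U.T
    return Cf @ pinv.T


def _solve_tikhonov(Cf: np.ndarray, sys: ConvolutionSystem, cfg: SolverConfig) -> np.ndarray:
    lam = cfg.lam
    if lam is None:
        lam = default_lambda("tikhonov", sys, 0.0)
    A = sys.A
    M = np.linalg.solve(A.T @ A + lam * np.eye(sys.n_frames), A.T)
    return Cf @ M.T


# ---------------------------------------------------------------------------
# Iterative shrinkage-thresholding (tv / wa_tv)
# ---------------------------------------------------------------------------


def _objective(
    Gf: np.ndarray,
    Cf: np.ndarray,
    A: np.ndarray,
    lam: float,
    frames_of,
    weights: Optional[np.ndarray],
) -> Tuple[float, float, float]:
    resid = Gf @ A.T - Cf
    fid = 0.5 * float(np.sum(resid * resid))
    prior = 0.0
    if lam > 0:
        fr = frames_of(Gf)
        axes = tuple(ax for ax in range(1, fr.ndim) if fr.shape[ax] > 1)
        mag = _grad_norm(_grad_axes(fr, axes)) if axes else np.zeros_like(fr)
        prior = float(np.sum(mag if weights is None else weights * mag))
    return fid + lam * prior, fid, prior


def _solve_ista(
    Cf: np.ndarray,
    sys: ConvolutionSystem,
    cfg: SolverConfig,
    spatial_shape: Tuple[int, ...],
) -> SolveResult:
    A = sys.A
    T = sys.n_frames
    n_vox = Cf.shape[0]

    def frames_of(Gf: np.ndarray) -> np.ndarray:
        # (V, T) -> (T, *spatial); the transpose copy is cheap at these sizes
        return np.ascontiguousarray(Gf.T).reshape((T,) + spatial_shape)

    def flat_of(fr: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(fr.reshape(T, n_vox).T)

    L = lipschitz_bound(sys)
    if L == 0:
        raise SolverFailure("degenerate system: A == 0")
    sigma = cfg.noise_sigma if cfg.noise_sigma is not None else estimate_noise_sigma(Cf)
    lam = cfg.lam if cfg.lam is not None else default_lambda(cfg.method, sys, sigma)

    adaptive = cfg.method == "wa_tv"
    delta = cfg.delta
    weights: Optional[np.ndarray] = None  # broadcastable to (T, *spatial)

    Gf = np.zeros_like(Cf)
    obj, fid, prior = _objective(Gf, Cf, A, lam, frames_of, weights)
    trace, fids, priors = [obj], [fid], [prior]
    converged = False
    n_done = 0
    p_warm: Optional[np.ndarray] = None

    for it in range(1, cfg.max_iter + 1):
        grad = (Gf @ A.T - Cf) @ A

        weights_prev = weights
        if adaptive and not (cfg.freeze_weights and weights is not None):
            # edge detector: per-frame gradient magnitudes of the (smoothed)
            # current iterate, aggregated over the time axis by a root mean
            # square.  Edges of the residue maps are spatially consistent
            # across frames while noise is not, so the temporal aggregation
            # suppresses the noise response of the detector by ~sqrt(T).
            # At iteration 1 the iterate is zero and the first
            # gradient-descent step stands in so the scale is never empty.
            probe = frames_of(Gf if it > 1 else Gf - grad / L)
            fr_cur = _weight_field(probe, cfg.weight_smoothing)
            axes = tuple(ax for ax in range(1, fr_cur.ndim) if fr_cur.shape[ax] > 1)
            if axes:
                mag2 = np.sum(_grad_axes(fr_cur, axes) ** 2, axis=0)
                mag = np.sqrt(np.mean(mag2, axis=0))  # (spatial,) RMS over frames
                # background subtraction: the median magnitude is a robust
                # noise floor; gradients at that level are not edges, and
                # removing the floor pins the weights of flat regions at
                # exactly 1 so noise suppression there never weakens
                mag = np.maximum(mag - np.median(mag), 0.0)
                if cfg.delta is None:
                    # scale tracks the iterate: delta is a fixed fraction of
                    # the maximum aggregated gradient magnitude
                    gmax = float(mag.max())
                    delta = _DELTA_FRACTION * gmax if gmax > 0 else 1.0
                weights = (1.0 / (1.0 + (mag / delta) ** 2))[None]

        # monotone guard.  ISTA descends for the objective whose weights it
        # used, provided the prox is accurate enough; recomputing weights can
        # raise the *recorded* value and the warm-started prox is inexact.
        # On an increase: fall back to the previous weights, then to a
        # high-accuracy prox (fresh dual, 10x inner iterations), then halve
        # the step.
        n_in = cfg.inner_prox_iters
        attempts = [(weights, 1.0 / L, n_in, True)]
        if adaptive and weights_prev is not None and weights_prev is not weights:
            attempts.append((weights_prev, 1.0 / L, n_in, True))
        base_w = attempts[-1][0]
        attempts += [
            (base_w, 1.0 / L, 10 * n_in, False),
            (base_w, 0.5 / L, 10 * n_in, False),
            (base_w, 0.25 / L, 40 * n_in, False),
        ]
        accepted = False
        for w_try, step, iters, warm in attempts:
            Z = frames_of(Gf - step * grad)
            if lam > 0:
                alpha = lam * step if w_try is None else lam * step * w_try
                U, p_new = _batched_tv_prox(Z, alpha, iters, p_warm if warm else None)
            else:
                U, p_new = Z, p_warm
            if cfg.nonnegativity:
                U = np.maximum(U, 0.0)
            G_new = flat_of(U)
            obj_new, fid_new, prior_new = _objective(G_new, Cf, A, lam, frames_of, w_try)
            if obj_new <= trace[-1] + _DESCENT_SLACK * max(1.0, abs(trace[-1])):
                accepted = True
                weights = w_try
                break
        if not accepted:
            rel_increase = (obj_new - trace[-1]) / max(abs(trace[-1]), 1e-30)
            if rel_increase > _DIVERGENCE_TOL:
                raise SolverFailure(
                    f"objective increased by {rel_increase:.3g} (relative) at iteration {it}"
                )
            # the remaining increase is inexact-prox noise at the numerical
            # floor, not divergence: stop and keep the previous iterate
            converged = True
            break
        Gf = G_new
        p_warm = p_new
        n_done = it
        rel_change = abs(trace[-1] - obj_new) / max(abs(trace[-1]), 1e-30)
        trace.append(obj_new)
        fids.append(fid_new)
        priors.append(prior_new)
        if rel_change <= cfg.tol:
            converged = True
            break

    return SolveResult(
        G_hat=frames_of(Gf).transpose(*(range(1, len(spatial_shape) + 1)), 0),
        objective_trace=trace,
        fidelity_trace=fids,
        prior_trace=priors,
        n_iter=n_done,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Entry point
# ---------------------------------------------------------------------------


def solve(series: np.ndarray, sys: ConvolutionSystem, cfg: SolverConfig) -> SolveResult:
    """Deconvolve tissue curves into a residue estimate.

    ``series`` has shape ``(..., T)`` with leading spatial axes (the TV
    methods regularize each time-frame across those axes).  Returns a
    :class:`SolveResult` whose ``G_hat`` matches the input shape.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] != sys.n_frames:
        raise ValueError(
            f"series has {series.shape[-1]} frames but the system expects {sys.n_frames}"
        )
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")

    spatial_shape = series.shape[:-1] or (1,)
    Cf = series.reshape(-1, sys.n_frames)

    if not series.any():  # degenerate all-zero input
        return SolveResult(
            G_hat=np.zeros_like(series),
            objective_trace=[0.0],
            fidelity_trace=[0.0],
            prior_trace=[0.0],
            n_iter=0,
            converged=True,
        )

    if cfg.method in ("tv", "wa_tv"):
        res = _solve_ista(Cf, sys, cfg, spatial_shape)
        res.G_hat = res.G_hat.reshape(series.shape)
        return res

    Gf = _solve_tsvd(Cf, sys, cfg) if cfg.method == "tsvd" else _solve_tikhonov(Cf, sys, cfg)
    if cfg.nonnegativity:
        Gf = np.maximum(Gf, 0.0)
    resid = Gf @ sys.A.T - Cf
    fid = 0.5 * float(np.sum(resid * resid))
    return SolveResult(
        G_hat=Gf.reshape(series.shape),
        objective_trace=[fid],
        fidelity_trace=[fid],
        prior_trace=[0.0],
        n_iter=0,
        converged=True,
    )
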