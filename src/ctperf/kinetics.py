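"""Tracer-kinetic convolution model for dynamic contrast-enhanced CT.

Indicator-dilution theory models the tissue enhancement curve of every voxel
as the convolution of the arterial input function (AIF) ``B`` with the
voxel's flow-scaled residue function ``G``:

    C(t) = integral_0^t B(t - s) G(s) ds

On the acquisition grid this becomes the causal discrete sum

    c_i = dt * sum_{j <= i} b_{i-j} g_j,    i = 0 .. T-1

i.e. ``C = A @ G`` with ``A`` a lower-triangular Toeplitz matrix built from
the AIF samples.  The quadrature factor ``dt`` lives inside ``A`` so that
``G`` keeps physical units of a flow-scaled residue (1/s on an HU-normalised
concentration scale).  The matrix is delay-sensitive: a residue shifted by
whole frames produces an identically shifted tissue curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz


@dataclass(frozen=True)
class ConvolutionSystem:
    """The discrete convolution operator ``C = A @ G`` for one AIF.

    Attributes
    ----------
    A : (T, T) ndarray
        Lower-triangular Toeplitz matrix with ``A[i, j] = dt * B[i - j]``
        for ``i >= j`` and zero above the diagonal.
    dt : float
        Frame spacing in seconds.
    B : (T,) ndarray
        AIF samples the matrix was built from.
    """

    A: np.ndarray
    dt: float
    B: np.ndarray = field(repr=False)

    @property
    def n_frames(self) -> int:
        return self.A.shape[0]


def build_conv_matrix(B: np.ndarray, dt: float) -> ConvolutionSystem:
    """Build the lower-triangular Toeplitz convolution system from AIF samples.

    Parameters
    ----------
    B : array-like, shape (T,)
        Arterial input function sampled on the acquisition grid, T >= 2.
    dt : float
        Frame spacing in seconds, > 0.
    """
    B = np.asarray(B, dtype=float).ravel()
    if B.size < 2:
        raise ValueError(f"AIF must have at least 2 samples, got {B.size}")
    if not np.all(np.isfinite(B)):
        raise ValueError("AIF contains non-finite samples")
    if not (np.isfinite(dt) and dt > 0):
        raise ValueError(f"dt must be positive and finite, got {dt}")
    A = toeplitz(dt * B, np.zeros_like(B))
    return ConvolutionSystem(A=A, dt=float(dt), B=B)


def forward(sys: ConvolutionSystem, G: np.ndarray) -> np.ndarray:
    """Apply the convolution operator to residue vectors.

    ``G`` may be a single time vector ``(T,)`` or any stack ``(..., T)`` of
    per-voxel residues; the operator acts independently along the last axis.
    """
    G = np.asarray(G, dtype=float)
    T = sys.n_frames
    if G.shape[-1] != T:
        raise ValueError(
            f"residue length {G.shape[-1]} does not match system frames {T}"
        )
    return G @ sys.A.T


def adjoint(sys: ConvolutionSystem, C: np.ndarray) -> np.ndarray:
    """Apply the transpose operator ``A.T`` along the last axis (solver gradient)."""
    C = np.asarray(C, dtype=float)
    if C.shape[-1] != sys.n_frames:
        raise ValueError("frame-count mismatch")
    return C @ sys.A


def lipschitz_bound(
    sys: ConvolutionSystem, tol: float = 1e-13, max_iter: int = 2000
) -> float:
    """Upper bound on the largest eigenvalue of ``A.T A`` by power iteration.

    Returns ``L >= sigma_max(A)**2``, the Lipschitz constant of the gradient
    of the data-fidelity term ``0.5 * ||A g - c||^2``, used as the inverse
    step size of the iterative shrinkage-thresholding loop.  The Rayleigh
    quotient converges to ``sigma_max**2`` from below; a relative safety
    factor of 1e-8 makes the returned value an upper bound while keeping the
    relative error against a dense SVD well under 1e-6.
    """
    A = sys.A
    M = A.T @ A
    rng = np.random.default_rng(0)
    v = rng.standard_normal(A.shape[0])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_iter):
        w = M @ v
        nw = np.linalg.norm(w)
        if nw == 0.0:  # A == 0
            return 0.0
        v_new = w / nw
        lam_new = float(v_new @ (M @ v_new))
        if abs(lam_new - lam) <= tol * max(lam_new, 1.0):
            lam = lam_new
            break
        lam, v = lam_new, v_new
    return lam * (1.0 + 1e-8)
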