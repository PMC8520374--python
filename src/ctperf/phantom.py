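"""Digital brain-perfusion phantom with analytically known ground truth.

Generates synthetic dynamic contrast-enhanced CT acquisitions: a
gamma-variate arterial input function, per-voxel flow-scaled residue
functions (exponential or box family), and tissue curves produced by the
discrete convolution model of :mod:`ctperf.kinetics`.  The phantom brain is
a two-class (gray/white) ellipse, mirror-symmetric about the mid-sagittal
plane, carrying two ellipsoidal lesions in one hemisphere:

* a core-infarct area (CIA) with severely reduced flow, and
* an ischemic penumbra (PI) with moderately reduced flow and prolonged
  transit/arrival times.

Lesion physiology is parameterized as percent-of-contralateral severities
(rCBF, rMTT, rTTP); the defaults are the pre-treatment region means of the
clinical cohort the package models (rCBF 43.17 / 18.37, rMTT 124.83 /
183.17, rTTP 122.57 / 150.74 for CIA / PI).  rCBV follows from the
central-volume identity, rCBV = rCBF * rMTT / 100: the four cohort means
are jointly inconsistent with MTT = 60*CBV/CBF, and deriving rCBV (rather
than rMTT) preserves the cohort's CIA-vs-PI ordering of all four
parameters.

Ground-truth maps are *grid-realized*: they are the values the exact
estimators return on the acquisition grid (residue peak, trapezoid area
ratio of the noiseless curves, central-volume MTT, discrete time-to-peak).
Lesion residue parameters are calibrated against the grid so the realized
rCBF/rCBV/rMTT severities match the requested percentages essentially
exactly; realized rTTP is quantized by the frame spacing.  As dt -> 0 the
grid-realized maps converge to the nominal tissue-class values (first
order in dt).  See docs/methods.md for the full rationale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from . import perfusion
from .kinetics import ConvolutionSystem, build_conv_matrix, forward
from .perfusion import (
    LABEL_BACKGROUND,
    LABEL_CORE,
    LABEL_NORMAL,
    LABEL_PENUMBRA,
    ConversionConstants,
)

RESIDUE_SHAPES = ("exponential", "box")


# ---------------------------------------------------------------------------
# Time axis and arterial input
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeGrid:
    """Discrete acquisition time axis: frame k is at ``t0 + k * dt``.

    Defaults follow a 20-cycle CTP protocol with 2 s per cycle.
    """

    n_frames: int = 20
    dt: float = 2.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 4:
            raise ValueError(f"need at least 4 frames, got {self.n_frames}")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.isfinite(self.t0):
            raise ValueError("t0 must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_frames)

    @property
    def duration(self) -> float:
        return self.dt * (self.n_frames - 1)

    def refined(self, factor: int) -> "TimeGrid":
        """Same window sampled ``factor`` times more finely (oracle use)."""
        return TimeGrid(
            n_frames=(self.n_frames - 1) * factor + 1,
            dt=self.dt / factor,
            t0=self.t0,
        )


@dataclass(frozen=True)
class AIFParams:
    """Gamma-variate bolus model for the arterial input function.

    ``B(t) = amplitude * (t - onset)**alpha * exp(-(t - onset) / beta)`` for
    ``t > onset``, zero before arrival.  The continuous-time peak sits at
    ``onset + alpha * beta``.  Defaults give a bolus arriving at 4 s and
    peaking near 300 HU at 8.5 s, a typical first-pass arterial curve.
    """

    amplitude: float = 66.0
    onset: float = 4.0
    alpha: float = 3.0
    beta: float = 1.5

    def __post_init__(self) -> None:
        vals = (self.amplitude, self.onset, self.alpha, self.beta)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"AIF parameters must be finite, got {vals}")
        if self.amplitude <= 0 or self.alpha <= 0 or self.beta <= 0 or self.onset < 0:
            raise ValueError(f"invalid AIF parameters {vals}")

    @property
    def peak_time(self) -> float:
        return self.onset + self.alpha * self.beta


@dataclass(frozen=True)
class AIFCurve:
    """Sampled arterial input function on a time grid."""

    values: np.ndarray
    grid: TimeGrid


def make_aif(params: AIFParams, grid: TimeGrid) -> AIFCurve:
    """Sample the gamma-variate AIF on the acquisition grid."""
    s = grid.times - params.onset
    with np.errstate(invalid="ignore"):
        vals = np.where(
            s > 0,
            params.amplitude * np.power(np.clip(s, 0, None), params.alpha) * np.exp(-np.clip(s, 0, None) / params.beta),
            0.0,
        )
    return AIFCurve(values=vals, grid=grid)


def make_residue(
    shape: str,
    cbf: float,
    mtt: float,
    delay: float,
    grid: TimeGrid,
) -> np.ndarray:
    """Flow-scaled residue function sampled on the acquisition grid.

    ``cbf`` is the flow amplitude in model units: the peak of G.
    Exponential family: ``G(t) = cbf * exp(-(t - delay)/mtt)`` for
    ``t >= delay``; box family: ``G(t) = cbf`` on ``[delay, delay + mtt)``.
    Both integrate (continuously) to ``cbf * mtt``.
    """
    if shape not in RESIDUE_SHAPES:
        raise ValueError(f"unknown residue shape {shape!r}")
    if cbf <= 0 or mtt <= 0 or delay < 0:
        raise ValueError(f"need cbf > 0, mtt > 0, delay >= 0; got {cbf}, {mtt}, {delay}")
    if mtt < grid.dt:
        warnings.warn(
            f"residue MTT {mtt:.3g}s is shorter than the frame spacing "
            f"{grid.dt:.3g}s: the residue is under-resolved",
            stacklevel=2,
        )
    t = grid.times - grid.t0  # residue clock starts at acquisition start
    if shape == "exponential":
        s = t - delay
        return np.where(s >= 0, cbf * np.exp(-np.clip(s, 0, None) / mtt), 0.0)
    return np.where((t >= delay) & (t < delay + mtt), float(cbf), 0.0)


def residue_area(G: np.ndarray, grid: TimeGrid) -> float:
    """Trapezoid-rule integral of a sampled residue (module's stated rule)."""
    return float(np.trapezoid(G, dx=grid.dt))


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueClass:
    """Homogeneous tissue compartment with nominal perfusion parameters."""

    name: str
    cbf: float  # mL/100g/min
    cbv: float  # mL/100g
    delay: float = 0.0  # bolus arrival delay, s
    residue_shape: str = "exponential"

    def __post_init__(self) -> None:
        if self.cbf <= 0 or self.cbv <= 0 or self.delay < 0:
            raise ValueError(f"invalid tissue class {self}")
        if self.residue_shape not in RESIDUE_SHAPES:
            raise ValueError(f"unknown residue shape {self.residue_shape!r}")

    @property
    def mtt(self) -> float:
        """Nominal mean transit time in seconds (central-volume identity)."""
        return 60.0 * self.cbv / self.cbf


@dataclass(frozen=True)
class LesionSpec:
    """Ellipsoidal lesion with percent-of-contralateral severities.

    ``kind`` is ``"core"`` (CIA) or ``"penumbra"`` (PI).  Severities apply
    multiplicatively to whatever tissue class underlies each lesion voxel.
    ``rcbv`` is derived from the central-volume identity.
    """

    kind: str
    center: Tuple[float, float, float]
    radii: Tuple[float, float, float]
    rcbf: float
    rmtt: float
    rttp: float

    def __post_init__(self) -> None:
        if self.kind not in ("core", "penumbra"):
            raise ValueError(f"lesion kind must be 'core' or 'penumbra', got {self.kind!r}")
        for sev in (self.rcbf, self.rmtt, self.rttp):
            if not (0 < sev <= 500):
                raise ValueError(f"severities must lie in (0, 500], got {sev}")
        if len(self.center) != 3 or len(self.radii) != 3:
            raise ValueError("lesion center and radii must be 3-tuples")
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"lesion radii must be positive, got {self.radii}")

    @property
    def rcbv(self) -> float:
        """Derived severity: rCBV = rCBF * rMTT / 100 (central-volume identity)."""
        return self.rcbf * self.rmtt / 100.0

    @property
    def label(self) -> int:
        return LABEL_CORE if self.kind == "core" else LABEL_PENUMBRA

    def severities(self) -> dict:
        return {"rcbf": self.rcbf, "rcbv": self.rcbv, "rmtt": self.rmtt, "rttp": self.rttp}


def _default_lesions() -> List[LesionSpec]:
    # Pre-treatment cohort means used as default severities.
    return [
        LesionSpec(
            kind="core",
            center=(45.0, 38.0, 0.0),
            radii=(5.0, 5.0, 1.0),
            rcbf=43.17,
            rmtt=124.83,
            rttp=122.57,
        ),
        LesionSpec(
            kind="penumbra",
            center=(43.0, 22.0, 0.0),
            radii=(6.0, 7.0, 1.0),
            rcbf=18.37,
            rmtt=183.17,
            rttp=150.74,
        ),
    ]


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of a synthetic perfusion acquisition.

    The default is a 64x64 single-slice brain scanned for 20 frames at
    2 s spacing, with gray/white matter at textbook perfusion values and
    CIA/PI lesions in the right hemisphere at the default severities.
    ``nx`` must be even so the mid-sagittal mirror map is voxel-exact.
    """

    shape: Tuple[int, int, int] = (64, 64, 1)
    time: TimeGrid = field(default_factory=TimeGrid)
    aif: AIFParams = field(default_factory=AIFParams)
    gray: TissueClass = field(default_factory=lambda: TissueClass("gray", cbf=60.0, cbv=4.0))
    white: TissueClass = field(default_factory=lambda: TissueClass("white", cbf=25.0, cbv=2.5))
    brain_radii: Optional[Tuple[float, float, float]] = None
    white_radii: Optional[Tuple[float, float, float]] = None
    affected_side: str = "right"
    lesions: Tuple[LesionSpec, ...] = field(default_factory=lambda: tuple(_default_lesions()))
    noise_sigma: float = 2.0  # HU
    seed: int = 0
    snap_delays: bool = True
    voxel_size_mm: float = 3.0
    consts: ConversionConstants = field(default_factory=ConversionConstants)

    def __post_init__(self) -> None:
        nx, ny, nz = self.shape
        if nx < 4 or ny < 1 or nz < 1:
            raise ValueError(f"grid shape too small: {self.shape}")
        if nx % 2 != 0:
            raise ValueError(f"nx must be even for a voxel-exact mirror, got {nx}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.affected_side not in ("left", "right"):
            raise ValueError(f"affected_side must be 'left' or 'right', got {self.affected_side!r}")
        kinds = [l.kind for l in self.lesions]
        if len(kinds) != len(set(kinds)):
            raise ValueError("at most one lesion of each kind")

    # geometry defaults scale with the grid --------------------------------
    def _brain_radii(self) -> Tuple[float, float, float]:
        if self.brain_radii is not None:
            return self.brain_radii
        nx, ny, nz = self.shape
        return (0.41 * nx, 0.46 * ny, np.inf if nz == 1 else 0.45 * nz)

    def _white_radii(self) -> Tuple[float, float, float]:
        if self.white_radii is not None:
            return self.white_radii
        nx, ny, nz = self.shape
        return (0.19 * nx, 0.22 * ny, np.inf if nz == 1 else 0.25 * nz)

    @property
    def center(self) -> Tuple[float, float, float]:
        nx, ny, nz = self.shape
        return ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _ellipsoid_mask(
    shape: Sequence[int],
    center: Sequence[float],
    radii: Sequence[float],
) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    q = np.zeros(tuple(shape))
    for ax in range(3):
        r = radii[ax]
        if np.isinf(r):
            continue
        q += ((idx[ax] - center[ax]) / r) ** 2
    return q <= 1.0


def _mirror(mask_or_vol: np.ndarray) -> np.ndarray:
    return mask_or_vol[::-1]


def region_geometry(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Build (labels, class_map) volumes; validates lesion placement.

    labels: 0 background, 1 normal, 2 penumbra, 3 core.
    class_map: 0 background, 1 gray, 2 white.
    """
    shape = spec.shape
    brain = _ellipsoid_mask(shape, spec.center, spec._brain_radii())
    white = _ellipsoid_mask(shape, spec.center, spec._white_radii()) & brain

    class_map = np.zeros(shape, dtype=np.int8)
    class_map[brain] = 1
    class_map[white] = 2

    labels = np.zeros(shape, dtype=np.int8)
    labels[brain] = LABEL_NORMAL

    affected = perfusion._affected_mask(shape, spec.affected_side)
    lesion_union = np.zeros(shape, dtype=bool)
    for les in spec.lesions:
        m = _ellipsoid_mask(shape, les.center, les.radii)
        if not m.any():
            raise ValueError(f"lesion {les.kind!r} covers no voxels")
        if not (m <= brain).all():
            raise ValueError(f"lesion {les.kind!r} extends outside the brain mask")
        if not (m <= affected).all():
            raise ValueError(f"lesion {les.kind!r} leaves the affected hemisphere")
        if (m & lesion_union).any():
            raise ValueError("core and penumbra lesions overlap")
        if (_mirror(m) & m).any():
            raise ValueError(f"lesion {les.kind!r} overlaps its own mirror image")
        lesion_union |= m
        labels[m] = les.label
    for les in spec.lesions:
        m = labels == les.label
        mirror_ok = labels[::-1][m] == LABEL_NORMAL
        if not mirror_ok.all():
            raise ValueError("the contralateral mirror of a lesion voxel is not normal tissue")
    return labels, class_map


# ---------------------------------------------------------------------------
# Grid calibration of lesion residues
# ---------------------------------------------------------------------------


def _effective_mtt(mtt: float, dt: float) -> float:
    """Rectangle-rule transit time of a grid-aligned sampled exponential.

    ``dt * sum_k exp(-k dt / mtt) = dt / (1 - exp(-dt/mtt))``: the value the
    acquisition grid realizes for the area/peak ratio of an exponential
    residue.  Tends to ``mtt`` (from above) as dt -> 0.
    """
    return dt / (-math.expm1(-dt / mtt))


def _invert_effective_mtt(target: float, dt: float) -> float:
    """Solve ``_effective_mtt(m, dt) == target`` for m (monotone in m)."""
    if target <= dt * (1 + 1e-12):
        raise ValueError(
            f"requested transit-time severity is unreachable on this grid: "
            f"effective MTT {target:.4g}s <= frame spacing {dt:.4g}s"
        )
    lo, hi = 1e-6 * dt, 1e6 * dt
    return float(brentq(lambda m: _effective_mtt(m, dt) - target, lo, hi, xtol=1e-12, rtol=1e-14))


def _peak_scale(tissue: TissueClass, consts: ConversionConstants) -> float:
    """Residue peak (model units, 1/s) for a tissue class: CBF*rho/(6000*k)."""
    return tissue.cbf * consts.rho / (6000.0 * consts.k)


def _discrete_ttp(C: np.ndarray, grid: TimeGrid) -> float:
    return grid.t0 + grid.dt * int(np.argmax(C))


def _calibrate_delay(
    shape: str,
    peak: float,
    mtt: float,
    sys: ConvolutionSystem,
    grid: TimeGrid,
    ttp_normal: float,
    rttp: float,
    snap_delays: bool,
) -> float:
    """Arrival delay realizing the requested discrete time-to-peak ratio."""
    G0 = make_residue(shape, peak, mtt, 0.0, grid)
    ttp0 = _discrete_ttp(forward(sys, G0), grid)
    target_ttp = (rttp / 100.0) * ttp_normal
    delay = max(0.0, target_ttp - ttp0)
    if snap_delays:
        delay = round(delay / grid.dt) * grid.dt
    # keep the shifted peak inside the acquisition window
    max_delay = grid.duration - (ttp0 - grid.t0)
    return min(delay, max(0.0, math.floor(max_delay / grid.dt) * grid.dt))


def _lesion_residue_params(
    les: LesionSpec,
    tissue: TissueClass,
    sys: ConvolutionSystem,
    grid: TimeGrid,
    consts: ConversionConstants,
    ttp_normal: float,
    normal_curve_area: float,
    snap_delays: bool,
) -> Tuple[float, float, float]:
    """(peak, mtt, delay) of the lesion residue over one underlying class.

    The peak scales by rCBF/100, which makes the realized rCBF severity
    exact (arrival delays are frame-aligned by default, so the sampled
    residue maximum is the peak itself).  For exponential residues the
    lesion MTT is then calibrated *numerically against the grid*: it is the
    root of

        area(C_lesion(mtt, delay)) = (rCBV / 100) * area(C_normal)

    with areas taken by the same trapezoid rule the CBV estimator uses, so
    the realized rCBV (and hence rMTT = 100*rCBV/rCBF) severities are exact
    on the acquisition grid, including its quadrature and window-truncation
    effects.  A closed-form rectangle-sum estimate seeds the root bracket.
    The arrival delay realizes the requested discrete time-to-peak ratio,
    snapped to the frame grid by default; box residues use nominal scaling.
    """
    peak = (les.rcbf / 100.0) * _peak_scale(tissue, consts)
    if tissue.residue_shape != "exponential":
        mtt = (les.rmtt / 100.0) * tissue.mtt
        delay = _calibrate_delay(
            tissue.residue_shape, peak, mtt, sys, grid, ttp_normal, les.rttp, snap_delays
        )
        return peak, mtt, delay

    # seed: grid-realized transit time ignoring window truncation
    target_eff = (les.rmtt / 100.0) * _effective_mtt(tissue.mtt, grid.dt)
    mtt = _invert_effective_mtt(target_eff, grid.dt)
    target_area = (les.rcbv / 100.0) * normal_curve_area

    def realized_area(m: float, delay: float) -> float:
        G = make_residue("exponential", peak, m, delay, grid)
        return float(np.trapezoid(forward(sys, G), dx=grid.dt))

    delay = 0.0
    for _ in range(4):  # alternate delay and area calibration to a fixed point
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # transient under-resolved brackets
            delay_new = _calibrate_delay(
                "exponential", peak, mtt, sys, grid, ttp_normal, les.rttp, snap_delays
            )
            f = lambda m: realized_area(m, delay_new) - target_area
            lo, hi = 1e-3 * grid.dt, 50.0 * grid.duration
            if f(lo) > 0 or f(hi) < 0:
                raise ValueError(
                    f"rMTT severity {les.rmtt} for lesion {les.kind!r} is unreachable "
                    f"on this acquisition grid"
                )
            mtt_new = float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))
        if delay_new == delay and abs(mtt_new - mtt) <= 1e-9 * mtt:
            mtt = mtt_new
            break
        mtt, delay = mtt_new, delay_new
    return peak, mtt, delay


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthMaps:
    """True parameter maps, residues and region labels of a phantom.

    Maps are grid-realized (see module docstring): CBF is the residue peak,
    CBV the trapezoid area ratio of the noiseless curves, MTT their
    central-volume quotient and TTP the discrete time of the curve maximum.
    MTT and TTP are NaN outside the brain mask.
    """

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    ttp: np.ndarray
    residue: np.ndarray  # (nx, ny, nz, T)
    labels: np.ndarray  # int8, 0 bg / 1 normal / 2 PI / 3 CIA

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > LABEL_BACKGROUND

    def as_perfusion_maps(self, consts: ConversionConstants) -> perfusion.PerfusionMaps:
        return perfusion.PerfusionMaps(
            cbf=self.cbf, cbv=self.cbv, mtt=self.mtt, ttp=self.ttp, consts=consts
        )


@dataclass
class PhantomData:
    """A built phantom: noiseless series, AIF, ground truth and geometry."""

    series: np.ndarray  # (nx, ny, nz, T), noiseless
    aif: AIFCurve
    truth: GroundTruthMaps
    spec: PhantomSpec
    system: ConvolutionSystem

    @property
    def brain_mask(self) -> np.ndarray:
        return self.truth.brain_mask


def build_phantom(spec: PhantomSpec) -> PhantomData:
    """Generate the noiseless acquisition and its ground truth.

    Deterministic: identical specs give bit-identical outputs (noise is a
    separate, seeded operation; see :func:`add_noise`).
    """
    grid = spec.time
    labels, class_map = region_geometry(spec)
    aif = make_aif(spec.aif, grid)
    sys = build_conv_matrix(aif.values, grid.dt)

    tissues = {1: spec.gray, 2: spec.white}
    nx, ny, nz = spec.shape
    T = grid.n_frames
    residue = np.zeros((nx, ny, nz, T))
    series = np.zeros((nx, ny, nz, T))

    # normal tissue (everything inside the brain, lesions overwritten below)
    ttp_by_class = {}
    area_by_class = {}
    for code, tissue in tissues.items():
        peak = _peak_scale(tissue, spec.consts)
        G = make_residue(tissue.residue_shape, peak, tissue.mtt, tissue.delay, grid)
        C = forward(sys, G)
        ttp_by_class[code] = _discrete_ttp(C, grid)
        area_by_class[code] = float(np.trapezoid(C, dx=grid.dt))
        mask = (class_map == code) & (labels == LABEL_NORMAL)
        residue[mask] = G
        series[mask] = C

    for les in spec.lesions:
        for code, tissue in tissues.items():
            mask = (labels == les.label) & (class_map == code)
            if not mask.any():
                continue
            peak, mtt, delay = _lesion_residue_params(
                les, tissue, sys, grid, spec.consts,
                ttp_by_class[code], area_by_class[code], spec.snap_delays,
            )
            G = make_residue(tissue.residue_shape, peak, mtt, delay, grid)
            residue[mask] = G
            series[mask] = forward(sys, G)

    brain = labels > LABEL_BACKGROUND
    cbf = perfusion.compute_cbf(residue, spec.consts)
    cbv = perfusion.compute_cbv(series, aif.values, grid.dt, spec.consts)
    mtt = perfusion.compute_mtt(cbf, cbv)
    ttp = perfusion.compute_ttp(series, grid.dt, grid.t0)
    for m in (mtt, ttp):
        m[~brain] = np.nan
    truth = GroundTruthMaps(cbf=cbf, cbv=cbv, mtt=mtt, ttp=ttp, residue=residue, labels=labels)
    return PhantomData(series=series, aif=aif, truth=truth, spec=spec, system=sys)


def add_noise(vol: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise of SD ``sigma`` HU, reproducibly.

    ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return vol
    rng = np.random.default_rng(seed)
    return vol + rng.normal(0.0, sigma, size=np.shape(vol))


def simulate_treatment_effect(spec: PhantomSpec, recovery_fraction: float) -> PhantomSpec:
    """Post-treatment spec: penumbra severities move linearly toward 100%.

    The core infarct is irreversibly damaged and is left unchanged,
    mirroring the clinical observation that reperfusion therapy normalizes
    penumbra perfusion but not the core.
    """
    if not 0.0 <= recovery_fraction <= 1.0:
        raise ValueError(f"recovery_fraction must be in [0, 1], got {recovery_fraction}")
    kinds = {l.kind for l in spec.lesions}
    if kinds != {"core", "penumbra"}:
        raise ValueError("treatment simulation needs both core and penumbra lesions")

    def moved(les: LesionSpec) -> LesionSpec:
        if les.kind != "penumbra":
            return les
        f = recovery_fraction
        return replace(
            les,
            rcbf=les.rcbf + f * (100.0 - les.rcbf),
            rmtt=les.rmtt + f * (100.0 - les.rmtt),
            rttp=les.rttp + f * (100.0 - les.rttp),
        )

    return replace(spec, lesions=tuple(moved(l) for l in spec.lesions))
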