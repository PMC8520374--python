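# Methods

This note documents the models, estimators and numerical choices behind
`ctperf`, in the spirit of a software methods appendix: what is computed,
under which assumptions, and where the design was genuinely open.

## Tracer-kinetic model

Dynamic contrast-enhanced CT measures, per voxel, a time–attenuation curve
C(t) (HU above baseline). Indicator-dilution theory relates it to the
arterial input function (AIF) B(t) and the voxel's flow-scaled residue
function G(t) = CBF' · R(t), where R(t) is the fraction of tracer still in
the voxel t seconds after an idealized instantaneous arterial bolus and
CBF' is flow in model units (1/s):

    C(t) = (B ⊛ G)(t) = ∫₀ᵗ B(t−s) G(s) ds.

On the acquisition grid (frame spacing dt, T frames) the model is realized
literally as a causal rectangle-rule sum, `c_i = dt Σ_{j≤i} b_{i−j} g_j`,
i.e. `C = A G` with A the lower-triangular Toeplitz matrix `A[i,j] =
dt·B[i−j]`. The operator is delay-sensitive: no block-circulant
(delay-insensitive) variant is provided. The quadrature factor dt lives in
A, so G keeps units of 1/s.

Consequence worth stating plainly: the rectangle rule is first-order
accurate, and residue functions have a jump at bolus arrival. At clinical
frame spacing (dt = 1–2 s) the discrete curve areas therefore differ from
their continuous-time counterparts by ≈ dt/(2·MTT) (13–25% for MTT 4 s).
This is a property of the model, not a bug, and it drives how ground truth
is defined for the phantom (below).

## Digital perfusion phantom

The phantom emulates a 20-frame, 2 s/frame acquisition of a single axial
slice (64×64 voxels by default; all sizes are configuration, not code).
Geometry: an elliptical "brain" of gray matter (CBF 60 mL/100g/min, CBV
4 mL/100g, hence MTT 4 s) with an inner white-matter ellipse (25, 2.5,
6 s), mirror-symmetric about the mid-sagittal plane x = (nx−1)/2 (nx must
be even so the mirror map is voxel-exact). Two disjoint ellipsoidal
lesions sit in one hemisphere: a core-infarct area (CIA) and a penumbra
(PI). Residues are exponential by default (box residues are supported);
the AIF is a gamma-variate `B(t) = a (t−t₀)^α e^{−(t−t₀)/β}` with α = 3,
β = 1.5 s, onset 4 s and amplitude chosen to peak near 300 HU — a typical
first-pass arterial curve. Gaussian noise (default SD 2 HU, seeded,
i.i.d.) models low-dose CT noise; there is no beam hardening, motion,
partial-volume or vascular anatomy.

Lesion physiology is parameterized as percent-of-contralateral severities
applied multiplicatively to the underlying tissue class. Defaults are the
pre-treatment cohort means of the clinical population the package models:

| region | rCBF | rMTT | rTTP | rCBV (derived) |
|--------|------|------|------|----------------|
| CIA    | 43.17 | 124.83 | 122.57 | 53.89 |
| PI     | 18.37 | 183.17 | 150.74 | 33.65 |

The four printed cohort means are jointly inconsistent with the
central-volume identity MTT = 60·CBV/CBF (they are independent cohort
statistics), so only three can be honoured. `ctperf` honours rCBF, rMTT
and rTTP and derives rCBV = rCBF·rMTT/100; this choice preserves the
cohort's CIA-vs-PI ordering of **all four** parameters (deriving rMTT
instead would invert the transit-time ordering). The derived rCBV values
are printed above.

### Grid-realized ground truth

Ground-truth maps are defined as the values the exact estimators return on
the acquisition grid: CBF is the sampled residue peak, CBV the trapezoid
area ratio of the noiseless curves, MTT their central-volume quotient, TTP
the discrete time of the noiseless curve maximum. With this definition the
central-volume identity holds exactly, the severity ratios are exact, a
noise-free reconstruction with the untruncated pseudo-inverse reproduces
the ground truth to machine precision, and the maps converge to the
nominal tissue-class values as dt → 0 (first order; verified by a fine-dt
test). Defining ground truth by the continuous-time nominals instead would
build the rectangle-rule quadrature bias (10–25%) into every recovery
test, punishing correct code for a property of the printed model.

To make severities exact **on the grid**, lesion residue parameters are
calibrated against it: the peak scales by rCBF/100 (exact because arrival
delays are snapped to whole frames); the lesion MTT is the root of
`area(C_lesion(mtt)) = (rCBV/100)·area(C_normal)` under the same trapezoid
rule the CBV estimator uses (a closed-form rectangle-sum inverse seeds the
bracket), which also absorbs window-truncation effects; the arrival delay
realizes the requested discrete time-to-peak ratio. Realized rTTP is
consequently quantized by the frame spacing — at dt = 2 s and a normal TTP
of ~10 s it can deviate from the requested percentage by up to
~dt/TTP·100 ≈ 20 percent-points in the worst case (typically well under
10); rCBF/rCBV/rMTT are exact to ≪1%. Treatment is simulated by moving the
penumbra severities linearly toward 100% while the core is untouched
(irreversible injury), matching the clinical contrast the package
reproduces.

What passing phantom tests do **not** show: robustness to non-Gaussian CT
noise, motion, AIF partial-volume error, midline asymmetry of real
anatomy, or realistic heterogeneous tissue texture.

## Deconvolution

All solvers minimize

    F(G) = ½ Σ_v ‖A g_v − c_v‖² + λ R(G)

- **TSVD**: pseudo-inverse with singular values below
  `tsvd_threshold·σ_max` discarded (default 0.1; exact zeros are always
  dropped).
- **Tikhonov**: `(AᵀA + λI)⁻¹AᵀC`, default λ = (0.1·σ_max)², symmetric
  with the TSVD cutoff.
- **TV / WA-TV**: R(G) = Σ_frames Σ_v w_v ‖∇G(v)‖ (isotropic, forward
  differences with Neumann boundary), w ≡ 1 for plain TV. Minimized by
  iterative shrinkage-thresholding: a gradient step with step 1/L (L from
  power iteration on AᵀA, a guaranteed upper bound on σ_max²) followed by
  a weighted-TV proximal step solved with Chambolle-type dual
  projected-gradient iterations (τ = 1/(4d), d active spatial axes,
  default 20 inner iterations, duals warm-started across outer
  iterations). Nonnegativity of G (physical) is enforced by projection,
  default on; direct methods clip their linear solution. Regularization
  couples voxels spatially within each time frame; the temporal axis is
  coupled only through the data term.

The defaults deliberately trade data fidelity for noise suppression; on
noiseless data, exact settings (threshold 0, λ → 0) reproduce the
measurements to ≤0.1% relative residual.

### The adaptive weights

The weighted-adaptive variant modulates the TV penalty with
Perona–Malik-type weights

    w = 1 / (1 + (m/δ)²),

where m is a per-voxel edge measure and δ a scale factor, so strong local
gradients (true edges) are regularized less and flat regions fully. The
published description of the method this package models states only the
qualitative behaviour (weights adapt to local intensity; δ is sensitive to
local voxel-intensity change); the concrete construction here is this
package's own, fixed after simulation experiments on the default phantom:

1. **Edge measure**: per-frame spatial gradient magnitudes of the current
   iterate, aggregated over the time axis by a root-mean-square. Residue
   edges are spatially consistent across frames while noise is not, so the
   aggregation suppresses the detector's noise response by ≈ √T.
2. **Noise-floor subtraction**: the median aggregated magnitude (a robust
   floor) is subtracted and the result clipped at zero, so flat regions
   get w = 1 exactly and the adaptive solver never denoises them less than
   plain TV.
3. **Scale**: δ defaults to half the maximum of the edge measure,
   re-derived every outer iteration so the scale tracks the growing
   iterate (an early-iteration anchor would misclassify mid-gradient
   voxels as edges: the first iterate is ~2.5× smaller than the converged
   one). An explicit `delta` in the configuration overrides the rule
   (δ = 10⁹ reproduces plain TV to ≤10⁻⁶).
4. **λ default**: 0.6·σ̂·‖A‖₂ for both TV variants, with σ̂ the noise SD
   (estimated by a MAD of temporal second differences unless given). The
   coefficient sits in the strong-denoising regime the adaptive weighting
   is designed for — paired-seed sweeps show solver map-MSE still falling
   at ten times smaller coefficients, i.e. weaker defaults under-regularize
   badly — while keeping plain TV near its own optimum so the baseline
   comparison is fair.

Weights are recomputed from the current iterate every outer iteration
(`freeze_weights` freezes them after the first computation, for
ablations). Because recomputing weights redefines the recorded objective,
monotonicity of the trace is enforced by a guard: on an increase the
iteration retries with the previous weights (under which the descent
lemma applies), then with a high-accuracy prox (fresh dual, 10× inner
iterations), then with halved steps; if the objective still cannot
decrease the solver stops cleanly at the previous iterate, and a genuine
divergence (>10⁻⁶ relative increase after all retries) raises
`SolverFailure`. Degenerate all-zero input returns an all-zero estimate,
converged at iteration 0.

## Perfusion maps

Standard estimators: CBF = k·6000·max_t G/ρ (residue peak; ρ = 1.04 g/mL
tissue density, k = 1 hematocrit factor), CBV = k·100·(∫C/∫B)/ρ
(trapezoid), MTT = 60·CBV/CBF (masked where CBF ≤ 0), TTP = t₀ +
dt·argmax C (earliest-frame tie rule, NaN for all-zero curves). When maps
are derived from a residue estimate, CBV and TTP use the model-consistent
reconstructed curves Ĉ = A·Ĝ — on noisy data the raw measured curves would
make those two maps identical for every solver, emptying any per-solver
comparison; with noiseless data Ĉ equals C and the distinction vanishes.
The clinical TTP-on-measured-curve convention remains available by passing
the measured curves explicitly.

Relative maps divide each affected-hemisphere voxel by its mirror across
the fixed mid-sagittal plane (×100); no midline estimation or registration
is attempted (phantoms are constructed symmetric). The region classifier
thresholds rCBF (defaults 30/70%) following the clinical convention that
the core is the most hypoperfused tissue; note the cohort means used as
phantom defaults are inverted in rCBF (core 43 > penumbra 18), so on the
default phantom the classifier separates the two lesions cleanly but with
swapped identities.

## Evaluation harness

PSNR/MSE/MAE score each solver's maps against the phantom ground truth
over the brain mask, with the PSNR peak taken from the reference map on
the mask (maps are physical quantities, not 8-bit images; mse = 0 is
reported as +inf). All solvers see bit-identical noisy realizations per
seed (paired design); failures yield NaN cells rather than aborting.
Aggregation is mean ± SD across seeds; no significance machinery is
attached. The reference-map mean is carried in the report metadata but
enters no metric.

## Problem sizes and runtimes

Default experiments use the 64×64×1×20 phantom (a desk-scale stand-in for
512×512 clinical matrices; grid size is configuration), 20 paired noise
seeds for solver comparisons, and a 40-frame noiseless phantom for
recovery tests. A single WA-TV solve of the default phantom takes a few
seconds on one CPU core; the full 20-seed three-solver comparison runs in
a few minutes.

## Known limitations

- The rectangle-rule convolution operator is first-order; absolute
  parameter accuracy against continuous-time truth requires fine dt
  (the package reports grid-realized truth for exactly this reason).
- Spatial-only regularization: no temporal TV or FISTA acceleration.
- No automatic λ selection (L-curve / discrepancy); λ is a plain config
  value with a fixed default rule.
- The TSVD/Tikhonov defaults bias noiseless reconstructions by ~1–2%
  relative residual (by design; see above).
- The treatment simulation moves region severities linearly; it models
  the direction and magnitude of reperfusion, not its biology.
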