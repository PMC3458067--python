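# Methods

## Model

`longiseg4d` segments serial (multi-time-point) brain images into white
matter (WM), gray matter (GM), cerebrospinal fluid (CSF) and background by
evolving three coupled level-set functions φ1, φ2, φ3 whose zero sets are
the WM/GM, GM/CSF and CSF/background interfaces.  Each φ is maintained as a
signed distance in millimetres, positive inside the enclosed region.  Smooth
region memberships are telescoping products of a regularized Heaviside H:

    u_wm  = H(φ1)
    u_gm  = (1−H(φ1)) H(φ2)
    u_csf = (1−H(φ1)) (1−H(φ2)) H(φ3)
    u_bg  = (1−H(φ1)) (1−H(φ2)) (1−H(φ3))

These sum to one identically for *any* triple, not only nested ones, which
keeps the data term a genuine four-way relabeling competition even when a
surface transiently escapes its enclosing surface (the naive
`u_csf = (1−H(φ2))H(φ3)` form is only a partition on nested states and lets
φ1 grow unopposed in the background).

The energy of one scan is

    E = w_d E_data + w_l E_length + w_t E_thickness        (single scan)
    E4 = E + w_g E_longitudinal                            (serial scans)

with default weights w_d = 0.5, w_t = 0.25, w_g = 0.5 (the reference
setting) and w_l = 0.1.

**Data term.**  Each of WM, GM and CSF is described at every voxel x by a
local mean vector and covariance matrix of the modality intensities
(T1, T2, FA), estimated in a Gaussian window (σ = 3 mm, truncated at 3σ)
weighted by the current *hard* segmentation regions.  The per-voxel class
cost is the kernel-integrated negative log-likelihood of the observed
intensity vector under the local Gaussians, minus the log of an optional
probabilistic atlas prior (floored at 1e−6).  Because the normalized kernel
preserves constants, the double integral collapses to convolutions of the
local precision matrices and their moment contractions.  Local windows give
robustness to smooth intensity bias fields.  The background class uses a
single global Gaussian per channel (the skull-stripped background is
near-constant); a config switch makes it local.

Statistics are estimated from hard (sharp-limit) regions rather than the
smooth memberships: with a heavy-tailed Heaviside, a thin (3 mm) cortical
band receives several-fold variance inflation from across-boundary leakage,
which destroys the WM/GM discrimination precisely where it matters.

**Heaviside regularization.**  Two classic regularizations are implemented:
the arctangent form H(x) = ½(1 + (2/π) atan(x/ε)) and the compact-support
piecewise-sine form H(x) = ½(1 + x/ε + sin(πx/ε)/π) on |x| ≤ ε, with
ε = 1 voxel.  The compact form is the default
(`EvolutionConfig.heaviside_family`): the arctangent's Lorentzian tails
leak ~10 % membership three voxels across an interface, which both corrupts
thin-structure statistics and biases the telescoped class competition near
touching interfaces by about one voxel.  Both satisfy H(0) = ½ and
H(x) + H(−x) = 1.

**Cortical thickness term.**  With both fields signed distances, φ2
evaluated near the WM/GM interface is the local GM band width.  The band
[d_min, d_max] = [1, 6.5] mm is enforced by a region-based, one-sided
quadratic penalty: WM interior closer than d_min to the GM/CSF interface,
GM band deeper than d_max, and the mirrored constraints on φ1 seen from
outside the GM envelope.  The penalty is zero with identically zero force
on any in-band nested geometry and its pointwise forces push both
interfaces straight back into band.  An interface-integral (geodesic) form
was tried first and rejected: it doubles as a weighted length penalty and
contracts the thin GM band in violation zones instead of conforming it.

**Longitudinal term.**  Interfaces of the other scans of the same subject
are warped into the current scan's grid (and re-distanced); the current
interface is constrained to lie between the −ε and +ε level sets of every
warped reference (ε = 1.5 mm by default), again as a region-based quadratic
band penalty, weighted per source time point and applied to φ1 and φ2.
Source weights are w ∝ exp(age/τ_a − |Δage|/τ_d) with τ_a = 3 and
τ_d = 6 months, normalized: later scans have higher tissue contrast and
guide more strongly (the last scan always carries the largest weight),
with temporal distance as a secondary decay.  A plain age-proportional
weight is *not* monotone in source age once the temporal decay is applied,
which is why the exponential form is used.

**Constraint scale.**  Both band penalties are multiplied by
`constraint_scale` (default 100 per mm²), converting squared millimetre
violations into units commensurate with the data term's per-voxel
log-likelihood differences.  Without it a weight-0.25 hinge is an order of
magnitude weaker than voxel noise and never binds; at the default a 1 mm
violation costs as much as strong intensity evidence, so the band acts as
the near-hard constraint the coupled-surface construction intends, while
remaining C¹ and zero on the band.

## Minimization

Explicit gradient descent with an accept/reject controller.  All forces are
*exact gradients of the discretized energies* (central differences with
replicated edges and their exact adjoints), so finite-difference checks
agree to numerical precision and descent directions are trustworthy.  Per
iteration, each field moves at most 0.9 voxel (sign-preserving cap that
shrinks with the trial step); the trial is re-distanced and accepted only if
the total energy does not increase beyond an allowance; otherwise the step
is halved (up to 8 times) and it doubles again after acceptance.  The
allowance is the convergence tolerance plus twice the energy change that
re-distancing alone induces, measured once per statistics phase — without
it, descent stalls as soon as per-step gains fall below the
re-initialization's own energy resolution.

Fields are re-distanced every accepted iteration by computing the exact
Euclidean distance to the linearly interpolated zero-crossing point set
(KD-tree query), re-signed with the current sign pattern; this preserves the
zero set, restores |∇φ| = 1, and is idempotent to interpolation error.

Statistics (and the class cost fields) are refreshed every 10 accepted
iterations; each refresh restarts the monotone-descent baseline.  The inner
loop stops when a whole phase reduces the energy by less than the relative
tolerance (1e−5), the step controller bottoms out, or 120 iterations are
reached.

The serial pipeline runs: per-scan initial fits; then up to 3 outer rounds
of (re-)registration followed by a symmetric sweep (chronological, then
reverse, up to 40 iterations per scan per sweep) so early and late scans
influence each other within one round; it stops early when the mean
fraction of changed labels drops below 0.2 %.  The outer refinement runs
regardless of the longitudinal weight, so guided and unguided runs spend
identical iteration budgets; with weight 0 the sweeps are plain per-scan
refinement and the result is bit-identical to the single-scan pipeline run
on each scan independently (`run_coupled_pipeline`).

**Initialization.**  With an atlas: cumulative inside-probabilities
P(inside Γi) > ½, which is nested by construction and preserves thin shells
that a 4-way argmax destroys after blurring.  Without: multi-Otsu
thresholds on the smoothed first channel, mapping ascending intensity to
BG < CSF < GM < WM (suited to adult-like T1 contrast), followed by hole
filling and intersection; degenerate results fall back to a concentric
nested triple.  Everything is deterministic given the inputs and seed.

**Registration.**  Pluggable backends: `identity` (pre-aligned data),
`translation` (sub-voxel phase correlation on labels or intensities), and a
SimpleITK demons plugin; a failing backend falls back to identity with a
warning and the longitudinal band for that pair is widened by 1 mm as a
registration-error allowance.  Known deformation fields (e.g. phantom
ground truth) can be supplied directly, bypassing registration.  Narrowband
bookkeeping is deliberately not implemented: full-grid vectorized updates
are as fast at the 2D/small-3D problem sizes this package targets.

## Synthetic data

The phantom emulates first-year developmental contrast: on T1 the WM mean
starts below GM (infantile), crosses it exactly once at 7 months (the
midpoint of the isointense window) and ends above it (adult-like); T2
mirrors this; FA keeps WM bright by a fixed margin at every age,
CSF stays T1-dark/T2-bright.  Intensities live on a nominal [0, 1] range
with additive Gaussian noise (default SD 0.05, i.e. SNR ≈ 10 at mid-range)
and a smooth multiplicative bias field (default ±10 %, 24 mm scale).
Geometry is a nested set of shells (BG ⊃ CSF ⊃ GM ⊃ WM) with a sinusoidally
"gyrified" WM boundary and an angular GM thickness profile
(base + amplitude·sin(freq·θ) − optional focal Gaussian pinch); the profile
is radial, so oblique boundary segments have a somewhat narrower
perpendicular band.  Per-age geometry is the first age pulled back through
a smooth random deformation of specified amplitude, with ground-truth
labels and deformation fields returned; pairwise deformations are composed
to first order (u_{t→s} ≈ u_t − u_s, exact to O(|u||∇u|), which the
longitudinal band absorbs).  A fixed per-tissue mean table can replace the
schedule for benchmark phantoms (`high_contrast_means()` gives ~5 noise-SD
separation between adjacent classes).  A synthetic population-atlas
surrogate is produced by blurring the one-hot truth (default σ = 6 mm,
reflecting the cm-scale boundary uncertainty of population templates).

What the phantom does *not* model: real cortical folding complexity and
topology, MR acquisition physics (Rician noise is available but off by
default), registration failure modes beyond smooth random error, and
developmental anatomical change beyond a smooth deformation.  Passing
benchmarks therefore demonstrates the mechanics of the coupled model —
contrast handling, constraint action, guidance propagation — not clinical
segmentation accuracy.

## Benchmark conditions (experiments module)

* **Single-scan recovery**: 128², one channel, well-separated mean table,
  SNR 10 — recovers each tissue with Dice ≥ 0.98.
* **FA benefit**: isointense age, T1 = T2 for WM/GM exactly; with vs
  without FA under the same 6 mm prior.
* **Longitudinal benefit**: five ages (0–12 months), T1+T2 only, 1 mm
  known deformations, GM thickness 3 ± 1.8 mm — thickness variation the
  blurred prior cannot encode is exactly what guidance must supply.
  Guided and unguided runs share initial fits and iteration budgets.
* **Band-width sweep**: same series with the known correspondences
  corrupted by a 1 mm-RMS smooth error field; one outer round per band
  width from a shared initialization.
* **Thickness pinch**: 0.5 mm spacing, isointense schedule, a focal 0.4 mm
  GM pinch, runs started from the true pinched geometry; the constrained
  run must re-open the band toward d_min = 1 mm.

## Numerical choices and edge cases

* |∇φ| floored at 1e−8 in unit normals; covariance regularized by
  1e−4 × per-channel global variance on the diagonal; local statistics fall
  back to global class statistics where the window mass is below 1e−3;
  empty classes fall back globally with a warning.
* Degenerate fields (no zero crossing) raise a dedicated error; trial steps
  that destroy an interface are treated as too large and halved.
* Hard labels use the precedence WM ≻ GM ≻ CSF ≻ BG, matching the sharp
  limit of the memberships and resolving transient nesting violations.
* Both empty masks in a Dice comparison count as agreement (1.0, logged).
* Energy histories record the per-step acceptance allowance so monotonicity
  is testable at the tolerance the controller actually enforces; exact
  monotone descent is impossible under every-iteration re-distancing.

## Known limitations

2D phantoms exercise every code path but cortical geometry is far richer in
3D; the translation backend cannot recover rotation or scale (use the
demons plugin or external registration for real serial data); the
longitudinal term can only correct errors larger than ε, so it protects
against drift and gross isointense failure rather than refining sub-band
detail; and the temporal weight model treats contrast quality as monotone
in age, which underweights a high-quality neonatal scan when guiding early
targets.
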