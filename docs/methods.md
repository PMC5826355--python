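# Methods

## Acquisition model

The sampling scheme is a Cartesian DSI grid: all integer lattice points
**g** with ‖g‖² ≤ R² (default R = 5, giving 515 points — 257 hemisphere
points acquired, duplicated by antipodal symmetry, plus the origin).
b-values follow b = b_max·‖g‖²/R² with b_max = 8,000 s/mm², so the grid
spans 22 distinct nonzero shells between 320 and 8,000 s/mm²; physical
q-vectors follow the narrow-pulse relation b = 4π²q²τ. The keyhole
hemisphere is defined by a lexicographic sign rule (first nonzero grid
coordinate positive), which makes the 258 + 257 = 515 arithmetic exact
and deterministic. The effective diffusion time τ defaults to 0.0538 s;
it is a free configuration parameter — none of the dimensionless fit
quantities depend on it (b·λ products are τ-invariant), only the absolute
scale of RTAP/RTPP/MSD does.

## Signal models

**DTI** is fitted to the b0-normalized attenuation of the b < 1,500
s/mm² subset (32 directions + b0) by log-linear least squares with a
second WLS pass weighted by squared predicted signals. Eigenvalues are
sorted descending; negatives (noise voxels) are clamped to zero and
flagged rather than rejected, so background voxels cannot halt a run. FA
of an all-zero tensor is defined as 0.

**3D-SHORE** expands E(q) on the orthonormal eigenfunctions of the 3-D
quantum harmonic oscillator with even angular orders only (magnitude
dMRI is antipodally even). The index ranges are l = 0, 2, …, N_max and
n = l … (N_max + l)/2, ordered l-major, n, then m = −l…l; N_max = 6
gives 50 coefficients. The scale is ζ = 1/(8π²τ·MD) with the voxel's
own DTI MD, which makes the (n=0, l=0) basis function exactly the
attenuation of an isotropic Gaussian at diffusivity MD. Fitting is
penalized least squares with an angular Laplace–Beltrami weight
(l(l+1))² and λ_reg = 1e−8 — near interpolation, since the 515-sample
fit is strongly overdetermined at order 6–8; λ_reg = 0 is allowed and
raises on singular systems.

Because the basis functions are Fourier eigenfunctions, the EAP is the
*same* expansion at the dual scale η = 1/(4π²ζ) with coefficients
multiplied by (−1)^(n−l)·(−1)^(l/2). All propagator functionals use this
identity:

* RTAP and RTPP are computed by either of two routes — the EAP-space
  line/plane integral, or the q-space plane/line integral supplied by the
  projection-slice theorem. Both are numerical quadratures (64-point
  Gauss–Legendre radially over [0, 10√scale], where the basis envelope is
  < 2e−22 at the endpoint; uniform angular nodes, exact for the
  trigonometric polynomials the basis produces in-plane). The two routes
  agree to machine precision on the same fit and serve as an internal
  correctness gate (tested at 0.5%).
* MSD contracts the isotropic (l = 0) coefficients against cached radial
  moments of the basis (a one-dimensional integral per n, computed once);
  a full quadrature route cross-checks it.
* The ODF (radial EAP integral per direction) is an analytic linear map
  from the coefficients to spherical-harmonic coefficients — the radial
  integral acts per (n, l) — evaluated on a subdivided-icosahedron
  tessellation. We use 642 vertices (3 subdivisions): icosahedral
  subdivision is exactly closed under u → −u, which is the property the
  even ODF needs; the count differs from the 724-direction tessellation
  common elsewhere because no installed package ships that point set.
  Negative ODF ringing is clipped to zero and flagged. GFA is the
  normalized ODF variance; PA the coefficient-energy ratio.
* The main diffusion direction defaults to the DTI principal eigenvector,
  with the ODF argmax available as a config switch; near-degenerate
  voxels ((λ₁−λ₂)/λ₁ < 0.05) are flagged but still return a direction.

### Accuracy of the propagator indices, and why the oracle order is 8

RTAP integrates E over the plane orthogonal to the fiber, where the
signal decays slowest (rate λ⊥). The scheme samples q only up to
q_max (b_max); the fraction of the plane integral beyond the sampled
range is e^(−b_max·λ⊥) — about 3% at λ⊥ = 0.45e−3 mm²/s and 0.5% at
λ⊥ = 0.65e−3. No fit can recover what was never sampled, so closed-form
agreement at the 1% level is only meaningful for tensors whose
perpendicular decay is resolved, i.e. b_max·λ⊥ ≳ 5. On such tensors,
basis truncation at N_max = 6 still leaves ~0.5–1.3% bias in RTAP;
at N_max = 8 all three integral indices (RTAP, RTPP, MSD) are within 1%
of their Gaussian closed forms. The closed-form oracle tests therefore
run at order 8, while the cohort pipeline keeps the more conservative
N_max = 6 default (fewer coefficients per voxel, greater stability at
SNR 28); the qualitative behavior used in the group statistics is
unchanged between the two orders.

## Synthetic cohort

The generator emulates the study's statistical structure, not its
anatomy.

*Voxel level.* Tissue signals are Gaussian mixtures
E = Σ f_c·exp(−b·uᵀD_c u). The white-matter compartment uses
tract-averaged eigenvalues (1.55, 0.65, 0.65)·10⁻³ mm²/s (FA ≈ 0.5,
MD ≈ 0.97·10⁻³) — bundle means mix the coherent core with orientation
dispersion and partial volume, so the radial eigenvalue is deliberately
above single-axon values, and the perpendicular decay is resolved by the
b ≤ 8,000 scheme (previous section). Gray matter uses (1.1, 0.75,
0.75)·10⁻³. Noise is Rician: out = √((s+n₁)² + n₂²) with Gaussian σ set
from the target b0 SNR of 28 (σ = 1/28 on unit-S0 tissue). SNR is
estimated the way it is defined: mean b0 signal in a corpus-callosum
analog ROI divided by the Gaussian σ recovered from the Rayleigh
background SD (σ̂ = SD/√(2−π/2)).

*Geometry.* A toy brain on a small grid: 36 bilateral GM parcels (the
eight motor regions M1, SMA, SC, PM, Thl, Cau, Put, GPi plus filler
regions), mirrored across the midline, a midline corpus-callosum block,
and polyline bundles wiring three motor networks — CC (corpus callosum
to each motor ROI, 8 connections), CORT (the four cortical ROIs
pairwise, 6), SUBCORT (cortical-except-SC × subcortical, 12).
Streamlines are stored in voxel coordinates (0-based, corner origin)
with sine-tapered lateral offsets so endpoints stay at parcel centers.

*Cohort level.* Ten controls × 2 sessions and ten patients × 3 sessions
(configurable). Each measure is
baseline·unit_factor·(1+z_{subject,index})·effect·(1+ε) with
z ~ N(0, CV_inter = 10%) and ε ~ N(0, CV_intra = 3%). Patient effects
are multiplicative per index and session, emulating the reported
longitudinal pattern qualitatively: anisotropy indices (GFA, PA, FA)
elevated 10% at tp1 and renormalizing; RTAP/RTPP elevated 8%/6% at tp1;
diffusivity indices (MD, MSD) rising 8–10% by tp2/tp3. ROI effects are
restricted to a designated 12-region subset (the motor regions plus four
fillers) — regional, not global, which is what makes the Group × TP ×
Region interaction a real signal; connection effects cover all three
networks. The clinical link is declared and monotone: the NIHSS motor
score at tp3 increases with the patient's latent subcortical GFA and
RTPP levels at tp1 (plus small noise), and the baseline NIHSS partially
tracks the same latent severity, so the clinical reference regression
retains moderate predictive power while the subcortical propagator model
recovers the link almost exactly. Effect sizes are free parameters of
the generator (nothing in the source study quantifies contralateral
modulations); all recovery claims in the tests refer to *injected*
effects.

Two routes consume the same latent model: `build_cohort` renders 4-D
volumes (patient modulations applied to left-hemisphere eigenvalues:
the anisotropy factor stretches the parallel/radial ratio, the
diffusivity factor scales the trace) and `simulate_measure_table` draws
the per-connection/per-ROI measure table directly. Voxel-wise fitting of
50-subject cohorts would add nothing to the statistics modules, so the
simulation-based checks (reproducibility recovery, null calibration) run
on the measure-level route; the image route is exercised end to end on a
reduced grid (20×14×10, 2+2 subjects, ~25 s) and carries the SNR
construction check.

*What the phantom does not model:* anatomy, lesion cores, EPI
distortion, motion, partial-volume mixtures at GM/WM interfaces beyond
the trivial one, non-Gaussian tissue signals (compartments are Gaussian,
so SHORE-vs-DTI differences on the phantom reflect basis truncation and
geometry, not genuine non-Gaussianity), or spatial noise correlations.
Passing tests therefore certify the correctness of the estimators and
statistics under the declared generative model, not in-vivo index
values, which are never targets.

## Quantification conventions

Per-fiber sampling: equally spaced arc-length points (0.5-voxel step),
trilinear interpolation, sample-center convention (voxel (i,j,k) at
coordinate i+0.5 …); per-fiber means averaged unweighted across the
bundle (arc-length weighting available). GM regions are masked at
probability ≥ 0.95; hemispheric means are combined with equal weight for
controls (voxel-count weighting available) and restricted to the
contralateral hemisphere for patients; regions emptied by the mask are
dropped and reported, never zero-filled.

## Statistics

*Test–retest (two control sessions).* σ_ws = √(Σᵢ(a_i,tp1 − a_i,tp2)² /
2k); CV_intra = σ_ws/μ·100 with μ the overall mean; CV_inter is the
per-session across-subject CV averaged over the two sessions; ICC =
σ_bs²/(σ_bs² + σ_ws²). The σ_bs estimator is the sample SD of the
per-subject session means — the simplest companion to the paired σ_ws;
ICC values depend on this choice, so it is recorded in the report
metadata. Tract scope pools each loop's (subject, connection) pairs as
measurement units for ICC/CV_intra, and summarizes per-connection
CV_inter as mean ± SD; GM scope computes everything per region.
Acceptability flags: CV_intra ≤ 10%, CV_inter < 15%; ICC bands poor
(<0.4) / fair / good / excellent (>0.75).

*Longitudinal tract comparison.* Δ_tp = |v_j − v_i|/v_i·100 per subject
and connection (denominator: earlier time point; mean-of-pair available),
averaged within each loop per subject; control Δ(tp1c,tp2c) vs each
patient pair by pooled-variance unpaired t-tests (Welch via flag);
Bonferroni across the family of 7 indices (family size explicit config);
a Kolmogorov–Smirnov normality check (sample-moment normal) is reported
alongside. Non-positive baselines are dropped with a log line.

*ANOVAs.* Balanced-design sums of squares from cell means; the
decomposition partitions the total SS and df exactly (asserted in the
tests, with the two-way repeated-measures route cross-checked against
statsmodels' AnovaRM). Mixed design: Group on df (1, 18) against
subjects-within-group; each within effect against its
subject-interaction error — Group×ROI and Group×TP×ROI on (35, 630)
with the 2×10×2×36 design, patient-only TP×ROI on (70, 630) with
3×36×10. Greenhouse–Geisser ε comes from the eigenvalues of the
contrast-projected pooled covariance (Kronecker Helmert contrasts);
Mauchly's W uses the standard χ² approximation, and with 36 regions and
20 subjects the contrast covariance is rank-deficient, so W = 0 and
sphericity is treated as rejected — the reported p is then the
GG-corrected one while the printed df pair stays uncorrected, matching
the convention of standard statistics packages. Post-hoc tests are
gated on a significant interaction (refused otherwise): per-(region,
time point) unpaired tests for the mixed design, per-(region, time pair)
paired tests for the repeated-measures design; Bonferroni multiplies by
the number of regions, LSD reports raw p; signs encode the direction
(patients > controls, or earlier > later).

*Outcome regression.* OLS with intercept; backward elimination removes
the predictor with the largest removal p (its partial-F p in the current
model, equal to the two-sided t p) while it exceeds p_out = 0.10, ties
broken by column order. Families: reference (age, stroke size, NIHSS
tp1), TBM (+ loop-mean MD, FA at tp1), SBM (+ loop-mean GFA, PA, RTAP,
RTPP, MSD), GBM (the seven index loop means, no clinical variables) —
one reference plus three networks × three families = 10 models, each
reported with R², adjusted R² (to three decimals), overall-F p, N and k.
Cohorts below 10 patients skip this stage (the full SBM design needs
N > 9). No cross-validation: the design targets the 10-patient setting.

## Numerical choices and degenerate inputs

Laguerre/harmonic evaluations go through scipy.special; normalization
constants in log-space (gammaln) to avoid overflow at high order.
Quadrature spans 10 envelope SDs (12 for the MSD cross-check). Seeds:
every stochastic component draws from numpy Generators spawned off a
single SeedSequence, so latents, covariates and session noise are
independent reproducible streams and the measure-level and image-level
cohorts share identical latents and covariates at equal seed. Degenerate
definitions: FA(0-tensor) = 0; ICC with both variances zero = 1
(flagged); PA and GFA of all-zero inputs raise; empty bundles are
missing values, not zeros. Pipeline problem sizes in the tests — 2+2
subjects on a 20×14×10 grid for the image route, n = 50 at measure level,
200 replicates for calibration — were chosen as the smallest sizes at
which the respective statistical claims are stable.
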