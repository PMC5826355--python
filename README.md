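# shoremaps

Diffusion-MRI microstructure pipeline for longitudinal two-group studies:
Cartesian DSI q-space sampling, DTI and 3D-SHORE signal modeling with seven
scalar indices, tract- and region-level quantification, test–retest
reliability, longitudinal group inference, and clinical-outcome regression —
exercised end to end on a synthetic stroke-vs-control phantom cohort.

## The scientific problem

After an ischemic stroke, the hemisphere *opposite* the lesion
(contralateral / contralesional) undergoes subtle microstructural
remodeling that conventional tensor indices capture only partially.
Ensemble-average-propagator (EAP) models fitted to multi-b diffusion
spectrum imaging (DSI) provide a richer family of indices. This package
implements that analysis chain for a design with ten patients scanned at
three time points (1 week, 1 month, 6 months) and ten controls scanned
twice, and — because no such dataset ships with it — a synthetic cohort
generator that emulates the acquisition (515-point keyhole Cartesian DSI
grid, b ≤ 8,000 s/mm², Rician noise at b0 SNR ≈ 28), the motor networks
(transcallosal CC, cortical CORT, subcortical SUBCORT), a 36-region GM
parcellation, and the longitudinal effect structure.

## Models and indices

The q-space attenuation E(**q**) and the EAP P(**r**) are Fourier duals,
P(**r**) = ∫ E(**q**) e^{i2πq·r} dq. Two models are fitted per voxel:

* **DTI** on the b < 1,500 s/mm² subset (32 directions): MD = (λ₁+λ₂+λ₃)/3
  and FA = √(1/2)·√((λ₁−λ₂)² + (λ₂−λ₃)² + (λ₁−λ₃)²) / √(λ₁²+λ₂²+λ₃²).
* **3D-SHORE**: E(q) = Σ c_nlm Φ_nlm(q) on the orthonormal 3-D
  harmonic-oscillator basis (generalized Laguerre × real spherical
  harmonics, scale ζ = 1/(8π²τ·MD)). Because the basis functions are
  Fourier eigenfunctions, the EAP has the same coefficients up to sign
  flips at the dual scale, giving analytic/quadrature access to
  - **RTAP** = ∫ P(r‖) dr‖ (line integral along the main diffusion
    direction; 1/(4πλ⊥τ) for a Gaussian voxel),
  - **RTPP** = ∫ P(r⊥) d²r⊥ (orthogonal plane integral; 1/√(4πλ‖τ)),
  - **MSD** = ∫ P(r) r² d³r (6·MD·τ, Einstein relation),
  - **PA** = √(1 − Σc²_n00 / Σc²_nlm) (propagator anisotropy),
  - **GFA**, the normalized variance of the ODF (the radial EAP integral
    per direction).

Index volumes are reduced to per-connection values (per-fiber trilinear
sampling, then unweighted bundle averaging) and per-region GM means (95%
probability mask; bilateral mean for controls, contralateral hemisphere
for patients). Statistics follow the study design: ICC, CV_intra and
CV_inter on the control test–retest data; percentage absolute changes
Δ_tp between time points compared with Bonferroni-corrected unpaired
t-tests; three-way mixed and two-way repeated-measures ANOVAs with
Mauchly/Greenhouse–Geisser handling; and backward-eliminated linear
models (p_out = 0.10) predicting the 6-month NIHSS motor score, scored by
the adjusted R² = 1 − (1−R²)(N−1)/(N−k−1).

## Worked example

```python
import numpy as np
import shoremaps as sm

scheme = sm.build_dsi_scheme(radial_grid_size=5, b_max=8000.0, tau=0.0538)
wm = sm.CompartmentSpec((1.55e-3, 0.65e-3, 0.65e-3), (0.0, 0.0, 1.0), 1.0)
signal = sm.simulate_voxel_signal([wm], scheme)

dti = sm.subset_by_bvalue(scheme, 0.0, 1500.0)
tensor = sm.fit_tensor(signal[(scheme.bvals < 1500) | scheme.is_b0], dti)
fit = sm.fit_shore(signal, scheme, n_max=8,
                   zeta=sm.estimate_zeta(sm.md(tensor), scheme.tau))

spec = sm.CohortSpec(seed=2024)
measures, covariates = sm.simulate_measure_table(spec)
models = sm.run_model_families(measures, covariates)
```

prints (via the fuller script in the docstrings):

```
scheme: 515 samples, 32 low-b directions
MD = 9.500e-04 mm^2/s   FA = 0.499
RTAP = 2271.5 mm^-2   (Gaussian closed form 2275.6)
RTPP = 30.92 mm^-1   (closed form 30.89)
MSD  = 3.067e-04 mm^2   GFA = 0.387   PA = 0.245
GFA subcortical loop: ICC = 0.94 (excellent), CV_intra = 2.8%
GFA delta(tp1,tp2) control 3.0% vs patient 8.7%: adjusted p = 5.3e-11 ***
outcome regression: reference adj R2 = 0.350; subcortical SBM adj R2 = 0.999
```

Reading: the noiseless white-matter voxel's propagator indices land on
their Gaussian closed forms; on the synthetic cohort the subcortical
network is highly reliable across sessions (ICC 0.94, within-subject CV
under 3%), the injected early anisotropy elevation in patients is
detected after Bonferroni correction, and the regression that includes
the subcortical propagator indices at baseline predicts the 6-month
motor score far better than clinical variables alone.

A thin CLI mirrors the stages:

```bash
shoremaps scheme --out results        # write bvals/bvecs + TSV sidecar
shoremaps phantom --seed 1 --out results
shoremaps run-all --seed 1 --out results
```

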