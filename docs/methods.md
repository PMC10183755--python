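# Methods

`callosim` models and analyzes the microstructure of the corpus callosum
as measured by ultra-strong-gradient diffusion MRI and multi-parametric
FLASH imaging: axon diameter and restricted-fraction estimation from
variable-diffusion-time data, NODDI, magnetization-transfer saturation
(MTSat), the g-ratio/conduction-velocity algebra, and the regional
mixed-effects statistics of a developmental cohort.  Because no real
acquisitions ship with the package, a synthetic-cohort generator
reproduces the statistical structure of such a study end to end.

## Acquisition model

Diffusion volumes are described per volume by b-value, unit gradient
direction, pulse duration δ, and pulse separation Δ.  Three built-in
protocols are provided: a fixed-diffusion-time multi-shell protocol
(Δ = 23 ms; b = 0/500/1200/2400/4000/6000 s/mm², 14 interleaved b=0
volumes, 254 volumes total) used for tensor and NODDI fitting, and two
variable-diffusion-time protocols (Δ ∈ {18, 30, 42, 55} ms; per Δ: 4 b=0,
30 directions at b=2000, 60 at b=4000 s/mm²; 376 volumes; δ = 7 ms) for
axon-diameter mapping.  Gradient amplitudes derive from the
rectangular-pulse PGSE relation b = (γGδ)²(Δ − δ/3) and stay below the
300 mT/m ceiling of ultra-strong-gradient human systems for every built-in
volume (peak ≈ 288 mT/m on the b=6000 shell).  Direction sets are
antipodally symmetric electrostatic-repulsion point sets generated once
with a fixed seed and shipped as text fixtures; the b=0 volumes of the
variable-Δ protocols lead each Δ block.

## Signal models

**Restricted cylinder.**  The perpendicular attenuation of water inside an
impermeable cylinder follows the Gaussian-phase-distribution (GPD) series
over roots of J₁′ (default 20 roots), with free Gaussian diffusion along
the axis (intra-axonal diffusivity D_a = 1.7 μm²/ms by convention,
configurable).  *Validity:* an independent Monte-Carlo random-walk
simulation (reflecting cylinder wall, no Gaussian assumption) agrees with
the series to 0.25% or better for diameters ≤ 6 μm across all built-in
shells, but the Gaussian-phase assumption itself breaks down at strong
attenuation: at d = 10 μm and G ≈ 270 mT/m the series overestimates the
signal by ~8–9%.  Within the diameter range that dominates the callosum
(≲ 6 μm apparent) the approximation is accurate; population summaries
involving the extreme upper tail inherit this bias.

**Diameter distributions.**  The restricted population signal is the
cross-section-weighted (d²·p(d), spins-per-cylinder) average of
single-cylinder attenuations, evaluated on a fixed 128-node
Gauss–Legendre grid over d ∈ [0.05, 25] μm.  Families: delta (single d),
gamma, truncated gamma (default bounds [0.1, 20] μm), and a continuous
Poisson density p(d) ∝ λᵈ e^{−λ}/Γ(d+1) on (0, 25] μm, numerically
normalized.  The scalar "apparent axon diameter" d_a reported from a fit
is the number-weighted mean of the fitted distribution; a
volume-weighted mean is also exposed.

**Extracellular space.**  An axially symmetric Gaussian compartment whose
perpendicular diffusivity decreases with diffusion time,
D_⊥(Δ, δ) = D_∞ + A·(ln(Δ/δ) + 3/2)/(Δ − δ/3), the short-range-disorder
form; A (μm²) is the disorder amplitude and D_∞ the long-time asymptote.
CHARMED composes restricted and hindered compartments with restricted
signal fraction FR; AxCaliber is the same composition with a diameter
distribution, fitted across diffusion times.

**NODDI.**  Watson-dispersed sticks (v_ic, concentration κ;
OD = (2/π)·arctan(1/κ)), a tortuosity-coupled extracellular zeppelin
(D_⊥ = D_∥(1 − v_ic)) and isotropic free water (v_iso, D_iso = 3.0
μm²/ms), with D_∥ = 1.7 μm²/ms fixed.  The dispersed stick is integrated
on a polar quadrature grid built in the frame of the mean orientation
(96 Gauss–Legendre nodes in cos θ × 48 azimuths), which makes the signal
exactly rotation-equivariant and keeps the Watson weights accurate up to
κ ≈ 64 (OD ≈ 0.01).  The extracellular compartment uses the Watson
mean-tensor approximation (exact first moment via the Dawson function);
at callosal dispersions (OD ≈ 0.04) the difference from the fully
integrated zeppelin is negligible and the κ→∞ limit is recovered to
O(1/κ).

## Fitting cascade

1. **Ball-and-stick** (shared diffusivity) estimates the fiber
   orientation, initialized from a log-linear tensor fit on the lowest
   shell; the orientation is then frozen.  Voxels with FA < 0.05 or stick
   fraction < 0.05 are flagged degenerate.
2. **CHARMED** (single-diameter cylinder + time-dependent zeppelin,
   orientation fixed) estimates FR, the cylinder diameter, and the
   extracellular diffusivities by bounded trust-region least squares; its
   estimates initialize stage 3.
3. **AxCaliber** estimates the distribution parameters, FR, and the
   extracellular time dependence with 5 seeded multi-starts (the
   objective is multi-modal near the resolution limit).  For the gamma
   families the shape parameter is fixed (k = 3) by default and only the
   scale is fitted: at realistic SNR the shape is not identifiable and a
   free shape inflates the diameter error several-fold through
   shape/scale/FR trade-offs; `fix_shape=None` restores the free fit.
   A profile scan over the distribution mean (×0.5–×2) flags voxels whose
   predicted signal is flat to <0.5% RMS — the resolution-limit plateau
   of small diameters at finite gradient strength — as
   `resolution_limited`.

Noise: magnitude data are treated with the offset-Gaussian approximation
E_obs ≈ sqrt(E_model² + σ²), σ estimated from the b=0 volumes; the
synthetic data are genuinely Rician.  Per-voxel log-likelihoods use the
Gaussian residual form with the MLE variance, which is what the
distribution-family comparison (`select_distribution`) ranks; exact ties
break deterministically toward the full gamma family.  Voxels are
independent — fitting is embarrassingly parallel with no shared state.

NODDI is fitted independently on the fixed-Δ protocol with the
orientation frozen from a tensor fit (b ≤ 1200 s/mm², the Gaussian
regime) and v_ic, v_iso, κ free; v_iso > 0.95 flags v_ic as
unidentifiable.

## MTSat

The three FLASH contrasts (T1w 23 ms/28°, PDw 23 ms/5°, MTw 42 ms/7°)
feed the standard small-angle rational estimators for apparent R1,
amplitude, and MTSat (percent units).  The estimator is exactly invariant
to global signal scaling (receive field).  The forward model places the
instantaneous MT saturation mid-TR with relaxation split evenly around
it — the discretization consistent with the estimator's derivation;
with it, saturations of 2–5 p.u. are recovered within ~1.3% across
R1 ∈ [0.5, 1.5] s⁻¹ (pulse-adjacent orderings leave a 5–7% inversion
bias and are not used).

## g-ratio and conduction velocity

MVF = 0.11 × MTSat (fixed histological calibration, configurable);
AVF = (1 − MVF)·FR (CHARMED route) or (1 − MVF)(1 − v_iso)·v_ic (NODDI
route, the default downstream); g = sqrt(1/(1 + MVF/AVF));
cv = 16.99 · d_a · sqrt(−ln g) m/s.  The logarithm is natural — only then
does maximizing cv at fixed outer diameter reproduce the classical
conduction-optimal g = e^(−1/2) ≈ 0.61.  g and cv are computed per voxel
and aggregated afterwards (region medians of voxel values, never
compositions of medians).

## Synthetic cohort

The generator emulates a cross-sectional developmental cohort (default
n = 50, ages uniform on [8, 18], 60% female):

* **Puberty**: PDS scores follow 1 + 3·logistic((age − onset)/1.5 yr)
  plus N(0, 0.5) noise, onset 11.5 yr (F) / 12.5 yr (M), adrenal onset
  0.5 yr earlier and gonadal 0.3 yr later; the noise level is calibrated
  so the linear R² between age and the summary score is ≈ 0.75 at n = 50.
* **Regional truth**: per (subject, region), each primitive measure (FA,
  OD, v_ic, FR, d_a, MTSat) equals the regional calibration median plus
  MAD-scaled standardized effects (age slope, sex offset, sex×PDSA
  interaction; defaults in `data/regional_effects.csv`, genu as the
  zero-reference region) plus a subject random effect (SD 0.5 MAD, shared
  across regions) and a subject×region effect (SD 0.25 MAD).  g and cv
  are derived per voxel from MTSat/v_ic/d_a, so their regional patterns
  and effects are emergent, not injected.  v_iso truth defaults to 0.02
  in callosal voxels.
* **Voxels**: voxel values scatter around the subject-region truth with
  SD equal to the regional MAD — the empirical voxel-level spread, which
  in real data embodies measurement noise at the study's SNR.  The
  mixed-model stages consume these tables directly; pushing every voxel
  of every cohort through the fitting cascade would confer no additional
  statistical content on the *statistics* stage and is exercised
  separately at signal level.
* **Signals**: for fitting experiments, voxel signals are forward-modeled
  (AxCaliber for the variable-Δ protocol, NODDI for the fixed-Δ protocol,
  FLASH triplets for MTSat) with Rician noise |S + ε₁ + iε₂|,
  ε ~ N(0, S₀/SNR), default SNR 30.
* **Cognition**: hit reaction time is linear in age and standardized
  subject-mean d_a (default standardized coefficient −0.63); d′ is linear
  in standardized MTSat (+0.57) and g (−0.48); Gaussian noise SDs 0.45
  and 0.55 leave realistic residual variance.  A subsample option mirrors
  small cognitive substudies but defaults to the full cohort.

What the generator does **not** emulate: image geometry and registration,
motion/eddy/susceptibility artifacts, partial-volume mixing at region
borders, spatially correlated noise, and any coupling between measures
beyond the shared random effects.  Passing tests therefore demonstrate
internal consistency of models, estimators, and statistics under the
stated noise model — not robustness to scanner artifacts.

## Statistics

Voxel-wise values are quantile-trimmed (drop strictly below the 1st /
above the 99th percentile, linear-interpolation definition; fewer than 10
values pass through with a warning).  Note that re-trimming an already
trimmed sample removes a further ~2% by construction; trimming is a
single-pass operation.

Mixed models are fitted by maximum likelihood (statsmodels MixedLM;
Powell optimizer with fallbacks — the quasi-Newton defaults are fragile on
variance-component models) with a subject random intercept and a
subject×region variance component; the DV and continuous covariates are
z-scored so coefficients are standardized, sex enters as a male indicator
(reference female) and region as treatment-coded categories (reference
genu).  Region-specific sex and sex×puberty effects are estimated as
region-interaction contrasts — within-subject comparisons, which is where
the repeated-measures design earns its power.  Candidate models are
compared by AIC (−2ℓ + 2k, k counting fixed effects, variance parameters,
and the residual variance), ties toward fewer parameters; marginal
effects are fixed-effects predictions on covariate grids with
delta-method CIs; an association is flagged only when the 95% CI excludes
zero **and** p < 0.005.  No multiplicity correction is applied beyond
that rule.

## Pipeline

`simulate → fit → mtsat → gratio → stats`, all intermediates plain
CSV/NIfTI, each stage resumable, with a JSON manifest (config hash, seed,
versions, per-stage counts) making a run reproducible.  The demo
configuration simulates 12 subjects × 20 voxels/region for the statistics
stages and pushes a small signal subset (2 subjects × 3 voxels) through
the full fitting cascade; cohort sizes, voxel counts, and the signal
subset scale through the YAML config.

## Problem sizes used in the test suite

Chosen as the smallest sizes that make the assertions statistically
meaningful: the Monte-Carlo oracle uses 10⁵ walkers per diameter; noisy
recovery suites use 60–200 voxels at SNR 30; mixed-model recovery and
null calibration use 100 cohorts each of 50 subjects × 6 regions × 50
voxels; unit tests use smaller cohorts (15–50 subjects).

## Known limitations

* GPD validity at large diameters/strong gradients (above).
* The time-dependent extracellular form is one of several published
  parameterizations; only D_⊥ carries time dependence.
* The MVF calibration (0.11) and cv proportionality (16.99) are fixed
  literature constants, configurable but never re-derived.
* Wald-type CIs/p-values from MixedLM; no Satterthwaite/Kenward-Roger
  degrees-of-freedom correction (at 50 subjects the difference is small
  but the null flag rate can sit slightly above nominal for
  between-subject terms).
* The continuous-Poisson family's support truncation at 25 μm is
  arbitrary but irrelevant at callosal diameters.
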