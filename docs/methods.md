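# Methods

This note documents the models, numerical choices and known limitations
of the package. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Induced-response coupling model

The analysis object is the *induced response*: trial-averaged,
baseline-corrected time-frequency power at the five motor sources (SMA,
iM1, cM1, iPM, cPM; ipsilesional mapped to the left hemisphere by
mid-sagittal flipping of right-lesion subjects). Stacking power over
sources and frequencies into g(t), the model is the linear dynamical
system

    dg/dt = A g + C u(t),        u(t) = exp(-(t - t_cue)^2 / 2 sigma^2)

with sigma = 50 ms. States are *percent* deviations from baseline, so
the resting state is g = 0 and coupling parameters are amplitude-scale
free. A is assembled from:

* **intrinsic decay** per source: a negative diagonal returning power to
  baseline. Defaults spread 3.5–9.5 s⁻¹ across sources, scaled per band
  by fixed factors (θ 0.6, α 0.9, β 1.4, γ 1.1 — theta responses
  persist, beta rebounds fast). Both spreads are deliberate: with a
  single shared decay, all band trajectories of a source are exactly
  proportional under one input bump, which makes (a) incoming couplings
  from different sources nearly collinear and (b) cross-frequency
  coupling exactly mimickable by rescaled within-frequency coupling.
  Heterogeneous time constants are physiologically reasonable and are
  what makes the estimation problem well posed.
* **extrinsic coupling** per directed edge: a target-frequency ×
  source-frequency matrix; within-frequency entries on the diagonal,
  cross-frequency entries off it, restricted to configured band pairs.
* **input weights** C per (source, band), with negative beta drive
  (movement-related beta desynchronization). The default drive
  (300 %/s) produces peak induced responses of ±30–50%, the magnitude
  of real movement ERD/ERS.

Integration is fixed-step RK4 at 5 ms (configurable); an eigenvalue
check raises a diagnostic error for unstable A. The unit tests verify
the integrator against scipy's adaptive solver at 1e-10 tolerance.

## Model space

Seven architectures over the nine reciprocal connection pairs
{SMA↔cM1, SMA↔iM1, SMA↔iPM, SMA↔cPM, iPM↔cPM, iPM↔iM1, cPM↔cM1,
iPM↔cM1, iM1↔cM1}: the original figure defining the reduced variants is
not recoverable, so the space is reconstructed from the two stated
hypotheses — *where* cross-frequency coupling lives (all edges /
ipsilesional edges only / interhemispheric edges only) crossed with the
edge set (full 18-edge / reduced 16-edge dropping the diagonal iPM↔cM1
pair) — plus an all-linear control with the full edge set. DCM1 (all
edges, all nonlinear) nests every other model. The space is a plain
list of `ModelSpec` objects and fully user-configurable.

## Variational-Laplace inversion

Free parameters per model: one within-frequency gain per (edge, band);
one cross-band gain per (nonlinear edge, ordered band pair); one
log-decay offset per source (band factors fixed — giving each band its
own free decay lets the decay absorb that state's incoming couplings,
which measurably destroys parameter recovery); one input gain per
(source, band). Tying all frequency bins of a band to one parameter is
what keeps the scheme identifiable at single-subject data sizes.

Priors are zero-mean Gaussians: SD 0.5 s⁻¹ on coupling gains (matching
the magnitude of physiological coupling rates; tighter priors
systematically over-shrink), SD 0.5 on log-decay offsets, SD 100 %/s on
input gains. Observation noise is one log-precision per source, updated
by fixed point. The optimizer is Gauss–Newton with Levenberg damping on
the free energy

    F = accuracy − complexity
      = −½ eᵀΠe + ½Σ N_s λ_s − (N/2)ln 2π − ½(θ−θ₀)ᵀΣ₀⁻¹(θ−θ₀)
        − ½ln|Σ₀| + ½ln|Σ_θ|

accepted steps never decrease F; convergence is declared when the
relative change stays below 1e-3 (configurable) for 3 successive
accepted iterations, with a maximum of 128 iterations and a warning on
non-convergence. Gradients come from exact sensitivity equations
integrated jointly with the state (the sensitivity bundle shares the
system matrix, so the whole Jacobian costs one batched RK4 pass); the
test suite checks them against finite differences implicitly via the
noiseless self-consistency and nested-model tests.

`reduce_to_modes` provides SVD compression of the frequency axis
(projector + coefficients, default 4 modes) as a standalone, tested
operation; the default inversion instead works on a reduced frequency
grid directly (typically 1–2 bins per band), which keeps the band-tied
parameterization exact. The grid reduction is `regrid_spectrogram`.

## Group model selection

FFX: softmax of column-summed free energies (log group Bayes factors),
computed via log-sum-exp. RFX: the standard variational Dirichlet
scheme over model frequencies (uniform prior α₀ = 1), iterated to
1e-8; exceedance probabilities by Monte-Carlo argmax over Dirichlet
draws (default 1e6, seeded). The two-model case is verified against
exact Beta-distribution quadrature.

## Synthetic worlds

The generator states one world per purpose; none of its parameters are
fitted to data.

* **Cohort world** (`generate_cohort`): population-mean coupling with
  band-diagonal gains uniform(−0.6, 0.6) on every edge and, on nonlinear
  edges, cross-band gains of magnitude 0.3–0.6 (bounded away from zero —
  a "nonlinear" subject with near-zero cross terms is effectively linear
  and model comparison rightly prefers the linear model); per-subject
  diagonal jitter (SD 0.05 default); couplings rescaled toward zero
  until stable. Favorable subjects get an additive ±0.3 s⁻¹ shift on
  three designated beta connections (SMA→cPM more inhibitory, SMA→cM1
  less inhibitory, cM1→SMA facilitatory — the circuit the outcome groups
  differ on). Clinical rows are drawn so that every row relabels to its
  generated condition under the 10%-of-maximum rule.
* **Recovery world** (`make_recovery_instance`): a random sparse
  architecture (4 directed edges, 1 nonlinear with θ↔β cross terms) with
  strong planted couplings (0.5–1.0 s⁻¹) — the regime the biomarker
  story rests on, where a handful of strong connections carries the
  signal. The dense 18-edge world is structurally near-collinear:
  pooled recovery correlation plateaus around 0.75 there even at very
  low noise, versus ≈1.0 noiseless for the sparse design.
* **EEG synthesis** (`simulate_eeg_trials`): each frequency bin
  contributes a sinusoid with amplitude source_amp·(1 + p/100), floored
  at zero, random phase per trial; channels are lead-field mixtures plus
  Gaussian sensor noise. This is one of many time-domain signals
  consistent with a target spectrogram, chosen because the Morlet
  magnitude is linear in amplitude, making the round trip exactly
  checkable. The default lead field is a seeded random matrix with
  unit-norm columns; a geometric (inverse-square distance to idealized
  10–20 electrode positions) mode exists for topography tests, and a
  real gain matrix can be supplied.

What a green synthetic test does **not** establish: realistic volume
conduction (no BEM/FEM head model), realistic artifact structure
(rejection is tested on amplitude outliers only), Morlet-induced
temporal smearing and cross-bin correlation of noise (acceptance noise
is i.i.d. per bin; the measured full-chain spectrogram error is larger
and temporally structured), or between-subject coupling variability of
real cohorts (the study does not characterize it; it is a config
parameter).

## Preprocessing conventions

Zero-phase 4th-order Butterworth band-pass (the band, 4–48 Hz, is the
stated quantity; the realization is ours). Artifact rejection is strict
`>` at 500 µV on any channel/sample; failed movements are a boolean
trial mask in the container, not detected. Baseline correction
(−850 to −800 ms) is percent change by default — subtraction is
available — so that coupling estimates are amplitude-scale free;
analysis window −500 to 800 ms; Morlet number 7, magnitudes (not
squared). The 7-cycle wavelet smooths over ≈190 ms at 6 Hz, so envelope
dynamics faster than that are unresolvable at theta by construction —
the round-trip test states this regime explicitly.

## Classification conventions

Favorable is the positive class throughout. Default logistic fit is
ridge (strength 1.0) on standardized features because the motivating
design has n = 37 subjects and 144 attributes; how the original
analysis regularized is unknown. Cross-validation is stratified 5-fold,
reshuffled over 100 repetitions (SD over repetition means);
standardization is fitted inside each training fold only, and a
leakage probe in the tests verifies that an outlier in a held-out fold
cannot alter training statistics. Backward elimination refits an
*unpenalized* logistic model and removes the largest Wald p-value while
it exceeds α = 0.05 (ties by column order); separable or singular
refits fall back to ridge-IRLS Wald statistics and are flagged in the
trace — under perfect separation Wald statistics are meaningless, so
the procedure is only informative on non-separable data. The
dichotomous-cutoff baseline scans all midpoints in both orientations,
ties to the smallest cutoff.

## Outcome labeling

Favorable iff any of ΔFMA ≥ 6.6, ΔWMFT ≥ 7.5, ΔTEMPA ≥ 16.2 (10% of
each scale maximum; ≥ because reaching the level counts; TEMPA is
negative-scored so improvement is post − pre on both scales). The
packaged table's printed labels are authoritative: the labeler reports
rows that disagree with the re-applied rule (there are two) rather than
overwriting them, and the statistics that are arithmetically
inconsistent with the table itself are reported as discrepancies.
Group t-tests are emitted in pooled and Welch forms, one- and
two-tailed, because the printed p-values are only consistent with
one-tailed pooled tests for some rows.

## Known limitations

* Cross-band and within-band couplings of the *same* edge partially
  alias under a single input event (same-source band trajectories are
  proportional to first order); the aliasing is broken only by coupling
  feedback and band-specific decays, so dense nonlinear networks are
  recovered with shrinkage-limited fidelity (~0.75 pooled correlation)
  while sparse strong networks recover well (>0.8).
* Free energies are Laplace approximations; model comparison is only as
  good as the local optimum found (multi-start is not implemented).
* The pipeline's flip stage runs as the identity on synthetic cohorts
  because the generator already works in the ipsilesional-left frame.
* The clinical table reproduces the printed source, including its
  internal inconsistencies (two label rows, two summary statistics, one
  subgroup count); these are surfaced by the discrepancy reporters.
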