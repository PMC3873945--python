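# Methods

This note documents the models, parameter choices and numerical decisions
behind `ecogdecode`, and what the synthetic-data studies do and do not
establish about real recordings.

## Signal model of the synthetic sessions

The generator emulates a continuous reach-and-return session recorded
from a rectangular ECoG grid over primary motor cortex, sampled directly
at the 500-Hz analysis rate (simulating a higher acquisition rate and
down-sampling would add nothing the pipeline can observe).

**Trajectory.** Cycles of a smooth reach from rest toward a target at
roughly (2, 1.5, 1) arbitrary length units and back, one `sin²` bump per
~5-s cycle (a ~700-s session at 134–248 trials brackets cycle lengths of
roughly 3–5 s; 5 s is used as the default and is configurable). A single
`jitter_sd` fraction (default 0.1) scales every stochastic component:
per-cycle period jitter, per-cycle amplitude jitter, and a small smoothed
additive wander. At `jitter_sd = 0` the trajectory is exactly periodic,
which the tests exploit. Trial-to-trial kinematic variability is
stylized, not calibrated — nothing in the source material quantifies it.

**ECoG.** Per channel `i` and band `b`:

    signal_i = Σ_b carrier_ib · env_ib + σ_n · white_i + σ_cm · common
    env_ib   = max(1 + m·w_b·drive_i(t − lag) + (m/√snr)·η_ib, 0.05)

* `carrier_ib`: unit-variance noise exactly band-limited to band `b`
  (frequency-domain construction), so the band-limitation invariant holds
  by design.
* `drive_i`: a channel-specific unit-norm linear mixture of the
  standardized x/y/z positions and speed, standardized. Channel-specific
  mixtures (rather than one global drive) make the three output axes
  jointly recoverable from several informative channels; any such fixed
  linear functional is within what the linear decoder assumes.
* `w_b ≥ 0`: planted band weights, nonzero only on informative channels;
  `lag` defaults to 0.09 s, inside the decoder's 0.6-s window.
* `m = 0.4`: envelope modulation depth; `snr` is the planted ratio of
  coupled-envelope variance to envelope-noise variance (default 10;
  recovery studies use 25 as the "high SNR" condition).
* `σ_n = σ_cm = 1`: broadband and common-mode noise. The common-mode term
  is on by default so common-average referencing is non-trivial to test.

Everything derives from one root seed (trajectory and ECoG streams are
spawned from it), and carrier/noise draws do not depend on the truth, so
null and planted sessions with the same seed share their noise.

## Preprocessing

* **CAR** requires ≥ 2 channels; referencing a single channel is refused.
* **Band-pass**: 4th-order Butterworth in second-order sections (the
  1.5-Hz delta edge at 500 Hz is numerically delicate in transfer-function
  form), applied forward–backward (`sosfiltfilt`, reflective padding).
  Zero-phase filtering was chosen over causal filtering: it preserves the
  feature/kinematics alignment that the 30–600-ms lag window then models.
* **Envelope**: rectify, then a unit-area Gaussian kernel of 0.1-s total
  width (σ = 0.04 s), truncated at ±0.05 s and renormalized, so DC gain is
  exactly 1.
* **Sliding z-score**: mean/SD over the half-open window `[t − 2 s, t)` —
  strictly before `t`, so the operation is causal; the first 2 s of every
  session are marked invalid and excluded from all fitting and
  evaluation. Windowed moments come from prefix sums of the series
  shifted by the *first window's* mean: the shift tames the
  `E[x²] − μ²` cancellation (a constant series yields exactly 0) without
  referencing future samples. σ is floored at
  `max(σ, 1e-6 · global SD, 1e-12)`; in degenerate (constant) windows a
  numerator at rounding-noise level is written as 0 rather than amplified
  by the floored σ.

## Decoder

* **Lag embedding**: lags k = 1…20 at Δt = 30 ms — the 20 steps exactly
  tile the interval (0, 0.6 s] *before* t, excluding lag 0 (strict
  causality). Rows are taken on a 30-ms stride by default; fitting at the
  full 500 Hz is possible via the stride setting but adds only
  near-duplicate rows.
* **PLS2**: centering only — features are already z-scored and position
  units are meaningful, so no column rescaling. Factors are extracted
  sequentially; the NIPALS inner iteration's fixed point (the dominant
  left singular vector of the residual cross-covariance E'F) is computed
  directly by SVD of the p×3 matrix, which is exact and removes any
  iteration-tolerance sensitivity. Both blocks are regression-deflated;
  the deflated predictor block is never materialized (scores and loadings
  are reconstructed from the originals plus accumulated factors, and the
  cross-covariance is updated by a rank-one identity), cutting the
  per-factor cost to two passes over the design matrix. On full-rank
  problems with all factors the fit reproduces least squares; scikit-learn
  serves as an independent cross-check in the tests, never as the
  implementation.
* **Model selection**: blocked 10-fold CV on contiguous temporal segments
  (shuffled folds would leak autocorrelated neighbors), scored by PRESS
  summed over held-out samples and axes. Training rows within one
  *feature horizon* — normalization window (2 s) + lag span (0.6 s) +
  envelope smoothing (0.1 s) — of the held-out block are embargoed: such
  rows share raw data with held-out rows, and without the embargo purely
  spurious factors can appear to validate. The selected count is the
  smallest whose PRESS is within 1% of the curve minimum, capped at 20
  (the cap mirrors the fixed choice used on the original recordings,
  where PRESS plateaued near 20). The curve additionally records the
  PRESS of the zero-latent (training-mean) predictor; if no latent count
  beats it, zero latent variables are selected and the decoder is the
  intercept alone. This implements "stop adding latent variables as soon
  as PRESS increases" at the bottom end and is what keeps the
  zero-coupling control honest: with ~5 760 collinear features and only a
  few dozen independent reach cycles, even one forced latent variable
  carries spurious held-out R² of order −0.2.
* The latent count is selected **once, on the full model**, and reused
  (capped by feasible rank) for every restricted fit — single-electrode,
  top-k, per-band — matching how the analysis it reimplements fixed the
  count after a single full-model CV.
* **R²** is the coefficient of determination `1 − SS_res/SS_tot` about
  the evaluation segment's own mean, not a squared correlation; negative
  held-out values are reported as-is.

## Electrode selection

Location-based groups take whole columns in order of distance from the
central sulcus; within a partially-used column, electrodes fill from the
lateral end inward (informative sites concentrate laterally; the order is
configurable, not hidden). Performance ranking breaks ties by ascending
channel id. Both methods use the same split and latent policy as the full
model, so both endpoints (all electrodes) coincide exactly — identity
restrictions return the identical design arrays to keep that equality
bitwise.

## Study conditions and problem sizes

The recovery studies in the tests and in `scripts/acceptance.py` run the
full-scale feature space — 32 channels on a 4×8 grid at 500 Hz, nine
bands, 20 lags at 30-ms stride (5 760 features) — with five seeds per
study; the session lengths are the package's desk-scale choice, and every
other condition is the full-scale one. Planted-truth studies
(10 informative channels with γ2/γ3/γ4 weights at snr 25 for electrode
recovery; γ3-only coupling for band recovery) use 150-s sessions (100 s
train / 45 s test). The zero-coupling control uses 300-s sessions (200 s
train / 90 s test): with only ~20 training cycles, a slow noise feature
can align with the quasi-periodic target across the entire training
segment by chance, and cross-validation — correctly, given what it can
see — accepts it; ~40 cycles make the zero-latent selection robust. This
is a small-sample property of short segments, not a pipeline defect, and
it vanishes toward the full 500-s training scale.

## Known limitations

* The generator's envelope coupling is band-coherent and spectrally flat
  within each band. One consequence: slicing a wide coupled band into
  10-Hz sub-bands yields several independent envelope estimates of the
  same drive, so the fractionized band set can decode *better* than the
  physiological set here — the reverse of what real recordings show. The
  band-set comparison operation is provided, but the synthetic studies
  cannot adjudicate that real-data claim.
* Narrow low-frequency bands (δ at 2.5 Hz width) carry large intrinsic
  envelope-estimation noise at 0.1-s smoothing; planted δ coupling is
  recoverable only at high SNR.
* No artifact rejection, line-noise filtering or bad-channel handling —
  the analysis chain this package reimplements used none, and the
  generator produces none of those defects.
* Passing recovery tests show the pipeline recovers planted linear
  envelope coupling; they say nothing about nonstationarity, cross-channel
  correlation structure, or electrode-density effects in real cortex.
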