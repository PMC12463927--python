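# Methods

`eegdtf` implements a complete resting-state EEG group-comparison pipeline of
the kind used in clinical studies of mild cognitive impairment (MCI) versus
normal controls (NC): band-specific power spectral density, directed
connectivity via the directed transfer function (DTF), surrogate-data
significance thresholding, and a two-group statistics layer with effect sizes
and false-discovery-rate control.  Because clinical EEG datasets of this kind
are rarely public, the package includes a first-class synthetic two-cohort
generator with known ground truth; every downstream stage is validated
against that truth.

## Preprocessing

A recording (32 channels, 10–20 montage) passes through:

1. **Common average reference** — subtract the cross-channel mean at every
   sample.  Note this makes the data exactly rank-deficient (channels sum to
   zero); see *Numerical choices*.
2. **Optional artifact hook** — ICA-based artifact removal requires manual
   component labelling and is inherently irreproducible from a written
   description, so the pipeline exposes a pass-through hook where a caller
   can inject their own cleaning function; by default nothing happens here.
3. **Zero-phase bandpass**, 1–30 Hz Butterworth of order 4 applied
   forward–backward (effective order 8, zero group delay).  No order is
   standard in the literature; 4th order is steep enough at 30 Hz without
   ringing.
4. **Epoching** into non-overlapping 5-s windows (a 5-minute recording gives
   60 epochs); the trailing remainder is discarded.
5. **Baseline correction** — per-epoch, per-channel mean subtraction.  In
   continuous resting data the only available baseline is the epoch itself;
   whether such correction should instead be applied to the continuous
   record is ambiguous, and the per-epoch reading was chosen.

## Spectral analysis

Welch PSD with 2-s Hamming segments and 50% overlap (0.5 Hz resolution,
≥3 segments per 5-s epoch), averaged over all epochs.  Band power is the
**mean** PSD over in-band bins — scale-free across frequency resolutions, and
group comparisons are invariant to the mean-versus-integral choice.  Band
edges are half-open, [lo, hi), so the 4 Hz bin belongs to theta, not delta.
Bands are delta 1–4 Hz, theta 4–7 Hz, alpha 8–13 Hz.  Absolute (not
relative) power is used.

## MVAR and the directed transfer function

Per epoch, the channels X(t) are modelled as a vector autoregression of
order p (default p = 2, selectable by BIC),

    X(t) = Σ_{n=1..p} A_n X(t−n) + e(t),

estimated by ordinary least squares on stacked lagged regressors.  With
Ā(f) = I − Σ_n A_n e^{−i2πfn/fs}, the spectral transfer matrix is
H(f) = Ā(f)^{−1} and the normalized DTF is

    γ²_ij(f) = |H_ij(f)|² / Σ_m |H_im(f)|²,

the share of total inflow into target i originating from source j; each
target row sums to 1 at every frequency (asserted to 1e-10 in tests).  The
scalar edge weight DTF_Mean averages γ² over the in-band frequencies of the
1–30 Hz grid (0.5 Hz steps) and then over epochs ("dynamic" connectivity:
one MVAR per 5-s epoch, averaged, rather than one model for the whole
recording).

**Surrogate significance.**  Each channel is independently
phase-randomized (uniform random phases; DC and Nyquist bins kept real, so
the amplitude spectrum is preserved exactly and the output is real), the
MVAR/DTF computation is repeated, and the per-edge threshold is the order
statistic at rank ⌈(1−α)·n⌉ of the surrogate DTF_Mean distribution — with
1000 surrogates and α = 0.05, the 950th sorted value.  Edges not strictly
above their threshold are set to 0 (ties conservatively non-significant).
The null is built on the epoch-averaged DTF_Mean (one null per
subject–edge–band), matching the statistic being thresholded.

## Statistics

Per electrode×band (power) or directed-edge×band (DTF_Mean after
thresholding): Shapiro–Wilk normality in both groups and Levene's variance
test (centered on the mean, as in SPSS) route the comparison to a
pooled-variance Student t with Cohen's d, or otherwise to Mann–Whitney U
with exact Cliff's delta.  Effect signs are positive when MCI > NC.
Benjamini–Hochberg FDR is applied separately within each band×metric family
(32 electrodes for power; 32×31 directed edges for DTF_Mean), matching
per-band reporting.  The gate alpha for routing is 0.05.  Pooled (not
Welch) t and uncorrected (not Yates) chi-square are used, which reproduce
the printed cohort-table statistics of the emulated study design
(t = 9.28 for MoCA, χ² = 0.595 for sex).  Pearson correlations between
per-subject edge strength and MoCA are computed across all subjects pooled;
raw p-values are reported and the multiplicity family for correlations is
left to configuration.

## Synthetic cohorts

Each channel is a sum of one latent oscillator per band plus white noise
(default SD 1.0 against unit-variance oscillators).  Oscillators are damped
AR(2) resonators with poles at radius 0.98 and the band-centre frequency —
inside the MVAR model family, and concentrating ≥70% of 1–30 Hz power
in-band (delta 0.91, theta 0.73, alpha 0.82; a radius of 0.95 leaves the
resonance too broad for the alpha band).  Group effects:

* **Band-power effects**: multiplicative amplitude factors on chosen
  electrodes for one group.
* **Directed couplings**: the target channel receives `strength` × the
  lagged **observed** source channel.  An earlier design mixed in only the
  source's latent band oscillator, but that makes the target a second,
  independent measurement of the oscillator, so the target's past genuinely
  improves prediction of the source — a real reverse-direction information
  flow that defeats direction recovery (measured forward ≈ reverse DTF).
  Coupling the observed channel keeps the reverse edge exactly zero and the
  forward edge representable by a finite-order MVAR.  The latent variant is
  retained as `mode="oscillator"` for cross-correlation-level tests.
* **MoCA scores** per group (defaults NC 26.70 ± 1.38, MCI 19.91 ± 2.98,
  clipped to [0, 30]), optionally linked linearly to a subject's realized
  coupling strength so the correlation stage can be tested for sign
  recovery.

What the generator does **not** emulate: head-volume conduction and common
sources (each channel's background is independent), 1/f broadband structure,
non-stationarity, and ocular/muscular artifacts.  Passing tests therefore
demonstrate that the estimators recover known effects under the model's own
assumptions — not that real-EEG confounds (volume conduction above all) are
handled.

## Numerical choices

* **Rank deficiency after average referencing**: the Gram matrix of the
  lagged regressors is exactly singular.  Pipeline entry points apply a tiny
  relative ridge (1e-10 of the mean Gram diagonal) before solving; the
  public `fit_mvar` defaults to exact OLS and raises a singular-fit error
  instead (condition number guard at 1e12).  BIC uses `slogdet` with a
  1e-12 jitter for the same reason.
* **BIC**: ln det Σ̂ + k²p ln(N)/N over candidate orders, unstable fits
  excluded, ties to the smallest order.
* **Stability**: companion-matrix spectral radius < 1.  The surrogate loop
  skips the eigenvalue check (cost) and instead redraws non-finite fits
  under a retry budget.
* **Transfer function**: frequencies where cond(Ā(f)) > 1e12 raise an
  error naming the frequency.
* **Thresholding ties**: strictly greater than the threshold survives.
* **Determinism**: every stochastic stage takes a `numpy` Generator or
  seed; cohort generation spawns per-subject child seeds, so results are
  reproducible and independent of subject count ordering.  The surrogate
  loop draws in fixed-size chunks of 20 so its random stream does not
  depend on batching.

## Problem sizes used in validation

The validation studies (`eegdtf.validation`, also driven by
`scripts/acceptance.py`) run at the package's demo scale, chosen so the full
suite runs on a laptop-class single core: recovery cohorts of 20 subjects
per group, 20-s recordings at 125 Hz (4 five-second epochs), 100 surrogates
per subject, connectivity analysed in the alpha band; surrogate calibration
at k = 8 channels, 12 epochs, 200 surrogates, pooled over 5 independent
datasets (280 directed edges).  The defaults of the library itself remain
the emulated study's scale (5 minutes at 250 Hz, 60 epochs, 1000
surrogates).

## Known limitations

* DTF on scalp data cannot rule out volume-conduction-driven spurious
  edges; the generator does not model them, and the package performs no
  source-space correction.
* The per-epoch MVAR assumes within-epoch stationarity.
* The surrogate null preserves each channel's amplitude spectrum but not
  cross-channel amplitude covariation.
* The routing gate (Shapiro–Wilk/Levene) has limited power at n ≈ 20; the
  Mann–Whitney fallback is the safe default in that regime.
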