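# Methods

`headnet` implements a season-long dose-response analysis for contact-sport
cohorts: cumulative head-impact exposure is scored from sensor kinematics,
inhibitory control from Flanker/Stroop logs, and whole-brain functional
connectivity from pre/post resting EEG; exposure is then related to pre/post
connectivity change, and the brain-behavior relationship is modeled with a
behavioral partial-least-squares (PLS) correlation. A synthetic cohort
generator provides data with known planted structure so every stage can be
validated end to end.

## Exposure scoring

Each recorded accelerative event carries peak linear acceleration (PLA, g),
peak rotational velocity (PRV, rad/s) and peak rotational acceleration
(PRA, krad/s²). Events are kept if video-confirmed and PLA > 16 g (the
sensor's trigger floor, strict). Because the three kinematics are strongly
interdependent, severity is summarized by a principal-component composite:
kinematics of all confirmed impacts are pooled across athletes and
z-transformed (ddof = 1), the covariance of the z-data (equivalently the
correlation matrix of the raw data) is eigendecomposed, and the per-impact
principal component score is

PCS_i = Σ_k (λ_k / Σλ) · (z_i · v_k),

the eigenvalue-weighted sum of the impact's projections on the principal
axes. wCHI is the sum of an athlete's PCS values; nHI is the plain count
(a magnitude-free sensitivity variant run through the same downstream code).
Design choices: pooling across the whole cohort is the only choice that
makes wCHI comparable between athletes; eigenvector signs are fixed by a
non-negative PLA loading so larger scores mean more severe impacts; athletes
with no confirmed impacts are retained at wCHI = 0 (zero-exposure athletes
belong in the dose-response sample). Mean-centering forces ΣPCS = 0 over
the pooled dataset, so wCHI is a relative, unitless quantity.

## Interference scoring

Trials with RT < 30 ms or > 3000 ms are removed (strictly outside; boundary
values retained). Accuracy is computed on retained trials. The weighted
reaction time is wRT = mean RT × (1/ACC%) × 100, i.e. mean RT divided by
the proportion correct — accuracy enters as a percentage so the two factors
of 100 cancel; this is the only reading that reproduces group-scale wRT
values a few percent above mean RT. The interference index is
wRTI = wRT(incongruent) − wRT(congruent) for the Flanker and
wRT(block 3) − wRT(block 1) for the Stroop (block 2 is scored but unused).
Higher wRTI = more interference.

## EEG preprocessing

1. Band-pass 1–50 Hz: cascaded Butterworth high-pass (≤ 1 dB loss at 1 Hz,
   ≥ 10 dB attenuation at 0.25 Hz) and low-pass (≤ 1 dB at 50 Hz, ≥ 10 dB at
   60 Hz), orders chosen by `buttord` to meet those single-pass specs, then
   applied forward–backward. Zero-phase filtering is deliberate: phase
   distortion would bias phase-lag connectivity.
2. Non-overlapping 2-s epochs (fs × 2 samples), per-epoch linear detrend,
   trailing remainder discarded.
3. Artifact screening is automatic (manual visual screening and ICA are not
   reproducible): robust z-scores of per-channel and per-epoch log-variance
   against the median/MAD, threshold |z| > 4. Flagged epochs are dropped,
   flagged channels spherically interpolated; more than 5 contaminated
   channels flags the subject for exclusion.
4. Spherical splines (order m = 4, ridge λ = 1e-5, Legendre series truncated
   at 50 terms) are used both for bad-channel interpolation and for the
   surface-Laplacian reference-free transform (kernel order m − 1, no
   constant term, hence exactly invariant to adding a common reference
   signal). Interpolation precedes the Laplacian.
5. Global field power (GFP = Σ channels Σ samples x², µV²) is computed per
   epoch and the 40 epochs closest to the median GFP are kept, preserving
   temporal order; ties broken toward earlier epochs; the median with an
   even count is the midpoint of the central pair.

## Spectra and connectivity

Multitaper spectra use DPSS tapers on 2-s epochs with ±3 Hz smoothing:
time–half-bandwidth NW = 2 s × 3 Hz = 6 and K = 2NW − 1 = 11 tapers (the
standard taper count at a given bandwidth). Coefficients are retained at 99
bins, 1–50 Hz in 0.5 Hz steps. Power is the taper- and epoch-averaged
one-sided density; normalized SPD is percent of the channel's mean power
across the 99 bins (so each channel's SPD averages to exactly 100%). Bands:
delta 1–4, theta 4.5–7, alpha 7.5–15, beta 15.5–30, low gamma 30.5–50 Hz,
inclusive on the 0.5 Hz grid.

Connectivity pools epochs × tapers as observations (440 at the design size
of 40 × 11; pooling maximizes debiasing stability). Coherence is magnitude
squared, |⟨S_xy⟩|²/(⟨S_xx⟩⟨S_yy⟩). The debiased weighted phase-lag index
uses the imaginary cross-spectrum I_j = Im(S_xy) per observation:

dWPLI = [(Σ I_j)² − Σ I_j²] / [(Σ |I_j|)² − Σ I_j²],

defined as 0 when the denominator vanishes (all I_j = 0, e.g. identical
signals). Slightly negative estimates are retained — clipping would bias
band means. Imaginary parts within 1e-12 of the cross-spectrum magnitude
are treated as exact zeros (rounding in fused complex products otherwise
contaminates the degenerate zero-lag case). Because it discards the real
part, dWPLI is invariant to instantaneous real mixing of independent
sources, whereas coherence is inflated by it — the core reason dWPLI is the
primary measure for scalp data.

Significance of each pair × frequency cell comes from a surrogate null:
per surrogate, each channel's amplitude series (the continuous
concatenation of the 40 selected epochs) is split at a uniform random index
in [0.1N, 0.9N] and both halves are order-reversed, independently per
channel; the surrogate is re-epoched and passed through the identical
estimator. The transform preserves each channel's amplitude histogram
exactly while destroying cross-channel phase alignment. A cell is
suprathreshold if it exceeds the 95th percentile of its surrogate
distribution. Whole-head band averages are reported in two modes —
`survivors-mean` (mean over suprathreshold cells only) and `zeroed-mean`
(subthreshold cells set to 0, mean over all cells) — because "average the
suprathreshold values" is genuinely ambiguous; outputs are always labeled
with the mode. The dose-response analyses in `analysis/` use `zeroed-mean`:
with survivors-mean the fluctuating count of ~5% false-positive survivors
enters the denominator and, at desk-scale channel counts, that denominator
noise swamps a planted effect confined to a few cells; zeroed-mean keeps
the summary linear in the signal.

## Graph metrics

Band-averaged thresholded dWPLI matrices (subthreshold and negative
survivors set to 0) define weighted graphs on channels. Path-based metrics
map weights to lengths as 1/w. Characteristic path length is the mean
weighted shortest-path distance over ordered pairs (disconnected pairs
excluded, with their count logged); global efficiency is the mean inverse
distance (disconnected pairs contribute 0); mean clustering is the
geometric-mean-of-triangle-weights coefficient on max-normalized weights
(degree < 2 nodes contribute 0); betweenness is the fraction of shortest
paths through a node (normalized by (n−1)(n−2)/2) and the network summary
is its maximum. A `binarize` flag supports the literal unweighted reading
of path metrics.

## Dose-response and PLS

Post − pre deltas per athlete are tested against wCHI (or nHI) with Pearson
correlations: two-sided p from the t distribution (n − 2 df), Bonferroni × 5
across the five bands (capped at 1), and a 500-draw percentile bootstrap
95% CI over subject resampling. Percentile (not BCa) is the minimal
bootstrap-CI construction; degenerate resamples are redrawn.

The behavioral PLS stacks, per condition (pre, post), the Pearson
correlations of each behavior column (SCWIT wRTI, FIT wRTI) with each brain
column (dWPLI pairs × 99 bins, COH pairs × 99 bins, SPD channels × 99 bins;
37422 + 37422 + 2772 = 77616 columns at 28 channels) into a 4 × p matrix R,
and decomposes R = U S Vᵀ. Each LV's covariance share is s_k²/Σs². LV signs
are fixed so the dominant behavior-salience entry is positive (SVD signs
are otherwise arbitrary and scalp-score directions would be irreproducible).
Permutation p-values shuffle the subject assignment of behavior rows within
condition (the conservative exchangeability unit that preserves the
condition structure) and count permuted singular values at or above the
observed. Bootstrap resampling draws subjects with replacement (both
sessions of a subject move together); each resample's saliences are
Procrustes-rotated onto the original behavior saliences before averaging;
the bootstrap ratio is the mean aligned salience over its bootstrap SE,
with |ratio| > 1.96 flagged reliable. Scalp scores are the projection of an
observation's brain row on a brain salience (multiplying by the singular
value would rescale, not reorder, subjects, so the plain projection is
used); the pre→post scalp-score change is tested against wCHI with the
dose-response machinery. A non-rotated mode (`contrast_pls`) projects R
onto supplied orthogonal contrast weights for confirmatory hypotheses.

## Synthetic cohorts

`headnet.synthetic` generates the study conditions: 18 athletes × 2
sessions, 500 Hz eyes-closed EEG (5-min default), ~78 confirmed impacts
per season (Poisson counts at rate 78/18 per athlete), and the full task
designs (200 Flanker trials, 3 × 120 Stroop trials; single-trial RTs
lognormal with shape 0.2 around condition means taken at group scale).
Impact kinematics share one latent lognormal severity factor (loading 0.8)
plus independent lognormal noise, with PLA floored at 16 g — reproducing
both the heavy tails and the inter-measure correlation that motivates the
PCA composite.

EEG channels carry independent 1/f^β noise (β = 1 by default; the realized
log-log PSD slope matches β within fit tolerance). A coupling injects a
shared 4th-order-Butterworth band-limited oscillation into both channels of
a pair, the second copy delayed by the requested phase lag at band center
via an exact Fourier fractional delay, so the true lag is known and a π/2
lag yields dWPLI near 1 at high strength. Volume conduction is modeled as
an instantaneous real mixing matrix (used to demonstrate the COH/dWPLI
contrast). One master seed fans out to per-subject substreams; identical
seeds give bit-identical cohorts.

The planted dose effect sets the post-season slow-band (delta by default)
coupling strength to base + slope × wCHI plus per-subject noise
(sd 0.15 per session), other bands unchanged. The slope can be calibrated
from the realized wCHI spread so the population exposure → Δstrength
correlation hits a target (0.7 in the reproduction runs):
slope = √2·σ·r/(sd(wCHI)·√(1−r²)). An optional behavior link adds
150 ms × Δstrength to the post-season Flanker incongruent mean RT, creating
a slow-band brain-behavior LV whose expression is dose-linked.

What the generator does not emulate: realistic scalp topographies or
forward-model mixing beyond one linear matrix, non-stationarity, ocular or
cardiac artifacts, per-athlete playing-time differences, or any
biomechanical head model. Passing tests therefore show the estimators and
inference machinery recover known structure under the stated statistical
assumptions — not that the pipeline is robust to every failure mode of real
recordings.

## Problem sizes in tests and reproduction runs

The shipped analysis scripts and the reproduction script use 8 EEG channels
and 120 s per recording at 500 Hz with 25 surrogates per null, and the PLS
uses 500 permutations / 200 bootstraps; full-geometry runs (28 channels,
5 min, 1000 surrogates, 1000/500 resamples) use the same code paths via
flags. End-to-end recovery at this scale: the recovered delta-band
dose-response r tracks each cohort's realized planted correlation with
attenuation ≈ 0.95 (estimation noise plus mild saturation of the
dWPLI-vs-strength response), and the mean over replicate cohorts lands
within ±0.1 of the 0.7 target.

## Known limitations

* PLS bootstrap ratios are anticonservative as null-hypothesis tests: with
  null data, |ratio| > 1.96 flags ~10–12% of columns at n = 18 (and ~8–9%
  even at n = 100) rather than 5%. Two mechanisms: the bootstrap SE of a
  correlation slightly underestimates its sampling sd at small n, and the
  SVD adaptively selects behavior weights, biasing every column's salience
  away from zero — Procrustes alignment preserves that adaptive bias
  (sign-only alignment is conservative instead). Ratios should be read as
  stability diagnostics, not calibrated z-tests; the acceptance suite
  documents the measured rate.
* The split-reverse surrogate preserves within-channel autocorrelation only
  approximately near the split points.
* The dWPLI-vs-coupling-strength response saturates toward 1, so Pearson
  dose-response correlations are mildly attenuated for strong planted
  effects.
* Characteristic path length silently restricts to connected pairs; on very
  sparse thresholded bands this can make values incomparable across
  subjects (the survivor count is logged for this reason).
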