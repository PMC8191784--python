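# Methods

## Generative model

The synthetic-data generator treats a molecule as a continuous-time Markov
chain (CTMC) over a small set of conformational states. A
`KineticScheme` holds the state labels, a rate matrix of transition rates
k_ij (s⁻¹, off-diagonal), and per-state FRET emission parameters (mean in
[0, 1], width in FRET units). State paths are exact Gillespie realizations:
in state s the waiting time is Exponential(Σ_j k_sj) and the next state is
drawn proportionally to k_sj. A state with zero exit rate is absorbing.
Unless a start distribution is given, paths start from the stationary
distribution of the rate matrix (solved by linear algebra), so pooled
censuses carry no equilibration transient.

Rendering to camera frames uses exact within-frame occupancy weighting: for
frame f of length Δt, Ē_f = Σ_s w_fs μ_s with w_fs the fraction of the frame
spent in state s. This is what makes "fast interconversion averaged within a
frame" representable, which the cross-correlation screen probes. Emission
jitter with sd Σ_s w_fs σ_s is added to Ē_f, then

- acceptor = I_tot · E_f + bg_A + N(0, σ_ch²)
- donor = I_tot · (1 − E_f) + bg_D + N(0, σ_ch²)

Photobleaching, when enabled, draws a single exponential bleach time (the
earlier of the two fluorophores; both channels drop together); the bleach
frame is scaled by its surviving fraction and later frames carry background
plus noise only. Blinking, spectral crosstalk, gamma factors and camera
image formation are deliberately out of scope.

Defaults: 50 ms frames (100 ms as the slow variant), 600 frames per trace,
total intensity 1000 counts, emission jitter 0.05, demo four-state FRET
means 0.35 / 0.48 / 0.92 / 0.92 for U / I / F / F* — the two folded states
share a FRET level and are distinguishable only kinetically. Trace length
and bleach statistics are chosen for testability, not to match any
particular instrument.

Seeding: a dataset's master seed is split per trace with
`numpy.random.SeedSequence(seed).spawn`, a counter-based splittable scheme,
so datasets are bitwise reproducible across platforms and individual traces
can be regenerated independently.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on —
exponential dwells, stationary occupancies, frame averaging, anticorrelated
channels, single-step bleaching, additive Gaussian channel noise. It does
not emulate intensity heterogeneity between molecules, acceptor blinking,
drift, baseline wander, or non-Gaussian EMCCD noise. Passing recovery tests
therefore demonstrates the correctness of the estimators under the stated
model, not robustness to every instrumental pathology of real data.

## FRET computation and QC

E = I_A/(I_A + I_D) per frame, uncorrected for gamma (a proximity ratio).
Background is subtracted per channel, either as user-supplied constants or
as the post-bleach mean of each channel (requires a detected bleach frame
and ≥ 10 post-bleach frames). Frames are masked — never clipped — when the
total intensity is at or below a floor (default 0), when E falls outside
[−0.2, 1.2] (bleach/blink artifacts), or after the bleach frame. Masked
frames are excluded from every downstream statistic.

Bleach detection is a two-segment change-point on total intensity (SSE
minimization), with significance = drop > 5 × robust noise sd (noise
estimated from median absolute first differences, insensitive to the step
itself); binary segmentation to depth 2 flags multi-step traces. QC
accepts a trace when it has ≥ 100 valid pre-bleach frames, at most one
bleach step, and — only if its channels vary beyond noise (sd > 2 × robust
noise sd) — a donor–acceptor Pearson correlation ≤ 0. The anticorrelation
test is restricted to dynamic traces because for a static molecule the
channel correlation is a coin flip around zero; common-mode drift, by
contrast, is dynamic and positively correlated, and is rejected. All
thresholds are configurable (`QCRules`).

## Population analysis

Histogram values are either one value per molecule (mean of the first 10
valid frames; shorter traces are dropped and counted) or all valid frames
within the first 30 s pooled across molecules — the latter for label
geometries whose state FRET values are too close for per-molecule averages.

Mixtures are fitted by EM on the raw values (10 restarts, |ΔlogL| < 1e-8,
up to 2000 iterations, variance floor sd ≥ 1e-3), not least squares on
binned counts; a bin-level histogram export exists for parity with
histogram-fitting workflows. Components are reported sorted by mean, and
population percentages are the mixture weights.

By default all components share one width (a "tied" mixture). At constant
total intensity the width of every population's peak is set by the same
channel/shot noise, and the shared width removes a real identifiability
failure: with a small population ~2–3 sd from a dominant one, a
free-variance EM can grow one component wide and absorb its neighbour's
weight. Free per-component widths remain available (`covariance="free"`).
Model order is user-fixed or selected by BIC over k ∈ {1..4}.

Welch's unpaired two-sided t-test (`compare_means`) compares mean FRET
between conditions.

## HMM idealization

`FretHMM` wraps a Gaussian-emission HMM (hmmlearn) fitted by Baum–Welch:
k-means-initialized restarts (10 by default, best final log-likelihood
kept), |ΔlogL| < 1e-6, ≤ 500 iterations, and a hard emission-variance floor
(sd ≥ 1e-3) applied after every M-step — plain maximum likelihood
otherwise (no covariance prior), so the k = 1 fit equals the sample
mean/sd exactly and the log-likelihood history (retained in full) is
non-decreasing. Masked frames are treated as missing by splitting each
trace into contiguous valid segments that enter the fit as independent
sequences. States are sorted by ascending mean. Fitting is per trace or
pooled across the molecules of a condition; pooled mode is used for rate
summaries because single traces carry too few transitions. Viterbi decoding
returns the MAP state per valid frame.

The fitted transition matrix is in transitions per frame;
`transitions_to_rates` multiplies by the frame rate and warns when any
p_ij > 0.2/frame, where the linear conversion visibly underestimates the
true rate.

## Dwell-time kinetics

Dwells are maximal runs of one (optionally lumped) state label; the default
lumping is {U, I} → unfolded vs {F} → folded, so unfolded-class dwells end
in folding events and vice versa. Durations are frame counts × Δt (minimum
one frame; no sub-frame imputation). Dwells touching a trace boundary or a
masked gap carry explicit left/right censoring flags.

Rate estimation is mono-exponential:

- drop policy: k̂ = n/Σt over boundary-free dwells (the spec-level default;
  least assumptions, but biased upward when traces are short relative to
  1/k because long dwells are preferentially censored);
- censored MLE: right-censored dwells (no exit observed) contribute
  exp(−k t) survival terms, giving the closed form k̂ = n_events/Σt_all. A
  left-censored dwell that ends in an observed transition is a complete
  exponential sample by memorylessness and counts as an event — treating
  first dwells as survival-only would discard up to a quarter of the
  folding events on slow-folding datasets and bias the rate down by the
  same order.
- histogram least squares: A·exp(−kt) fitted to binned counts (bin = 2
  frames), for parity with histogram-based fitting.

stderr = k̂/√n_events throughout.

For the pooled folding/unfolding pair the frame-quantized estimates are
mapped back to continuous time through the exact two-state relation between
the per-frame transition matrix and the CTMC generator (the matrix
logarithm, closed-form for two states): with p_uf = k̂_fold Δt and
p_fu = k̂_unfold Δt,

k_tot = −ln(1 − p_uf − p_fu)/Δt, split as k_fold : k_unfold = p_uf : p_fu.

The correction vanishes for rates ≪ frame rate and is essential at
p ≈ 0.13/frame, where the naive estimate is ~15% low. Events faster than
one frame remain unobservable (missed-event correction is out of scope);
the residual bias from merged sub-frame dwells is a few percent at
k ≈ 0.14 × frame rate and is the dominant remaining error there.

## Cross-correlation screening

C(τ) = Σ_t δI_D(t) δI_A(t+τ) / [(n − |τ|) σ_D σ_A], the biased normalized
estimator, with a two-sided Gaussian null band z_{1−α/2}/√(n − |τ|)
(α = 0.01 default). Segments shorter than 4 × max_lag are refused, not
padded. The verdict is "dynamics" iff C(0) < −band and the anticorrelation
persists beyond lag 0: either C(1) < −band (switching faster than the frame
time leaks correlation only into the first lag, with lag-1/lag-0 ratio
(1−e^{−a})²/(2(a−1+e^{−a})) for a = k_tot Δt) or |C| beyond the band at ≥ 2
consecutive positive lags (slower hidden dynamics). On static noise the
false-positive rate is far below α because two independent exceedances are
required.

## SHAPE normalization

Three steps per lane: subtract the lane's gel background (an empty gel
region); divide every band by the same lane's band at the invariant
reference position (59 by default); divide each position by its value in
the reference condition (0 mM MgCl₂), which is therefore exactly 1
everywhere. Negative post-background intensities clamp to 0 with a flag
(faint bands near background are expected); a reference band at or below
background is an error naming the lane. Normalization is invariant to
per-lane rescaling by construction. An optional no-reagent control lane can
be subtracted band-wise (off by default). Replicate tables combine as
per-cell mean and standard error (n − 1 denominator). Band quantification
from gel images is upstream and out of scope.

## Pipeline and provenance

`run_pipeline` executes simulate → FRET/QC → histogram + mixture → pooled
HMM → kinetics from a single YAML/JSON config that is schema-validated
(unknown keys rejected) before any stage runs. All randomness flows from
one master seed; outputs include a provenance record (config hash, package
version, per-stage parameters, QC counts). A stage failure aborts with the
stage name and leaves a `failed` marker.

## Problem sizes used in the shipped tests

Rate recovery runs 300 traces × 600 frames at 20 Hz per condition (≈ 1400
folding events at the slow endpoint, ≈ 4000 at the fast one), enough that
the Monte-Carlo stderr of each recovered rate is 1.5–3%. The population
recovery draws 1000 per-molecule values; mixture invariants use 100 seeded
replicates of 500 values (BIC selection) and 20 replicates of 3000 values
(weight recovery). These sizes were chosen so each check is decisively
powered while the whole suite stays desk-scale.

## Known limitations

- No gamma/crosstalk correction: reported E is a proximity ratio, not an
  absolute efficiency.
- No missed-event (blur) correction: rates approaching the frame rate are
  underestimated by the fraction of sub-frame dwells, even after the
  discretization inversion.
- The tied-width mixture default assumes comparable emission widths across
  populations; genuinely heterogeneous widths need `covariance="free"`.
- The HMM assumes Gaussian emissions and first-order Markov dynamics;
  non-Markovian kinetics (e.g. static heterogeneity between molecules)
  will be averaged into the pooled rates.
- QC's anticorrelation rule is skipped for static traces, so a static
  common-mode artifact with no high-frequency noise signature can pass.
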