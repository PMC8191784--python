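# fretfold

Single-molecule FRET trajectory analysis for RNA folding pathways, with a
matching SHAPE gel-quantification module. `fretfold` implements the full
analysis chain used to characterize riboswitch aptamer folding — e.g. the
U ↔ I ↔ F ↔ F\* pathway of an adenine riboswitch aptamer, where an unfolded
(U), intermediate (I), ligand-free folded (F) and ligand-bound folded (F\*)
conformer are distinguished by FRET level and kinetics — and a synthetic-data
generator that emulates the measurement so every stage of the inference can
be validated by parameter recovery.

It is written for single-molecule biophysicists who have donor/acceptor
intensity trajectories (or want realistic simulated ones) and need
population decompositions, idealized state paths, and folding/unfolding
rates with uncertainties.

## What it computes

**FRET efficiency.** Per frame, the uncorrected proximity ratio

E = I_A / (I_A + I_D)

after per-channel background subtraction, with photobleaching detection,
artifact masking (E outside [−0.2, 1.2]) and molecule-level QC
(anticorrelation of donor and acceptor over dynamic segments, single bleach
step, minimum length).

**Population histograms.** Per-molecule values (mean of the first 10 frames
of each trace) or cumulative frame pooling over the first 30 s, decomposed
into populations by a maximum-likelihood Gaussian mixture

p(E) = Σ_k w_k N(E; μ_k, σ²)

with EM, BIC model selection, and population percentages reported from the
mixture weights. Conditions are compared with Welch's unpaired t-test.

**Idealization and kinetics.** A Gaussian-emission hidden Markov model
(Baum–Welch + Viterbi), fitted per trace or pooled across the molecules of
a condition; the fitted transition matrix is in transitions per frame, so
k_ij = p_ij × (frame rate). State dwell times, lumped as {U, I} → unfolded
vs F → folded, are fitted with a mono-exponential decay,

survival(t) = exp(−k t),

by maximum likelihood with proper right-censoring of boundary dwells and an
exact two-state correction for frame discretization.

**Hidden-dynamics screening.** The normalized donor–acceptor
cross-correlation C(τ) of single-state segments, with a Gaussian
significance band: genuine sub-resolution switching shows a negative
zero-lag peak decaying as exp(−(k₁+k₂)|τ|Δt).

**SHAPE reactivities.** Gel band intensities are background-subtracted,
normalized per lane to an invariant reference position (59 by default), and
scaled so the reference condition (0 mM MgCl₂) is exactly 1; replicates are
combined as mean ± SE.

**Synthetic data.** A continuous-time Markov chain over conformers
(Gillespie), rendered to camera frames with exact within-frame occupancy
weighting, per-state emission jitter, Gaussian channel noise and single-step
photobleaching.

## Worked example

Simulate 100 molecules of a two-state folder (k_fold = 0.84 s⁻¹,
k_unfold = 0.64 s⁻¹, FRET 0.35/0.89, 50 ms frames) and run the whole
pipeline from the bundled config:

```bash
fretfold run examples/demo_run.yaml out/demo
```

which writes traces, the population mixture and the rate estimates. With
the bundled seed the mixture (`out/demo/mixture.json`) is

```
mean 0.396  sd 0.072  weight 51.4%
mean 0.866  sd 0.072  weight 48.6%
```

— two populations near the generating FRET means, with weights near the
stationary occupancies (0.43/0.57; 10-frame averaging of switching traces
blurs both slightly) — and the recovered kinetics (`out/demo/rates.json`)
are

```
k_fold:   0.852 +/- 0.026 1/s  (n=1059 dwells)
k_unfold: 0.642 +/- 0.020 1/s  (n=1058 dwells)
```

against generating truths of 0.84 and 0.64 s⁻¹.

The same recovery across a monovalent-salt series (folding accelerating
0.19 → 2.7 s⁻¹ while unfolding stays near 0.84 → 0.64 s⁻¹):

```bash
fretfold reproduce-fig3 --seed 1 --n-traces 60
```

```
 nacl_mM  true_k_fold  recovered_k_fold  true_k_unfold  recovered_k_unfold
     0.0     0.190000          0.167895           0.84            0.822076
    50.0     0.323054          0.294933           0.80            0.750018
   100.0     0.549285          0.573397           0.76            0.758745
   150.0     0.933942          0.861818           0.72            0.692349
   200.0     1.587968          1.535214           0.68            0.674267
   250.0     2.700000          2.537200           0.64            0.651771
```

The folding rate spans ~14× across the series while the unfolding rate
changes by less than 25%.

Every stage is also available as a library (`fretfold.simulate_dataset`,
`fretfold.FretHMM`, `fretfold.folding_unfolding_rates`,
`fretfold.fit_mixture`, `fretfold.normalize_shape`, …) and as individual
subcommands (`fretfold simulate / fret / hist / hmm / kinetics / ccf /
shape`).

## Documentation

See `docs/methods.md` for the generative model, estimator derivations
(censored dwell MLE, frame-discretization inversion, tied-width mixtures),
default parameters and known limitations.
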