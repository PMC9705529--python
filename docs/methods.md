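# Methods

`dynmodnet` implements a dynamic modular brain-network analysis for
condition comparisons on ROI-level, band-limited EEG time series: per-trial
sliding-window WPLI connectivity, multilayer-modularity community
detection, module-allegiance metrics, and a paired statistical battery.
This note documents the models, the tunable parameters, the synthetic
ground-truth generator, and the numerical and design choices a maintainer
should know about.

## Signal conditioning

For users starting from continuous recordings, the front end applies a
5th-order Butterworth band-pass (0.3–50 Hz), a 2nd-order IIR notch at
60 Hz (Q = 30), epoching around stimulus events (−1 s to +2 s, with the
2 s post-onset sub-window used for analysis), and an alpha-band (8–13 Hz)
zero-phase band-pass. All filters run forward–backward (`sosfiltfilt`):
phase estimates downstream must not be biased by filter delay, so the
effective order is doubled. Artifact rejection is deliberately out of
scope; externally cleaned data can enter the pipeline at the epoch or ROI
stage.

## Connectivity: weighted phase lag index

For signals x, y in a window, with analytic signals obtained by Hilbert
transform of the band-limited series,

    WPLI = | Σ_t Im S_xy(t) | / Σ_t | Im S_xy(t) |,    S_xy = x_a conj(y_a).

Only the imaginary (lagged) part of the per-sample cross-spectrum enters,
so zero-lag (volume-conducted) coupling is invisible by construction. The
0/0 case (identical, zero-lag, or null signals) is defined as 0 — zero
evidence of lagged interaction — using a relative floor of 1e−10 on the
summed |Im| so that floating-point residue of exactly zero-lag pairs does
not produce spurious values. A debiased-squared estimator is available
behind a flag (`debiased=True`) but off by default.

The analytic signal is computed once over the full 2 s analysis segment
and then sliced per window, avoiding per-window Hilbert edge transients.
Windows are 300 ms with 50% overlap; trailing samples not covered by a
full window are dropped, so a 2 s trial at 500 Hz gives exactly 12 layers.

**Known property — short-window bias.** With 8–13 Hz signals and 150-sample
windows, any two *independent* narrowband processes hold a nearly stable
phase offset across a window, so the plain WPLI of uncoupled pairs is far
above zero (≈0.5–0.7 here). This is a property of the estimator at this
window length, not an implementation artifact; module structure is
recoverable only because coupled pairs sit consistently higher. Analyses
of real data with these parameters inherit the same bias floor.

## Multilayer modularity and generalized Louvain

Each trial's 12 WPLI matrices are the intralayer weights of a multilayer
graph; node i in layer l couples to itself in layers l±1 with uniform
strength ω (ordinal coupling). The quality function is

    Q = (1/2μ) Σ_{ijlr} [ (A_ijl − γ k_il k_jl / 2m_l) δ_lr + δ_ij ω adj(l,r) ] δ(g_il, g_jr)

with per-layer Newman–Girvan null (resolution γ), intralayer strengths
k_il, layer totals 2m_l, and 2μ the sum of all node-layer strengths
including interlayer couplings. The optimizer is a generalized Louvain
heuristic on the dense supra-modularity matrix: greedy single-vertex moves
over seeded random permutations (first-found best gain, gain threshold
1e−12 to break ties deterministically; moving to an empty community —
going solo — is always a candidate), followed by aggregation into
super-vertices, repeated until no move improves Q. Runs are deterministic
given a seed; ensembles of R runs draw child seeds from one base seed via
`numpy.random.SeedSequence`. Labels are canonicalized to 1..K by first
appearance, and all downstream metrics are invariant to relabeling.

A brute-force oracle (`exhaustive_max_modularity`) enumerates every set
partition of up to 13 node-layer vertices via restricted growth strings
and is used to verify that best-of-100 heuristic restarts reach the global
maximum on random small graphs.

**Parameter defaults.** γ = 1 and ω = 1, the standard choices for
temporal multilayer analyses at ~80-node scale. ω must be judged relative
to intralayer node strengths: an 80-node WPLI graph has strengths ~40–60,
so ω = 1 is a gentle persistence prior, but a 12-node graph has strengths
~5–8, where ω = 1 overwhelms the intralayer structure and freezes labels
across layers (estimated flexibility collapses to ~0). Desk-scale runs
therefore use ω = 0.1 (`demo_config`), about a tenth of typical strength,
and the package records γ and ω with every run. R defaults to 500
repetitions; R = 50 is sufficient for metric stability at desk scale and
is used in the bundled analyses.

## Metrics

For a partition g (node × layer) and T windows, per-node **flexibility**
is F = S/T where S counts consecutive-window label changes; the maximum is
(T−1)/T (11/12 here). The alternative T−1 denominator found in parts of
the literature is *not* used. Ensemble values average F over repetitions.

**Module allegiance** P[i,j] is the fraction of (repetition, layer)
observations in which i and j share a module — pooling over both
repetitions and layers uses every observation; a per-layer variant is
available (`layer_allegiance`). **Recruitment** of a system is the mean
allegiance among its node pairs (self-pairs excluded); **pairwise
integration** of two systems is the mean allegiance between their node
sets; **overall integration** is the unweighted mean of the six pairwise
values among SMN, DMN, VN and ATN. Raw co-occurrence probabilities are
reported — no permutation-null normalization — matching the probabilistic
definition of the metrics. **Node-to-system density** is the mean
connectivity weight between a node and a target system's nodes across
windows. "Others" nodes participate in graphs but are excluded from
system summaries. Percent change between conditions is 100·(post−pre)/pre,
computed between per-condition trial means when trial counts differ.

## Statistics

Two-tailed paired t-tests compare per-trial metric values between
conditions (trials paired by index when counts match; repeats can be
pre-averaged by a grouping column). All units tested for one metric within
one contrast form a single Benjamini–Hochberg FDR family (α = 0.05).
Effect sizes are Cohen's dz = mean(diff)/SD(diff) with the n−1 SD.
Normality is checked with an Anderson–Darling test (estimated mean and
variance, case-3 correction A*² = A²(1+0.75/n+2.25/n²), the standard
piecewise-exponential p approximation; validated against a simulated null
in the tests). Post hoc power for the paired t uses the noncentral t
distribution with ncp = dz·√n and df = n−1 — dz = 0 recovers exactly α.
Pearson correlation against an ordinal experience code (experienced = 1,
rudimentary = 2, naive = 3) comes with a Fisher-z 95% CI. Report tables
mark *p<0.05, **p<0.01, ***p<0.005.

## Synthetic generator

The generator emulates the study conditions — 80 nodes, 2 s trials at
500 Hz, alpha band, 20 trials per condition — and plants a module schedule
that downstream stages must recover:

* **Schedule.** Window 1 is a balanced random partition into K modules; at
  each later window every node resamples its module uniformly with its
  system's switch probability p (so the realized change rate is
  p·(K−1)/K). Planted flexibility is computable exactly from the schedule.
  An optional cross-system co-module probability plants elevated
  integration between chosen systems.
* **Carriers.** Each module owns one continuous, unit-amplitude
  phase-diffusing oscillator (Brownian phase, 0.25 Hz Lorentzian
  linewidth) at a module-specific frequency spaced evenly inside the band
  (8.5 and 12.5 Hz for K = 2). Distinct per-module frequencies model
  distinct individual-alpha peaks of separate assemblies and are what
  makes uncoupled pairs *detectably* uncoupled at 300 ms windows: their
  phase difference rotates through full cycles within a window and the
  WPLI washes out, whereas a shared-frequency design leaves uncoupled
  pairs at the bias floor (~0.7), indistinguishable from coupled ones.
* **Lags.** Within each (window, module), members receive the carrier at
  lags spaced evenly over [−3π/8, +3π/8], so every co-module pair differs
  by a lag bounded away from 0 and π and is visible to WPLI. (Independent
  random per-node lags were tried first and rejected: they leave a
  sizeable fraction of co-module pairs nearly zero-lag, hence invisible.)
  A fixed scalar lag is available for controlled two-node tests; exact
  zero-lag specifications are rejected.
* **Transitions and noise.** Membership changes are cross-faded with
  complementary raised-cosine ramps (≤20 ms). Per-node noise is white
  Gaussian filtered into the carrier band, at noise_sd = 0.15 of the
  carrier amplitude by default — a deliberately favorable SNR, because
  in-band noise itself exhibits the WPLI short-window bias and higher
  levels bury the planted contrast. The generator validates recovery; it
  does not stress-test robustness at realistic SNR.
* **Determinism.** All randomness flows from one seed through documented
  `SeedSequence` splitting (one child per trial); identical (config, seed)
  reproduce bit-identical arrays.

**What passing tests show — and don't.** The generator produces
narrowband, phase-coupled signals with planted modular dynamics, but not
1/f background, amplitude bursting, volume conduction, artifacts, or
inter-subject variability. Recovery of planted effects here demonstrates
that the estimation chain is correct and sensitive under clean conditions;
it does not guarantee sensitivity on real EEG at lower SNR.

## Problem sizes in the bundled analyses

The analysis scripts and validation runs use a 12-node roster (three nodes
per system: SMN, DMN, VN, ATN), K = 2 planted modules, base switch
probability 0.4 (halved for DMN in the "Stim-Move" condition), 50 trials
per condition, R = 50 repetitions, ω = 0.1, γ = 1. Under these conditions
the planted DMN flexibility decrease is detected (paired t, BH-FDR 0.05)
in 20/20 seeded replicates, with the other three systems serving as
negative controls. The 80-node default configuration runs the identical
code path and is exercised for shape and contract correctness.

## Known limitations

* The bundled 80-node table assigns AAL cortical regions to large-scale
  systems from the general functional literature; it is an editable
  stand-in, not a study-specific parcellation, and every metric accepts a
  user-supplied `SystemMap`.
* Plain WPLI at 300 ms windows carries a large positive bias for
  uncoupled narrowband pairs; consider the debiased variant or longer
  windows when absolute connectivity levels matter.
* γ and ω materially shape flexibility estimates; results should be
  reported with the values used (the pipeline records them in
  `config.json`).
* ICA artifact rejection, source localization, and channel-level
  simulation are out of scope.
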