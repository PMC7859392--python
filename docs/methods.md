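# Methods

This note documents the models, defaults and design choices behind
`banditflame`, and what the synthetic-data tests do and do not establish.

## Task environment

The restless three-armed bandit pays integer points in [1, 100].  Arm `a`'s
latent mean follows a mean-reverting (decaying) Gaussian random walk

    μ[t+1, a] = λ μ[t, a] + (1 − λ) θ + ε_t,   ε_t ~ N(0, σ_d²),

with realized payoffs `round(μ[t, a] + η_t)`, `η_t ~ N(0, σ_p²)`, clipped
to the payoff range after rounding.  Defaults follow the canonical
restless-bandit lineage: λ = 0.9836, θ = 50 points, σ_d = 2.8, σ_p = 4,
200 trials.  The stationary distribution of the walk is
N(θ, σ_d²/(1 − λ²)) — sd ≈ 15.5 points — and initial means are drawn from
it so early and late trials are exchangeable.  Clipping (not reflection)
handles the rare boundary excursions; ties between arms are allowed.

The walk's autocorrelation time is long (≈ 1/(1 − λ) ≈ 60 trials), so a
200-trial session contains only a handful of effectively independent
observations of each arm's level.  Consequences used throughout: the grand
mean of a single structure has an SE of ≈ 5 points around θ, and Monte-Carlo
checks of stationarity must average over structures, not trials.

## Agents

Agents generate synthetic behavior with known explore/exploit structure;
they are simulation devices, not models fitted to data.  The delta-rule
softmax agent updates `Q[a] += α (r − Q[a])` and samples from
`softmax(β Q)`; β is the inverse decision temperature in 1/points (β = 0 is
uniform choice).  Variants add a count-based exploration bonus
`b/(1 + n_a)` before the softmax, or ε-greedy lapses.  The uniform random
chooser defines chance-level earnings: 1000 simulated choosers per reward
structure, grand mean per-trial payoff reported.

## Trial classification

Arms are ranked each trial by latent mean (ties to the lower index); "best"
is judged on the objective walk mean, never the noisy payoff, since payoff
noise is observation noise.  For each trial t ≥ 1 (trial 0 is
unclassifiable):

- stay on the best arm → exploitation; stay on a non-best arm → non-best stay;
- switch: if the destination's cumulative selection count over trials
  0..t−1 is (tied-)minimal across arms → directed exploration, else random
  exploration.  Counting ties as directed is the generous-to-directed
  reading of "least selected".

The value-based alternative marks only best → second-best switches as
directed, both ranks evaluated at the switch trial (ranks drift slowly, so
adjacent-trial rank evaluation almost never differs).  Exploit runs are
maximal stretches where the chosen arm is the current best; a run breaks
when the choice changes *or* the chosen arm loses best rank.  The mean run
length includes length-1 runs by default (`min_run_len=2` restricts to
continuous selection proper, as the notion is ambiguous); shift counts are
raw counts per session.

On this task family, earnings versus decision noise form an inverted U:
extreme exploiters cannot track the drifting means, so the maximum sits at
moderate sharpness (temperature ≈ 3–4 points) and earnings collapse only at
the noisy end.  The classic negative random-exploration/earnings
correlation is therefore asserted cohort-level over the operating range of
human-plausible temperatures, not as global monotonicity.

## Synthetic cohort

Defaults emulate a 19-control / 45-patient case–control study.

- **Shared walks.**  All subjects in a cohort play the same pre-generated
  walk instantiation (the common practice for this task family), so group
  contrasts reflect behavior rather than per-subject walk luck; independent
  walks are available via `shared_structure=False`.
- **Latent inflammation score** L ~ N(shift_group, 1), shift 0.5 for
  patients.  Softmax temperature = group base + 1.5·L (bases 3 and 8
  points, floored at 0.5); log hsCRP = group shift (0.7) + 0.7·L + N(0,
  0.6²).  This single linear link couples hsCRP, disorganization and random
  exploration; the magnitudes were calibrated once so the within-patient
  Spearman correlation between hsCRP and random-exploration counts sits
  near 0.4 at n = 45 and the control group's random-exploration count sits
  near 23 per session.
- **Immune panel.**  16 markers on a log2 scale drawn from
  N(5 + shift·group, Ω⁻¹) with a sparse chain-plus-hub precision Ω over the
  group-shifted markers (partial correlations ≈ 0.3); 11 markers carry
  ±0.55–1.0 log2 group shifts, three are null, and two sit ~90% below their
  LOD to exercise exclusion.  Censoring is recorded as a mask; raw values
  are kept so the preprocessing stage performs the substitution.
- **Clinical covariates** are drawn to match the study's descriptive
  statistics (BMI 23.4 vs 26.4, education 14.4 vs 12.3 years, PSP 97 vs 52,
  antipsychotic dose log-normal around 500 mg/day equivalents, etc.).
  PANSS items come from a five-factor model with the disorganized factor
  loading 0.6 on L.

What the generator does *not* emulate: assay-specific normalization
internals, non-Gaussian marker marginals, item-level PANSS rater effects,
and any direct causal path from inflammation to choice other than the
linear latent link.  Passing recovery tests therefore show the pipeline
detects the modelled coupling at study scale — not that real data carry it.

## Statistics

Normality gating uses Shapiro–Wilk at α = 0.05, per group for group tests
(both groups must pass for Student's t; otherwise Mann–Whitney U) and per
variable for correlations (Pearson vs Spearman).  Cohen's d always uses the
pooled-SD formula, including alongside U statistics, so effect sizes are
comparable across the gate.  Partial correlations residualize both
variables on the covariates (with intercept) and correlate residuals; the
Spearman variant rank-transforms first; p values use t with n − k − 2 df.
Covariate-adjusted group effects come from OLS `marker ~ group +
covariates` with dummy-coded categoricals.  Benjamini–Hochberg is the
standard step-up with monotonicity enforcement; the Bonferroni threshold
for the three focal immune–behavior markers is 0.05/3 (displayed 0.017).
The composite cognitive score averages the two subtest z-scores anchored to
the control group (sample sd, n − 1), making the control mean exactly 0.
Panel cleaning decides exclusion (> 80% below LOD, computed after dropping
QC-failed subjects) on the raw censoring mask before substituting remaining
censored cells with the marker LOD; the operation is idempotent.

## Network estimation

Columns are standardized; the binary group node enters as 0/1 with Pearson
(point-biserial) correlation — deterministic, at the cost of ignoring the
node's discreteness.  The graphical lasso runs over 100 log-spaced
penalties from λ_max (largest absolute off-diagonal correlation) down to
λ_max/100; the model minimizes EBIC

    −2 ℓ(Θ) + E log n + 4 E γ log p,   γ = 0.5 (configurable),

with E the number of nonzero upper-triangle edges.  Setting the penalty to
zero reproduces the closed-form sample partial correlations exactly, which
the tests verify against both the precision-matrix identity and the
regression-residual construction.  Centrality: strength Σ|w|, closeness and
betweenness on distances 1/|w| (closeness is per-component in disconnected
graphs and flagged).  The bootstrap resamples subjects with replacement,
re-estimates the full path per replicate (percentile 95% CIs; B = 1000
default, B = 200 with a 30-point replicate grid in the pipeline — the EBIC
optimum is broad so coarsening the replicate grid barely moves the
intervals), and calls two edges or nodes "different" when the CI of their
bootstrap difference excludes zero.  Replicates with constant columns or
non-convergence are dropped; more than 5% drops is an error.

## Pipeline and reproducibility

One root seed fans out via `numpy.random.SeedSequence` to per-stage child
seeds, so cohort generation, agent simulation, network layout and bootstrap
are each independently reproducible and the whole run is bit-identical
under a fixed config.  The manifest records the package version, a SHA-256
config hash, and per-stage row counts.  Stage order: cohort → trial
classification → panel cleaning → gated statistics → network → within-
patient immune–behavior correlations restricted to the three markers most
associated with group, at the 0.05/3 threshold.

## Problem sizes

Defaults were chosen to keep a full study-scale analysis interactive on one
CPU: 64 subjects × 200 trials simulate in under a second; the 13-node EBIC
path fits in ~1 s; a B = 200 bootstrap runs in ~1–2 min.  The test suite
uses 20-seed replicate designs for recovery/power properties and
10,000-sample draws for distributional oracles.

## Known limitations

- The agent family is delta-rule learning; it cannot reproduce human
  earnings levels at matched exploration rates (humans track the walks
  better), so group separations in points are smaller than in real cohorts.
- Bootstrap intervals are percentile, not BCa; no case-dropping stability
  coefficient is computed.
- The value-based classifier's rank evaluation at the switch trial is one
  of two defensible readings of "switching from the best option".
- LOD substitution-at-LOD is a crude imputation; censored-likelihood
  approaches are out of scope.
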