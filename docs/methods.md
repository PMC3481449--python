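# Methods

## Model and procedure

The package treats gene regulation as a first-order discrete dynamical
system on a ternary alphabet: each gene's level at time t+1 (down −1,
basal 0, up +1) is statistically determined by the levels of a small
set of predictor genes at time t. Inference is per-target feature
selection: for each target Y, find the predictor subset **X** (size ≤
kmax) minimizing the biological score BS(Y,**X**) = E·w1 + P·w2, then
pool the winning predictor–target pairs over all targets into one
network.

E is the penalized mean conditional entropy of the aligned
(predictors-at-t, target-at-t+lag) samples. Aligned tuples containing
the not-observed code are dropped; if none survive, the target is
skipped. With N samples, k predictors, observed states x (count n_x,
empirical conditional entropy Ĥ(Y|x), base 2, divided by log₂3 so the
uniform ternary distribution scores 1) and M = 3^k − #observed states:

    E = (α·M + Σ_x n_x·Ĥ(Y|x)) / (α·M + N).

Charging every unobserved state the maximal normalized entropy 1 with
weight α expresses maximal uncertainty about states never seen, and
grows with 3^k — the guard against over-large predictor sets when the
series has only a few dozen time points. α is exposed
(`PenaltyConfig.alpha`, default 1); α = 0 recovers the unpenalized mean
conditional entropy. A variant that also down-weights states observed
exactly once exists in the literature; it is deliberately not enabled —
the single α knob keeps the penalty auditable.

P is the fraction of predictors without a prior edge to the target.
This is the simplest [0,1], minimization-compatible form consistent
with a weighted-sum integration: it reduces to a pure support indicator
at k = 1, and at w2 = 1 it makes prior-supported subsets strictly
dominate, which is the behavior a "prior only" endpoint must have.
Genes absent from the prior count as unsupported. The prior never
restricts candidacy — every other gene remains a candidate predictor;
the prior only shifts scores.

Auto-relationships are excluded by construction (a target is never its
own candidate). Inferred predictor→target links are stored undirected
because the reference networks used for evaluation (protein–protein,
fusion-based, pathway/annotation co-membership) are undirected pair
sets; edge direction would be unverifiable against them.

## Search

Per cardinality k = 1..kmax the best subset is sought with Sequential
Forward Floating Selection: greedy inclusion of the best-scoring
addition, then conditional backward exclusions that fire only while the
reduced subset strictly improves on the best subset already known at
that smaller size. The implementation primes the search with a pure
greedy-forward pass, so the returned size-k score is never worse than
plain sequential forward selection; exclusions may continue down to
size 1. The global answer is the best value over cardinalities under
strict improvement, so the smallest cardinality wins exact ties.

All ties — within forward/backward steps and across cardinalities — are
broken by (score, subset size ascending, lexicographic gene order).
This makes the entire pipeline a deterministic function of its inputs;
there is no randomness anywhere in inference or evaluation.

SFFS is a heuristic: with target size 2 the floating step cannot fire
below size 3 except as a pure revert, so the search returns the best
pair *containing the best singleton*, which is not always the global
best pair (a pair of individually uninformative, jointly informative
predictors — an XOR-type rule — defeats it). The tests therefore check
equality with exhaustive enumeration exactly on instances where the
optimum is provably reachable, and the weaker dominance guarantees
everywhere.

## Evaluation

Networks are compared over all unordered pairs of distinct genes in an
evaluation universe, by default the gold standard's gene set
(config-overridable). PPV = TP/(TP+FP), Sensitivity = TP/(TP+FN),
Similarity = √(PPV·Sensitivity); ratios with zero denominator score 0,
keeping Similarity defined and conservative when nothing is inferred.

The weight sweep evaluates w2 ∈ {0, 0.2, …, 1} (w1 = 1 − w2); reported
curves are raw metric values, with per-curve min–max normalization to
[0,1] available alongside (constant curves map to 0). Normalization is
a presentation device for comparing gain *shapes* across gold standards
with very different base rates; conclusions about absolute performance
must use the raw curves, which every report includes.

Hub evaluation scores only the subnetwork of the ⌈0.10·n⌉
highest-degree genes and every edge incident to at least one hub
(degree ties broken by gene id), with the hub-incident genes as the
universe. Hub count rounding (ceiling) and the tie rule are
implementation choices — any fixed deterministic rule works; these make
small fixtures exactly predictable.

## Preprocessing defaults

| parameter | default | meaning |
|---|---|---|
| h, l | +0.5, −0.5 | quantization thresholds on the standardized signal (dimensionless, units of σ) |
| min_observed | 25 | minimum observed time points per gene |
| missing code | 3 | not-observed marker in quantized data |
| α | 1.0 | entropy penalty weight per unobserved state |
| lag | 1 | dynamics offset between predictors and target |
| kmax | 3 | maximum predictor-subset size |
| w2 grid | 0, 0.2, …, 1 | biological-information weights swept |
| hub fraction | 0.10 | share of genes counted as hubs |

Standardization uses population moments over observed points (the
transformation is defined through expectation and standard deviation as
moments, not sample estimators; `ddof` is switchable). The threshold
branches overlap at α = h and α = l; the extreme branches take
precedence, a measure-zero choice that makes the mapping total.
Symmetric thresholds at ±0.5σ give roughly 38% basal calls on Gaussian
signals; they are configuration, not dogma, and every experiment report
echoes the values used. kmax = 3 keeps the 3^k conditional tables
estimable at ~48 time points; the benchmark studies use kmax = 2 for
the same reason at T = 40.

## Synthetic benchmark

`generate_truth` draws a preferential-attachment (Barabási–Albert)
graph — heavy-tailed degrees, a few hubs — assigns each gene up to 3 of
its neighbors (random subset, seeded) as regulators, and draws an
arbitrary deterministic ternary update table per gene. `simulate_dynamics`
iterates from a random ternary initial state; with probability `noise`
per gene per step the rule output is replaced by a uniform draw, so
noise interpolates from fully deterministic (0) to independent of the
regulators (1). `corrupt_prior` deletes each true edge with the
false-negative rate and inserts non-edges with per-pair probability
calibrated so the expected insertion count is fp_rate·|edges|.

Default conditions for the benchmark study: 30 genes, 40 time points,
noise 0.05, kmax 2, prior corruption 0.2/0.2 where a corrupted prior is
called for, five replicate seeds. These sizes keep a full weight sweep
in tens of seconds while leaving the inference genuinely fallible
(expression-only PPV ≈ 0.8, not 1.0), so gains from the prior are
measurable rather than saturated.

What the generator does *not* emulate: periodic transcriptional
programs (no cell-cycle-like oscillation is imposed), microarray noise
spectra or dye effects, missing-data patterns (simulated series are
fully observed; missingness is exercised separately in unit fixtures),
and directed or signed regulation semantics beyond the arbitrary
ternary tables. Passing benchmarks therefore demonstrate correctness of
the machinery and qualitative behavior of the integration weight — not
performance on real microarray data.

## Numerical and degenerate-input choices

* Entropies via `scipy.stats.entropy` on count vectors; 0·log 0 = 0.
* Exact float comparison plus lexicographic tie-breaks in the search;
  no tolerance is injected (scores reaching equality through distinct
  arithmetic paths are treated as distinct unless bit-equal, which the
  deterministic evaluation order makes reproducible).
* Constant-expression targets are skipped with a warning (their
  conditional entropy is 0 for any predictor, which would draw
  arbitrary edges); constant genes are likewise dropped at
  quantization, where they cannot be standardized.
* Weight-grid duplicates are removed and the grid sorted before
  sweeping; each w2 is evaluated once.
* The weight sweep shares one (E, P) component cache across grid
  points — scores are re-weighted, never recomputed, so sweep results
  are identical to independent per-w2 runs.

## Known limitations

* SFFS suboptimality as described above; exhaustive search is
  exponential and deliberately out of scope beyond the test oracles.
* The prior penalty ignores edge confidence; all prior links count
  equally.
* Evaluation is undirected; a method recovering correct regulators with
  wrong direction is indistinguishable from one recovering direction.
* Negative priors (known non-interactions) are not supported.
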