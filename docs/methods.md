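# Methods

This note documents the models, estimators, numerical choices and known
limitations of `phylogcn`. It is the package's own account of its science;
every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Trees and distances

Trees are rooted, with branch lengths in expected nucleotide substitutions
per site; polytomies are allowed everywhere. Newick I/O goes through
dendropy; internally trees are flat parent/child arrays. Pairwise patristic
distances use an Euler-tour + sparse-table LCA structure, so the million
pair queries of the autocorrelation estimator are O(1) each after an
O(n log n) build. Branch lengths absent from a newick source are read as 0;
wherever an algorithm divides by a branch length, zero lengths are replaced
by ε = 1e-8 substitutions/site (`phylogcn.EPSILON`). How the original
analyses handled zero-length edges is not documented anywhere we know of;
the ε policy is this package's choice and is applied uniformly.

## The synthetic study conditions

All experiments run on generated data; the defaults (`SimConfig`) define
one fixed regime, chosen once:

* **Tree**: pure-birth, N = 2000 tips, rescaled so the root-to-tip depth is
  0.5 substitutions/site — pair distances then span roughly 0–1, the range
  over which 16S copy-number autocorrelation has been observed to decay.
  A birth–death variant (d < b) is available; extinct lineages are pruned
  and unary nodes suppressed.
* **Trait**: an equal-rates (ER) Markov chain on states 1..15, matching the
  observed range of 16S copy numbers. For the ER chain every non-constant
  eigenmode decays at α = λS/(S−1), so the tip-pair correlation at
  patristic distance d is exp(−αd) regardless of how states are scored.
  The default rate solves exp(−α·0.15) = 0.5 analytically — the trait's
  correlation halves by 15% substitutions/site, the decay scale reported
  for real 16S copy numbers. Branch evolution is sampled exactly (keep the
  parent state with probability e^{−αt}, else redraw uniformly), not by
  time discretisation. A reflected ±1 random walk on 1..S (rate λ to each
  admissible neighbour; uniform stationary distribution; identical to the
  S = 2 ER chain) is provided as a second, more gradual trait model.
  Neither model is claimed to be the true generative process of copy-number
  evolution; they supply a trait with a known, tunable autocorrelation.
* **Coverage mask**: 50% of tips keep their trait value. The default
  `clade_drop` policy removes whole clades, drawing each dropped clade's
  size log-uniformly (capped at half the remaining excess) so that both
  shallow singletons and deep clades disappear. This reproduces a broad
  NSTD spectrum: at seed 42, 49.2% of tips end up further than 15%
  substitutions/site from the nearest known tip and 45.8% further than 30%.
  `random` masking (i.i.d. retention) is available for comparisons.
* **Communities**: 50 samples × 2000 reads. Per sample, ~7.5% of OTUs are
  drawn present, weighted log-normally (μ = 0, σ = 2), and reads are
  multinomial. To emulate the real-world gradient between well-covered
  (e.g. host-associated) and poorly covered environments, each sample gets
  a bias β ~ U(0, 8) and OTU presence probabilities are tilted by
  exp(−β·NSTD); samples with above-median β are labelled "proximal", the
  rest "distal". β = 0 recovers the unbiased model. This gradient is what
  spreads community NSTIs (0–0.44 at seed 42) and is the only part of the
  generator that looks at the coverage mask.

What the generator does **not** emulate: 16S sequence evolution, primer and
PCR bias, OTU clustering artifacts, tree estimation error, and the
phylogenetically clumped sampling of real reference databases. Passing
tests therefore show that the estimators and algorithms behave correctly
under a known trait process on a correct tree — not that real copy numbers
follow an ER chain.

## Reconstruction methods

All five methods interpolate exactly: a tip with known trait is returned
unchanged. Predictions live in [1, S].

* **Sankoff parsimony** (`mpr_ae`/`mpr_pr`/`mpr_exp`): dynamic programming
  with cost vectors; unknown tips contribute zero vectors. The downward
  pass combines each node's subtree costs with rest-of-tree costs, giving
  the minimal total cost conditional on every node's state; the MPR set of
  an unknown tip is the argmin set of that vector (1e-9 relative
  tolerance), and the point prediction is its arithmetic mean (a
  `min_state` tie policy is available). The three cost functions — 1,
  |i−j|, e^{|i−j|} — are the simplest monotone instantiations of the named
  schemes; the exact cost formulas used by existing software are not
  published, so numeric agreement with it is not claimed.
* **Mk-ER maximum likelihood**: Felsenstein pruning with the ER closed-form
  transition kernel (an O(S) update; no matrix exponentials) and per-node
  scaling. The rate is maximised in log-space by L-BFGS-B within
  [1e-6, 1e3]/mean-branch-length, one moment-matching start (invert the
  two-tip identity probability at the mean sampled pair distance) plus four
  seeded random restarts, ftol 1e-8. The root prior is the empirical state
  frequency among known tips. Marginal posteriors at all nodes come from an
  exact outside pass (prefix/suffix sibling products); for the reversible
  ER chain this equals rerooting at each node with the prior carried along.
  If all known tips share one state the rate is pinned at the lower bound
  and flagged (`MkFit.at_boundary`).
* **PIC**: upward inverse-branch-length-weighted fusion restricted to
  known-data subtrees; each fused node carries an inflated effective branch
  length ℓ₁ℓ₂/(ℓ₁+ℓ₂). Polytomies are resolved internally into zero-length
  right-ladders (fusion of independent estimates is associative, so node
  estimates do not depend on the resolution order); unknown tips inherit
  the estimate of their nearest ancestor **in the original tree**, which
  keeps predictions invariant to child order.
* **WSCP**: the objective Σ (x_p − x_c)²/ℓ is a tree-structured
  positive-definite quadratic; one upward Gaussian-elimination pass reduces
  every subtree to an equivalent observation (mean, precision), the root is
  the precision-weighted mean, and a downward substitution recovers all
  node values. This is exact on polytomous trees directly, so no resolution
  is performed. Unknown tips take their parent's optimum (their own edge
  term is then zero).
* **Subtree averaging**: flat arithmetic mean of known descending tip
  values per node; unknown tips inherit from the nearest ancestor with any
  known descendant.

Correctness is established against independent oracles: exhaustive
enumeration over all ancestral assignments (Sankoff costs exactly; Mk
likelihood and marginals to 1e-8) and a generic numeric minimiser of the
WSCP quadratic (1e-6), plus closed-form small-tree examples for PIC and
subtree averaging.

## Estimators

**ACF.** `trait_acf` samples N ordered tip pairs uniformly with replacement
among known tips (desk-scale default N = 1e6), bins them into equal-width
distance intervals over [0, max sampled distance], and computes the Pearson
correlation within each bin over the symmetrised pair set with bin-local
means. Whether the original analyses used equal-width or equal-count bins,
or sampled with replacement, is unstated; these defaults were chosen for
simplicity. Bins with zero trait variance are flagged undefined (NaN), not
dropped. **Caveat**: on a single 2000-tip trait history the binned
correlations carry clade-level realization noise of order ±0.1 at mid
distances (a few deep ancestors dominate those bins), plus a small downward
bias from centring on realized bin means. More pair samples do not reduce
either term; averaging over independent trait histories does. The ensemble
closed form exp(−αd) is therefore tracked tightly only where many
effectively independent clades contribute — the estimator itself is
verified against a direct recomputation on a finite pair set.

**NSTD.** Two passes (rootward minimum over subtrees, leafward propagation
with sibling exclusion via the two smallest child contributions), linear
time, verified against the brute-force all-pairs minimum to 1e-10. When two
prediction sets carry different calibration sets, an item's effective NSTD
is the arithmetic mean of the two values.

**R².** `coefficient_of_determination` is 1 − SS_res/SS_tot, asymmetric
(first argument is explained by the second) and possibly negative; zero
reference variance raises an error rather than returning NaN. Pearson r²
is a separate function and the two are never interchanged. NSTD-binned R²
uses bins [kw, (k+1)w) and omits bins with fewer than 10 items (defaults:
w = 10% for genome-style, 5% for OTU-style comparisons).

## Experiments

**Cross-validation.** Per repeat, 2% of known tips are hidden (drawn
without replacement; the test set is shared across cutoffs within a repeat,
which reduces between-cutoff variance); per cutoff c the training set
excludes all known tips whose minimum distance to the test set is below c
(set-distance reading). Cells with an empty training set or constant test
truth are flagged and skipped, not fatal; the default grid is 0–0.4 in
steps of 0.05 with 3 repeats. With 1000 known tips this gives 20-tip test
sets, so individual R²cv values carry substantial sampling noise (spread of
roughly ±0.25 at cutoff 0 across seeds); the decay of the curve is the
robust signal, and is additionally asserted as a seed-averaged trend.

**Community comparison.** Per sample, OTUs with ≥1 read and predictions
from both methods enter; R² uses raw predicted copy numbers (a log option
exists), NSTI weights the averaged NSTDs by relative abundance. Samples
with <2 eligible OTUs or zero variance are flagged and excluded from
trends. The NSTI–R² trend is a Pearson correlation with a permutation P
value, P = (b+1)/(m+1) over m = 1000 shuffles of the R² vector — the +1
convention avoids zero P values; its null calibration is verified to be
uniform in the test suite.

**Correction.** Read counts are divided by predicted copy numbers (all
predictions must be ≥1; OTUs with reads but no prediction are an error),
optionally renormalised to relative cell abundances summing to 1.

## Reproducibility

Every generator and every stochastic stage derives its random stream from
a single integer seed via named substreams (CRC32 of the stage name into a
`SeedSequence` spawn key), so the full pipeline is a pure function of
(config, seed); rerunning any driver or the acceptance script with the same
seed reproduces outputs byte for byte. CLI outputs carry a `#` header with
tool version, subcommand, parameters and seed.

## Known limitations

* The two acceptance-level stochastic checks inherit desk-scale noise: the
  single-realization ACF cannot be pinned to the ensemble closed form
  within ±0.05 in every bin (see the ACF caveat), and 20-tip test sets make
  individual cutoff-0 R²cv values a noisy estimate of the methods' true
  low-NSTD accuracy (~0.7–0.8).
* The Mk fit profiles a single global rate; no rate heterogeneity, model
  selection, or non-ER matrices.
* Sankoff transition costs are this package's instantiations of the named
  schemes; other implementations may differ in scale.
* The abundance model draws OTUs independently within a sample; no
  compositional interactions, sequencing error, or replicate structure.
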