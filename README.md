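# phylogcn

How predictable is a discrete genomic trait — here, the 16S rRNA gene copy
number (GCN) — from a phylogeny and a partial set of known values?

Amplicon surveys count 16S reads, but cells carry between 1 and ~15 copies
of the 16S gene, so read counts are biased estimates of cell counts.
Correction tools predict each taxon's GCN from its phylogenetic placement
relative to sequenced genomes ("hidden-state prediction", HSP). Whether
that works depends on two things this package quantifies: how fast the
trait decorrelates along the tree, and how far typical taxa sit from their
nearest sequenced relative. `phylogcn` implements the full analysis as a
tested library plus pipeline, driven entirely by synthetic trees and
traits, for method developers and microbiome analysts who want to study
when GCN correction can be trusted.

## What's inside

**Reconstruction methods** (`phylogcn.hsp`) — five HSP families mapping a
rooted tree plus a partially known tip trait to predictions for all tips:

* Sankoff maximum parsimony with all-equal (`mpr_ae`), proportional
  (`mpr_pr`, cost |i−j|) and exponential (`mpr_exp`, cost e^{|i−j|})
  transition costs; point prediction is the mean of the MPR state set;
* maximum likelihood under the equal-rates Mk model (`mk_er`): the rate λ
  of the S-state chain with generator q_{ij} = λ/(S−1) is profiled in
  log-space (5 restarts), and unknown tips get exact marginal posterior
  expectations Σ_s s·P(s | data);
* phylogenetic independent contrasts (`pic`): Felsenstein's
  inverse-branch-length-weighted upward pass, restricted to subtrees with
  data;
* weighted squared-change parsimony (`wscp`): the exact minimiser of
  Σ_edges (x_parent − x_child)²/ℓ with known tips fixed;
* subtree averaging (`sa`): mean of known descendant values, inherited by
  unknown tips from the nearest such ancestor.

**Statistics** (`phylogcn.metrics`) —

* the phylogenetic autocorrelation function ACF(d): Pearson correlation of
  trait values over random tip pairs binned by patristic distance d (for an
  equal-rates Markov trait the ensemble curve is exp(−λS/(S−1)·d));
* NSTD: each tip's distance to the nearest tip with known trait, computed
  by linear-time two-pass message passing;
* NSTI: the abundance-weighted mean NSTD of a community;
* the coefficient of determination R² = 1 − SS_res/SS_tot (negative when
  predictions are worse than the mean; distinct from Pearson r², which is
  also provided), NSTD-binned R², and the relative deviation
  |A−B|/((A+B)/2) between two predictions.

**Experiments** (`phylogcn.evaluate`) — NSTD-stratified cross-validation
(hide 2% of known tips, additionally exclude training tips within a
distance cutoff of the test set, repeat and average), per-community
comparison of two prediction sets (R² vs NSTI, with a 1000-permutation
test for the trend), and GCN correction of read-count tables.

**Synthetic data** (`phylogcn.simulate`) — seeded pure-birth/birth–death
trees, exact equal-rates Markov and reflected ±1-walk trait histories,
random or clade-wise coverage masks, and log-normal community tables with
an optional coverage gradient across samples.

## Worked example

```bash
python analysis/01_simulate_benchmark.py --seed 42
python analysis/02_trait_autocorrelation.py --seed 42
python analysis/03_crossvalidate_hsp.py --seed 42 --methods mpr_exp,pic,sa
python analysis/04_compare_methods_communities.py --seed 42
```

prints (abridged):

```
coverage: 1000/2000 tips known (clade_drop)
NSTD spectrum: 49.2% of tips > 15%, 45.8% > 30%
  correlation drops below 0.5 at ~16.5% substitutions/site (calibration target: 15%)
mpr_exp  R2cv by cutoff  0.00:+0.49, 0.05:+0.35, 0.10:+0.07, ..., 0.40:-0.35
pic      R2cv by cutoff  0.00:+0.70, 0.05:+0.36, 0.10:+0.08, ..., 0.40:-0.60
sa       R2cv by cutoff  0.00:+0.61, 0.05:+0.12, 0.10:+0.13, ..., 0.40:-0.70
  [all     ] Pearson r(NSTI, R2) = -0.738 (r2=0.545), permutation P = 0.0010, n=50
```

Reading: the trait's autocorrelation halves by ~15% substitutions/site,
yet about half the tips sit further than that from any tip with known
copy number — so cross-validated accuracy is decent only at distance
cutoff 0 and collapses below zero by cutoff 0.4, and communities enriched
for poorly covered clades (high NSTI) are exactly the ones where two
prediction methods stop agreeing with each other. That is the case against
blanket copy-number correction, reproduced end to end on synthetic data.

The same stages are available as a CLI (`phylogcn simulate | hsp | acf |
nstd | nsti | crossval | compare | correct | benchmark`); every output file
records its parameters and seed in a `#` header.

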