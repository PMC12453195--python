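# Methods note

This note records the statistical model behind each analysis, the synthetic
data generator and what it is (and is not) meant to be realistic about, the
numerical choices, and known limitations. Problem sizes quoted here (numbers
of OTUs, permutations, random trees) are this package's own desk-scale
defaults, chosen so the full test suite runs in minutes on one CPU.

## Phylosymbiosis: normalized matching-cluster congruence

Host-aggregated community profiles (mean counts per host species) are turned
into a Bray-Curtis (or binary Jaccard) distance matrix and clustered with
UPGMA. Congruence between this microbial dendrogram and the host phylogeny is
the matching-cluster (MC) distance: each non-root internal node of a rooted
tree defines a cluster (its tip set); the MC distance is the minimum-cost
perfect matching between the two cluster sets, where the cost of pairing two
clusters is the size of their symmetric difference and unmatched clusters pair
with the empty set. The matching is solved exactly with the Hungarian
algorithm (`scipy.optimize.linear_sum_assignment`); correctness is tested
against a brute-force oracle that enumerates all topologies and permutations
for small trees.

The raw MC distance is normalized by the mean MC distance between the host
tree and random trees (Yule/coalescent-merging by default, or uniform-attach),
giving nMC with the fixed points: 0 means perfect congruence, about 1 means
"no more congruent than random". The p-value is the add-one rank of the
observed distance in the null sample, P = (1 + #{null <= obs}) / (1 + n).

### Conditioning the null on outgroup rooting

When both trees are rooted on the same outgroup (the standard pipeline roots
the UPGMA dendrogram on the most distant host), the observed pair share one
cluster — the ingroup — by construction, while unconstrained random trees do
not. Measured at zero simulated signal, the unconditioned null rejects in
roughly half of replicates at alpha = 0.05: it is anti-conservative by design,
not by bug. `random_tree_null` and `congruence_test` therefore accept an
optional `outgroup=` argument that conditions the null on the shared rooting
(a random ingroup topology attached at the root beside the outgroup). With it,
the rejection rate at zero signal is at the nominal level within Monte Carlo
error, and the identity nMC = 0 for identical trees is unchanged. The CLI
always roots on the outgroup and therefore always conditions; the library
default remains the unconditioned null so that the classical procedure can be
reproduced exactly.

Because the MC distance on few leaves takes few distinct values, permutation
p-values are tied and therefore super-uniform (conservative); tests assert
validity, P(p <= alpha) <= alpha, rather than exact uniformity.

PERMANOVA on the sample-level distance matrix is the standard pseudo-F with
sample-label permutations, checked against a frozen `vegan::adonis2`
reference; the intra- vs inter-host permutation test compares mean within- and
between-group distances under the same permutation scheme.

## Human-enrichment scans

Genus-level presence is "at least one read in at least one sample of that
host". A genus is host-unique if present in exactly one host; proportions are
over annotated genera only (the pooled unclassified fraction is excluded).
Host pairs are compared by chi-squared tests on unique counts. The log2
fold-change scan works on relative abundances with a small pseudocount,
restricted to genera present in at least 20% of samples of both hosts in a
pair, with Benjamini-Hochberg correction across genera; the "human signature"
is the set of genera whose abundance differs significantly between humans and
at least a configurable number of non-human primates. The signature is
sign-agnostic: both human-enriched and human-depleted genera qualify.

## Genus-scan cophylogeny: dual PACo + ParaFit

For every genus found in all four hominids (minus *Aspergillus*, *Fusarium*,
and *Penicillium*, excluded a priori as unresolvable from ITS), sequences are
dereplicated (identical sequences merged, provenance retained), a
neighbor-joining tree is built from Jukes-Cantor distances, and each OTU
subtree spanning all four hominids with at least three tips is tested:

- **PACo**: both patristic matrices are embedded by principal-coordinates
  analysis with the Cailliez correction (the smallest additive constant that
  removes negative eigenvalues, computed from the standard 2n x 2n companion
  matrix and verified against a frozen `ape::pcoa(correction="cailliez")`
  value). Host coordinates are replicated per association link, both
  configurations scaled to unit sum of squares, and the Procrustes residual
  m2 = 1 - (sum of singular values)^2 of the cross-covariance gives the
  statistic (R2 = 1 - m2). The null randomizes the association matrix by
  quasiswap: a chain of 2x2 checkerboard swaps that preserves row and column
  sums exactly.
- **ParaFit**: the fourth-corner statistic, the squared Frobenius norm of
  C^T A^T B for host and parasite PCoA embeddings A, B and association matrix
  C, checked against a frozen `ape::parafit` value; the null permutes each
  parasite's host links independently.

An OTU is called cophylogenetic only when **both** tests pass
Benjamini-Hochberg FDR at Q < 0.05, each test family corrected separately.

`fpr_validation` estimates the procedure's false-positive rate by shuffling
each fungal tree's tip labels (equivalently, permuting association columns —
the tree shape and its embedding are unchanged, so PCoA is computed once per
tree) and running the dual test on every shuffled instance. With 99
permutations per test, the uncorrected both-tests rate sits below 5% (the two
tests are positively correlated but not identical, so requiring both raw
p < 0.05 is stricter than either alone), and the FDR gate drives it to 0 in
practice.

## Molecular clock

Within one OTU, the nucleotide sequence divergence (NSD) between two hosts is
the mean pairwise p-distance between their sequences (Jukes-Cantor correction
optional for deep splits). Calibration anchors the Homo-Pan NSD to 6 Ma:
factor = 6 / NSD(Homo, Pan). Applying the factor back to the same mean
divergence returns exactly 6 Ma — an identity, not an estimate — which is the
package's calibration self-check.

For other splits, two caveats are built into the API:

- The per-OTU CI (mean ± 1.96 sd/sqrt(n) over cross-host sequence pairs)
  treats pairs as independent, but pairs within one OTU share the host-path
  mutation history, so that CI understates the estimator's sampling error and
  cannot be expected to cover the truth at the nominal rate. Estimates from
  fewer than five pairs are flagged `approximate_ci`.
- `estimate_split_over_otus` therefore pools one calibrated estimate per OTU
  and takes the normal CI over independent OTUs, which is i.i.d. and achieves
  nominal coverage; the simulated-truth recovery experiment (100 replicates of
  20 cospeciating OTUs) covers the true Homo-Gorilla split in >= 90% of
  replicates.

Raw p-distances saturate slightly at hominid depths (about 0.1 Ma downward
bias at 8 Ma with r = 0.005 substitutions/site/Ma). A small bias matters once
the pooled CI is narrow, so `estimate_split_over_otus(..., corrected=True)`
uses Jukes-Cantor-corrected divergences; the CI-coverage experiment uses the
corrected estimator, while the default stays on raw p-distances to mirror the
classical calibration.

## Synthetic data generator

The generator is a measurement model for testing the statistics, not a
mechanistic gut-mycobiome simulation. It aims to be realistic about the
*structure* of the data — compositional counts with lognormal depths, a large
unannotated fraction, host-structured signal mixed with individual noise,
sequences that actually evolve along the host tree — and makes no claim about
parameter realism beyond order-of-magnitude plausibility.

- **Host tree fixture**: eight primate species on an ultrametric tree with
  branch lengths in Ma (Homo-Pan split 6 Ma, Homo-Gorilla 8.15 Ma,
  lemur outgroup 74 Ma deep).
- **Communities**: per-OTU host effects follow Brownian motion on the host
  tree (rate `bm_rate` per sqrt(Ma), log scale), blended with an i.i.d.
  host-free effect by the signal parameter s in [0, 1]; s = 0 makes host
  profiles exchangeable, s = 1 makes the host tree the only structure.
  Per-sample lognormal noise, per-(OTU, host) presence thinning (zero
  inflation), multinomial sampling at lognormal depths. A configurable number
  of planted human-enriched genera multiply human abundances by
  `enriched_fold`; the planted names are exposed via
  `taxonomy.attrs["enriched_genera"]`. Note that presence thinning also
  creates genuinely host-absent genera at any s, so enrichment scans can
  report true differences that were not planted.
- **Sequences**: per-OTU alignments evolve under Jukes-Cantor along the
  (sheared) host tree at rate r substitutions/site/Ma; each host contributes
  `n_seqs_per_host` tips with `within_host_divergence` Ma of extra divergence;
  with probability pi (`host_independence`) a tip is reassigned to a random
  host. pi = 0 is perfect codivergence; pi = 1 erases host signal; pi = 0.5 is
  the mixed regime used in the false-positive experiment.

## Numerical choices

- Exact Hungarian matching for MC (no heuristics); cluster sets as integer
  bitmasks.
- PCoA eigendecomposition via `numpy.linalg.eigh` on the Gower-centered
  matrix; eigenvalues below a tolerance are treated as zero; the Cailliez
  constant is the largest real eigenvalue of the companion matrix.
- Permutation p-values always use the add-one estimator, so p = 0 is
  impossible and tests remain valid at any permutation count.
- All stochastic functions take explicit seeds (`numpy.random.default_rng`);
  the CLI writes resolved parameters next to each stage's outputs.

## Limitations

- MC-based congruence compares topologies only; branch lengths are ignored.
- The quasiswap chain is run for a fixed number of attempted swaps
  (100 x number of ones); for very constrained margins the sampled
  distribution over the fixed-margin state space is approximate.
- The Jukes-Cantor model (equal base frequencies, single rate) and raw
  p-distances understate deep divergences; the Jukes-Cantor-corrected NSD is
  available but the default mirrors the classical procedure.
- The unconditioned random-tree null is anti-conservative whenever both trees
  are rooted on a shared outgroup (see above); use `outgroup=` for calibrated
  p-values in that design.
- The generator plants abundance signal at genus level and sequence signal at
  OTU level independently; it does not couple community composition to
  sequence evolution.
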