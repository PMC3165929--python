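# Methods

## Model

A metagenomic fragment is represented by its canonical l-mer frequency
vector. The canonical index collapses each l-mer with its reverse
complement (representative: the lexicographically smaller string; column
order: sorted representatives), so strand of origin is irrelevant by
construction. Class counts follow `4^l/2` for odd `l` and
`(4^l + 4^(l/2))/2` for even `l` — the even-`l` formula counts the
`4^(l/2)` palindromic l-mers as singleton classes and gives 136 for
`l = 4`. Sliding windows containing any non-ACGT symbol are skipped, not
randomised or wildcarded, so no invented counts enter the vector; a
fragment whose every window is ambiguous has no defined normalisation and
is dropped with a warning. Counts are normalised by the number of counted
windows (not by fragment length), making fragments of different lengths
comparable.

Fragments are compared with a rank-band-filtered distance: sort the
component-wise absolute differences ascending (stable sort, ties keep the
original column order for cross-platform reproducibility) and sum the
entries whose zero-based rank lies in the half-open range
`[floor(lower*m), floor(upper*m))`. With the defaults `lower = 0.6`,
`upper = 0.8` and `m = 136` this keeps ranks 81–107, i.e. 27 components,
~20 % of the dimension. Floor/half-open arithmetic is a deliberate,
deterministic reading of "the 60–80 % band"; an empty band (possible for
very small `m`) is a parameter error, reported with `m` and both bounds.
The band sum is not rescaled: any positive constant factor leaves every
nearest-centre decision, and therefore the clustering, unchanged. The
trimmed distance is *not* a metric — the retained component set differs
from pair to pair, so the triangle inequality can fail — and nothing in
the package or its tests relies on metric properties.

Clustering is k-means with this distance for assignment and the
arithmetic componentwise mean for the centre update, initialised with k
distinct data rows (Forgy). The mean is not the analytic minimiser of the
band-restricted distance, so the objective (the summed band distance of
every row to its assigned centre) is not guaranteed to decrease
monotonically; convergence is therefore declared when the assignment
vector repeats, with a `max_iter` cap (default 100). An empty cluster is
re-seeded with the row farthest from its stale centre so the result
always has k non-empty clusters. The algorithm is restarted (default 10
seeds, `seed .. seed+9`) and the run with the smallest objective is kept,
ties going to the lowest seed. All randomness flows from explicit integer
seeds; identical inputs and seeds give byte-identical outputs.

## Evaluation

Accuracy matches clusters to species one-to-one by maximum-weight
bipartite matching on the species × cluster contingency table
(`scipy.optimize.linear_sum_assignment`) and reports the matched fraction
in percent. One-to-one matching is stricter than per-cluster majority
vote and is the standard choice when k equals the species count; when the
counts differ, unmatched rows or columns contribute zero — a convention,
since no canonical rule exists for that case.

## Rank-band calibration

`calibrate_range` estimates, for every rank position, the probability
P_i that the interspecies sorted difference D_i(A, C) exceeds the
intraspecies D_i(A, B), from random fragment triples (A, B same species,
C another). Because feature values are integer counts divided by the
window total, sorted difference lists tie exactly — at the lowest ranks
both lists are almost surely 0. Scoring ties as "not larger" would pin
P_i near 0 there even when no signal exists, so the default scores a tie
as 1/2 (the unbiased, Mann–Whitney-style convention), under which a
same-species null gives exactly 0.5 in expectation at every rank;
strict scoring remains available via `ties="strict"`. Curves are
estimated at 10,000 triples by default — enough for a binomial standard
error of ~0.005 — with the per-rank standard error reported alongside.

## Synthetic communities

The simulator emulates the factors that drive composition-based binning
difficulty: number of species, fragment length, abundance ratio
(fragments per species) and per-base substitution error rate. Species
genomes are first-order Markov chains over A/C/G/T, giving each species a
distinct, internally stable tetramer distribution whose divergence is
controlled by the distance between transition matrices. Fragments are
exact substrings at uniform start positions, each reverse-complemented
with probability 1/2 to exercise strand collapsing; substitution errors
replace a base with one of the other three uniformly (composition
features are position-free, so substitutions are the relevant
perturbation — no indels, quality profiles or chimeras are modelled).

The reference community is two species of 500 kb at ~65 % vs ~32 % GC
with state-dependent transition structure — divergence comparable to
genomes separated at order level or above — sampled as 2000 + 2000
fragments of 2000 bp at 2 % substitution error. Test-suite checks that
only need qualitative behaviour run smaller communities (e.g. 150 + 150
fragments of 1000 bp from 100 kb genomes); the acceptance script runs the
full reference community and averages accuracies over three community
seeds.

What passing on these communities shows — and does not. Markov genomes
have spatially homogeneous composition; real genomes carry atypical
regions (promoters, horizontally transferred segments) that create the
intraspecies noise the band's upper trim targets, and closely related
taxa differ far less than the GC-divergent reference pair. Accuracy on
the reference community therefore demonstrates correctness of the
pipeline and its error robustness, not expected performance on
genus-level separations in real data.

## Numerical choices and limitations

- Feature rows sum to 1 within 1e-9; the clustering objective invariant
  is recomputed from scratch to 1e-9 in tests.
- Distance band arithmetic is exact integer index computation after a
  single float multiply-and-floor; all reductions (Manhattan, Chebychev)
  hold to 1e-12 on random vectors.
- `l` is limited to 1–8: beyond 8 the background noise of the
  exponentially growing dimension swamps the signal, and the vector no
  longer fits the short fragments the tool targets.
- No automatic choice of k (the species count is assumed known for
  evaluation), no alternative clusterings (hierarchical/density-based),
  and no handling of paired ends, quality scores or assembly.
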