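# Methods

## Input model

The pipeline consumes a table of unordered kinase pairs × treatments with
real z-scores quantifying how much each kinase–kinase interaction (defined
by shared putative downstream phosphosites) changed under an inhibitor
treatment. Negative z-scores mean inhibition. Cells may be missing; a
missing cell means "no measurement / no edge", and is never imputed as
zero. Pairs are canonicalised (members sorted lexicographically), so row
order and within-pair order never matter. Kinase aliases that share
identical measurements (e.g. two isoforms reported as one activity) can be
merged via a configurable alias map; merging removes pairs that collapse
onto themselves and deduplicates pairs whose z-scores agree within an
absolute tolerance (default 1e-9 — merged isoforms are expected to carry
numerically identical scores, so the tolerance only absorbs representation
noise). Conflicting duplicates are an error, not a silent average.

Summary statistics (`summarise`) are computed over strictly negative (or
strictly positive) z-values; zeros belong to neither side. The reported
standard deviation is the sample convention (ddof = 1) with the population
value exposed alongside, since published summary tables rarely state which
was used; a single retained value gets sd 0 (both conventions are degenerate
there). `n_kinases` counts distinct kinases incident to at least one
retained pair.

## Networks

For one treatment and one sign, the network keeps exactly the pairs whose
z-score is strictly of that sign, weighted by |z|; nodes are the kinases
incident to a retained edge, ordered lexicographically so the adjacency
matrix is reproducible. Networks are undirected — the data cannot say which
kinase acts upstream — with no self-loops and no isolated nodes.
Serialisation is lossless GraphML (edge attribute `weight`, graph attributes
`treatment`, `sign`) or an edge-list CSV with the metadata in comment lines.

## Community detection

Quality function, summed over **all ordered pairs including i = j**:

    Q(c) = sum_ij (A_ij - gamma * P_ij) * delta(c_i, c_j)

Null models:

* **Newman–Girvan**: P_ij = s_i s_j / (2m) with s the node strengths and 2m
  the total weight. The diagonal term s_i^2/(2m) is kept; this makes the
  null strength-preserving, so the one-community partition scores exactly 0
  at gamma = 1 — a closed form the test suite checks on arbitrary networks.
* **uniform**: constant expected weight P_ij = <w> = 2m / (n(n-1)) off the
  diagonal, P_ii = 0. On a complete network with equal weights every
  partition scores 0 at gamma = 1. This is the standard constant-expectation
  null; the uniform null tends to be the better default for these dense,
  heavy-tailed |z| networks because it does not discount hub kinases.

The resolution gamma (> 0, default 1) multiplies the null and sets the
community scale; the pipeline analyses a single scale but exposes gamma for
multi-scale exploration.

**Louvain.** Local moving visits nodes in a random order re-drawn every
pass (this is the only source of stochasticity; a seed makes runs
bit-reproducible). Each node may move to any community, or to a fresh
singleton, that strictly improves Q by more than 1e-12 (the threshold stops
cycling on floating-point noise); the first-encountered best community in
label order wins ties. When a pass makes no move, communities are
aggregated. Because the null is arbitrary, aggregation sums blocks of
B = A − gamma*P rather than re-deriving a null from aggregated weights — a
weight-only aggregation would be wrong for the uniform null. After the
hierarchy converges, one final local-moving phase runs on the flat network,
so the returned partition is a genuine single-node-move local optimum of Q
(plain Louvain guarantees this only at the aggregated level).

**Exhaustive oracle.** `brute_force_partition` enumerates all set partitions
(restricted-growth codes; refused above n = 12) and returns the global
maximiser, breaking exact ties by fewest communities and then by the
lexicographically smallest grouping. It exists to certify the heuristic on
small instances and is used as an independent check throughout the tests.

## Consensus

An ensemble of `ensemble_size` Louvain runs (default 100) yields a
co-classification matrix whose entry (i, j) is the fraction of runs
co-assigning i and j — entries times the ensemble size are exact integer
counts, so "binary" is a well-defined exact test, with no epsilon. If the
matrix is not binary, it is itself treated as a weighted network (diagonal
zeroed) and the ensemble is re-run on it under the same null family and
gamma — an assumption, since the choice of null on the derived matrix is
genuinely open; the same-family choice keeps the procedure a single
self-contained recipe. An optional threshold can zero small entries between
iterations (default off: the matrix is re-clustered as-is). Iteration stops
when the matrix is binary — typically after 1 or 2 iterations on networks
with clear structure — and the consensus partition is the connected blocks
of that binary matrix. More than `max_iterations` (default 20) ensembles is
reported as an error carrying the last matrix, never as a silent result.

Per-run seeds derive from the master seed by a counter scheme
(master, iteration, run) through `numpy.random.SeedSequence`, and are
recorded so any individual run can be replayed. Robustness is assessed by
repeating the whole consensus with distinct master seeds and reporting all
pairwise ARI and NMI (both, since either alone can be flattering).

## Pathway analysis

`select_community` picks the community containing the inhibitor's main
target (after alias merging). Communities selected in different treatment
networks targeting the same pathway are intersected; the shared kinases are
the candidate pool. `anchor_filter` keeps candidates with a strictly
positive edge to **every** anchor kinase, looked up in the full designated
treatment network (the community only scopes the candidate list — a
candidate's anchor edges need not be intra-community). Anchors themselves
are excluded from the survivor set; already-known pathway members can
additionally be excluded from the ranking via configuration while still
being reported. Community strength CS(v) = sum of v's edge weights to
co-members; since weights are |z|, CS is non-negative and ranking by |CS|
equals ranking by CS. Ranks are competition ranks (ties share the smaller
rank). The cross-network candidate ordering — best (minimum) rank across
reports, ties by mean CS descending, then name — is a packaging decision;
the underlying per-network CS values and ranks are all reported.

`run_pipeline` composes the stages from a single config (treatments →
targets, sign, null, gamma, ensemble size, master seed, aliases, anchors,
exclusions) and emits a JSON-serialisable report embedding the config and
derived seeds; with `sort_keys=True` two runs with the same inputs are
byte-identical.

## Synthetic data

The generator plants a known community structure in a one-treatment z-score
table. For each within-community pair, with probability `p_within` a
z-score is drawn from Normal(mu_within, sigma_within) truncated to be
strictly negative by redrawing (sign-flipping would distort the stated
mean); with probability `heavy_tail_fraction` the draw instead uses the
tail component Normal(mu_tail, sigma_tail). Between-community pairs use
`p_between`, `mu_between`, `sigma_between`. A `positive_noise_fraction` of
the remaining pairs receive small positive z-scores (|Normal(0.3, 0.2)|);
everything else is missing.

Defaults (chosen once as a clearly recoverable yet non-trivial instance
that a single run solves in well under a second): 60 kinases in three
communities of 20, p_within 0.6 vs p_between 0.1, bulk means −1.5 vs −0.2
(sd 0.5 / 0.2), heavy_tail_fraction 0.05 with tail mean −8 and sd 3, and
10% positive noise. The bulk negative moments sit on the scale of real
inhibitor-treatment columns (means a few tenths to ~1 in magnitude, sd
below 1) and the tail component reproduces their signature extreme minima
an order of magnitude below the bulk; the tests assert the generated
minimum falls more than five bulk standard deviations below the bulk mean.

What the generator does **not** emulate: correlated z-scores between
overlapping pairs (real pairs sharing a kinase are not independent),
treatment-to-treatment correlation beyond the shared planted partition,
kinase-specific measurement coverage, and any notion of directionality.
Passing recovery tests therefore demonstrates that the algorithmic chain is
correct and well-calibrated for block-structured weight contrasts, not that
real perturbation data satisfy those assumptions.

The first member of the designated "pathway" community acts as the
inhibitor target and the first three as anchors, so the full selection →
intersection → anchor-filter → ranking chain can be scored against the
planted truth (`evaluate_recovery`: ARI, NMI, and precision/recall of the
selected community against the planted pathway community). A
multi-treatment helper draws independent tables per treatment over one
shared planted partition for end-to-end pipeline runs.

## Numerical and degenerate-input choices

* Move acceptance needs a strict gain > 1e-12; closed-form zero identities
  are asserted to 1e-8/1e-9 absolute (floating-point sums, not symbolic).
* Zero-total-weight networks are rejected before any null is formed;
  empty sign-filtered networks raise a named error, not an empty object.
* Brute-force tie-breaks (fewest communities, then lexicographic) make the
  oracle deterministic even on exactly degenerate landscapes, e.g. a single
  2-node edge under the uniform null, where every partition scores 0 and
  the one-community grouping is returned.
* Alias-merge tolerance is absolute (1e-9), not relative: merged isoforms
  are expected to be exact duplicates.

## Problem sizes used in the checks

The packaged checks run the oracle comparison on 200 random networks of
4–8 nodes (the exhaustive enumeration is vectorised over all partitions),
consensus behaviour on 50 planted replicates with 50-run ensembles, and
recovery/precision on 20 replicates each — sizes at which the full suite
and the reproduction script each complete in well under a minute on one
core while exercising every stage at its default configuration.

## Known limitations

* Louvain is a heuristic: on ~7% of small random dense networks it returns
  a local optimum below the exhaustive maximum (it never exceeds it); the
  consensus layer is what makes the pipeline's output stable.
* The uniform-null constant ⟨w⟩ = 2m/(n(n−1)) is one reasonable convention
  for "uniform"; other constants rescale gamma.
* Candidate nomination is correlational. The pipeline cannot assign
  upstream/downstream directionality; it nominates kinases for follow-up,
  nothing more.
* Very weak planted contrast (p_between → p_within, equal means) is
  flagged as unrecoverable at generation time; recovery scores there are
  reported but carry no guarantee.
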