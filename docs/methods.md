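# Methods

## Motif model and matching semantics

A motif is an ordered list of *anchors* (single residues or residue
classes drawn from the 20 canonical amino-acid letters) and *gaps*
(`.{m,n}` ranges; a bare `.` is a gap of exactly 1). The total span of a
match is bounded by `span_min = Σ(1 per anchor + gap minima)` and
`span_max = Σ(1 per anchor + gap maxima)`; for the stringent ABA-site
motif these are 26 and 30 residues, which brackets the 27-residue site
reported in human SAV1 (positions 137–163 under the same 1-based,
inclusive coordinate convention used throughout the package).

Matching is boolean — no position-weight scoring — and exhaustive: the
scanner backtracks over all gap-length assignments and reports every
distinct `(start, end)` span, rather than the leftmost-greedy single match
a naive regular-expression search would give. Distinct spans are keyed on
`(start, end)`; when several gap vectors realise the same span, the
anchor positions of the lexicographically smallest vector are reported
(depth-first search with ascending gap lengths visits vectors in exactly
that order, so the first completion wins deterministically).

Design choices that were genuinely open:

* **Ambiguity codes** (B, J, O, U, X, Z) are tolerated in sequences but
  never satisfy an anchor class, while any residue — including an
  ambiguity code — can occupy a gap position. This is the conservative
  choice: it can suppress a match at an uncertain residue but never
  fabricates an anchor.
* **Consecutive gaps are not coalesced** at parse time; the pattern
  structure is preserved losslessly and the scanner's semantics make
  coalescing unnecessary.
* **Site counting** operates on *merged sites* — the transitive closure of
  interval overlap (≥ 1 shared position; intervals that merely touch
  end-to-start are distinct) — so gap-length jitter around one biological
  site does not inflate counts. This is what makes "two adenylate-cyclase
  catalytic centres in one protein" a well-defined number.
* **Two adenylate-cyclase signature variants** are shipped (`AC_TEXT`,
  `[RSK][YFW][DE].{8,12}[RK].{1,3}[DE]`, and `AC_FIG`,
  `[RSK].[DE].{8,12}[RK].{1,3}[DE]`) because both circulate for the same
  signature and they are not equivalent; neither is silently preferred.
* Anything outside the grammar (`^ $ * + ?`, nucleotide alphabets,
  single-number repeats `.{k}`) raises a syntax error rather than being
  reinterpreted.

## Background expectation

`expected_match_count` returns the union bound
`Σ_configs (L − span(config) + 1) · Π anchor-class probabilities` for an
i.i.d. sequence of length `L`. Because distinct gap vectors can realise
the same span, this slightly over-counts distinct `(start, end)` hits; it
is therefore documented and tested as an approximate upper bound, with the
Poisson-band checks widened threefold when the expectation is below 5.
When comparing observed scan counts on planted proteomes with this
expectation, hits that overlap a planted interval of the same motif are
excluded (`count_background_hits`): such hits are alternative spans induced
by the planted anchors, not independent background events, and would
otherwise bias the comparison upward for anchor-rich motifs.

## Candidate tables

Candidacy is presence-based: a protein is a candidate iff it has ≥ 1
merged site of the primary motif. Site counts and flags are computed for
every motif in the set, and summary counts match descriptions by
case-insensitive substring (DNAJ-family membership is an annotation
property, not a sequence property, so the description is the right place
to look). Candidate lists are sorted by accession and invariant under
input record order.

## Enrichment statistic

For a term with `K` of `N` background proteins and `k` of `n` candidates,
fold enrichment is `(k/n)/(K/N)` (0 when `k = 0`) and significance is the
exact one-sided hypergeometric upper tail `P(X ≥ k)`, summed in log space
from log-gamma binomial coefficients. Exactness is cheap at `N ~ 2×10⁴`
and lets the implementation be verified against brute-force enumeration of
all draws for small universes (agreement ≤ 10⁻¹² for every parameter
combination with `N ≤ 12`). Only over-representation is tested. BH-FDR
uses the standard step-up via statsmodels; terms with `q` below the
configured threshold (default 0.05) are retained, and the full table is
always returned alongside. The background defaults to all annotated
proteins and should be set to the scanned proteome for proteome-wide runs;
published GO-based enrichment figures depend on the annotation release and
background used, so the package recomputes them only from a user-supplied
annotation table rather than asserting them.

## Network filtering and Markov Clustering

Edges carry a combined score and optional per-channel scores on [0, 1]
(integer inputs > 1 are read on the STRING 0–1000 scale and divided by
1000; reciprocal duplicates keep the higher combined score). Filtering
keeps edges with combined ≥ 0.700 by default and, when the co-expression
view is active, additionally requires a co-expression channel score
≥ 0.400 — an edge lacking the channel fails an active co-expression
filter. Both modes are exposed because published displays differ on
whether the co-expression cut applies jointly or as an alternate view.
Hub statistics: weighted degree is the sum of combined scores over
incident edges (ties broken lexicographically), average node degree is the
unweighted `2E/V`, and the clustering coefficient is the mean local
transitivity with degree-< 2 nodes contributing 0.

MCL runs on the column-stochastic matrix of the weighted adjacency with
self-loops of weight equal to each node's maximum incident edge weight
(standard MCL practice, preventing immediate mass loss at hubs; 1.0 for
isolated nodes). Each iteration expands (matrix power 2), inflates
(elementwise power, default 3, then column renormalization), prunes
entries below 10⁻⁶ and renormalizes; iteration stops when the maximum
absolute entry change falls below 10⁻⁹ or after 200 iterations
(non-convergence returns the partial clustering with a warning flag —
never observed on the tested graphs, which converge in ≤ ~15 iterations).
Rows of the limit with residual mass are attractors; each attractor's
nonzero support is one cluster, identical clusters are deduplicated,
overlaps are permitted, and clusters are ordered by size (descending) then
smallest member. The expansion power, pruning threshold, tolerance and
iteration cap are fixed for determinism; inflation is the only granularity
parameter a user normally touches.

## Synthetic data

The generators are pure functions of their spec, each drawing from a
single seeded `numpy.random.Generator`:

* **Proteomes** — sequence lengths are log-normal with configurable mean
  and standard deviation (defaults 1000 ± 300 residues, a realistic scale
  for human proteins), floored at the widest planted motif's span plus 10;
  residues are i.i.d. from a configurable composition (uniform by default;
  a human-like SwissProt composition table is included). Planted instances
  sample gap lengths uniformly in range, anchors uniformly from their
  classes and gap residues from the background, and are spliced at
  uniformly chosen offsets that never overlap another planted instance —
  which is what makes planted recall exactly 1.0 a construction guarantee
  rather than a statistical outcome. Incidental background matches remain
  possible and are correct scanner behaviour, quantified against the
  analytic expectation.
* **Annotation tables** — one planted term takes a fixed number of
  candidates (`round(fold · base_rate · n)`) and non-candidates
  (`round(base_rate · (N − n))`), membership random but counts fixed so
  the realized fold tracks the target; ≥ 10 decoy terms sample the
  background at the base rate (default 0.05). Unattainable folds (rate
  above 1, or candidates identical to the background) are rejected.
* **Edge tables** — complete intra-module subgraphs with combined scores
  uniform on (0.85, 1.0) and inter-module noise edges present with
  probability 0.3, uniform on (0.0, 0.3); the ranges are disjoint by
  construction so the 0.700 filter provably severs modules. The
  co-expression channel mirrors the combined score for simplicity.

What the synthetic data does *not* emulate: domain structure, repeats,
homology, compositional heterogeneity along sequences, or realistic
annotation-term size distributions. Passing the planted-truth tests
demonstrates correctness of the machinery, not biological precision or
recall on real proteomes.

## Problem sizes and determinism

The test suite and the acceptance script run the scanner–oracle comparison
on 200 random length-100 sequences per motif, planted recovery on a
100-sequence × ~1000-residue proteome (50 stringent + 30 SH3 instances),
enrichment on a 20-candidate / 2000-protein background, and MCL on 6+6-node
two-module graphs — sizes at which every check is exact or tightly banded
and the whole pipeline completes in seconds. All randomness flows from
explicit seeds; identical inputs, configuration and seed produce
byte-identical outputs.

## Known limitations

* Boolean matching only: no PWM/HMM scoring, no nucleotide support.
* Terms are opaque labels; no GO graph propagation.
* STRING's PPI-enrichment p-value needs STRING's degree-matched background
  model and is intentionally not approximated.
* Exact reproduction of published proteome-wide counts depends on the
  (unstated) UniProt and annotation releases; the package provides the
  recipes, not the frozen databases.
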