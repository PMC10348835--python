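# Methods

## The decomposition

The LZ-76 procedure scans a sequence with a growing window and emits the
window content whenever it has not been seen before. Two conventions matter
here and are fixed throughout the package:

* **Ordered output.** The classic procedure returns a *set* of subpatterns;
  graphs and feature vectors need the subpatterns in emission order with
  their start positions, so the canonical output is the ordered list
  (`Decomposition.subpatterns`), with the raw set retained
  (`raw_dictionary`) for anyone who wants the textbook object.
* **Trailing remainder.** When the scan reaches the end of the sequence
  while the current window duplicates a known subpattern, the leftover
  symbols are appended to the last emitted subpattern
  (`merged_tail=True`). This keeps the decomposition lossless, which every
  downstream structure relies on. The merged token — not the raw one — is
  what enters BOW dictionaries and graph nodes, so the BOW vocabulary and
  the graph node vocabulary coincide; the alternative (indexing the raw
  tokens) would make feature vectors and graphs disagree about what a
  "subpattern" is.

The scan advances its two indices monotonically, so decomposing N
sequences of maximum length L costs O(N·L) — the same order as K-mer
extraction (verified in the tests by counting window slices).

## Node encodings and the graph

Three encodings map subpatterns to graph nodes:

| scheme  | node key                        | alphabet    | acyclic |
|---------|---------------------------------|-------------|---------|
| `naive` | subpattern                      | nt or aa    | no      |
| `ndp`   | `{sub}{(pos−1) mod 3}_{pos}`    | nucleotide  | yes     |
| `aap`   | `{sub}_{pos}`                   | amino acid  | yes     |

`pos` is the 1-based index of the subpattern's **first** character (so
`LF_7` is "LF" starting at position 7); positions strictly increase along
any parse, which is what makes the positional graphs DAGs. The reading
frame in `ndp` is `(pos − 1) mod 3`, i.e. frame 0 for position 1.

Edge weights are transition counts normalised by the **total outgoing
transition events** of the source node (not by its number of distinct
successors), so each node's out-weights form a conditional probability
distribution — the property the Pgen product and the random walks require.
Construction is one path insertion per record; repeated identical records
each count (read-level semantics), except where an operation explicitly
works on unique sequences (the `unique=True` flag; K1000 below). Graph
content is invariant to input order, and the JSON serialisation is
canonical (sorted keys), so equal graphs produce byte-identical documents.

The optional gene layer stores **joint** (v_call, j_call) counts per edge —
joint, because constrained generation must know whether a specific pair
supports an edge; V and J marginals are derived views. Allele strings are
kept verbatim (no IMGT normalisation): annotations come from upstream
tools and renaming them is out of scope.

## LZPgen

`Pgen(s) = P(X0) · Π w(x_{i-1}, x_i)` over the sequence's encoded path.
The product has `len(path)` factors: the initial-state marginal plus one
factor per transition. Conventions for queries that leave the observed
graph:

* A missing transition (node present but edge absent, or node absent
  altogether — the two are not distinguished) contributes the **geometric
  mean of the present edge weights of the same path**. Edge weights are
  log-linear in nature; the geometric mean is the imputation that preserves
  the log-additive structure of the product.
* A missing initial state is treated exactly like a missing edge and enters
  the same imputation. The alternative (probability 0 for any unseen start)
  would zero out most out-of-repertoire queries on deep graphs whose paths
  are otherwise well supported.
* If **no** edge of the path is present, the geometric mean is undefined;
  the result is probability 0 with `degenerate=True` rather than an
  exception, so batch scoring never aborts.

LZPgen on the naive graph is refused by default (its cycles make the path
product hard to interpret); `allow_naive=True` overrides.

## Sequence generation

The walk starts at an `Init` draw and repeatedly samples a successor from
the out-edge weights. At a terminal node T it stops outright if no other
terminal is reachable from T, else stops with probability
`PT(T) = Ψ(T)/(Ψ(T)+Σ_{x∈U}Ψ(x))` over the other reachable terminals U.
After a declined stop the walk resumes from the **full** out-edge
distribution (no exclusion or renormalisation — the simplest reading of a
single stopping draw). Successor draws are inverse-CDF over successors in
lexicographic key order, so a seed fixes outputs across platforms.

Constrained mode first draws a V and a J allele from their **marginal**
source frequencies, then only traverses edges whose joint gene usage
supports the drawn pair, renormalising over the admissible out-edges at
each step. Ψ and PT are *not* recomputed on the admissible subgraph — the
termination mass is defined once, from the whole repertoire; restriction
applies to edge admissibility only. Because the pair is drawn from
marginals, a combination never observed jointly can be drawn; every walk
then dead-ends and, after `max_restarts` (default 100) fresh starts with
the same pair, a `GenerationError` names the offending pair. This is a
real property of the method, not a defect: the repertoire simply contains
no support for that gene combination. `max_steps` defaults to 10× the
longest source path and can only be hit on cyclic (naive) graphs.

A generated walk concatenates losslessly into its sequence, but that
sequence's *own* LZ-76 parse need not share the walk's subpattern
boundaries — the graph freely joins subpatterns whose concatenation
re-parses differently. On a 300-draw sample from a mid-sized synthetic
repertoire roughly 80% of generated sequences re-parse with different
boundaries; the tests measure this rate and verify exact agreement
whenever the boundaries do coincide.

## Feature vectors

**BOW.** A dictionary is the union of subpatterns over one or more
repertoires in first-observation order (deterministic, hence reproducible
vectors); a repertoire is encoded as dictionary-token counts over all its
parses divided by the repertoire depth N. Out-of-vocabulary subpatterns
are ignored and counted (`n_ignored`), mirroring how a fixed dictionary is
applied to an unseen cohort.

**Eigencentrality.** The dominant eigenpair `A x = λ x` of the naive
graph's weighted adjacency, computed by shifted power iteration
(`x ← (A+I)x`): the shift leaves eigenvectors unchanged while breaking the
±w symmetry of periodic components that defeats plain power iteration.
Convergence is declared on the eigenpair residual `‖Ax − λx‖ ≤ 1e-10`
(λ from the Rayleigh quotient), checked every 10 sparse matvecs with a
200,000-iteration budget; the vector is L2-normalised and nonnegatively
oriented. Two classes of graph are refused with an explanatory error
rather than returning noise: positional (ndp/aap) graphs and naive graphs
that happen to contain no cycle — both have nilpotent adjacency, spectral
radius 0, and no meaningful dominant eigenvector. Vectors are re-indexed
onto a shared vocabulary with zeros for absent nodes so repertoires can be
compared in one basis; the aligned vector is deliberately not
re-normalised (absence is information).

## K1000

The K index of a repertoire is the node count of an LZGraph built from k
unique sequences sampled without replacement, averaged over `repeats`
sampling procedures (k=1000, 50 repeats by default; `ndp` for nucleotides,
`aap` for amino acids). Unique sequences are taken as a sorted set before
sampling, so the index depends only on the unique-sequence *set* and the
seed — never on record order or clonal abundances — which is the point:
it measures structural ("information capacity") diversity, orthogonal to
abundance-based alpha diversity. Repertoires with fewer than k unique
sequences raise by default; `fallback=True` lowers k to the available
count with a warning, the advised adaptation for shallow repertoires.

## Per-sequence diagnostics

The **variation curve** of a sequence against a reference graph is the
distinct-successor out-degree δ⁺ at each node of its encoded path, with 0
for nodes absent from the graph; **LZ-Centrality** is its mean. One
centrality query costs O(L) node lookups against a graph built once in
O(N·L) — versus O(N²·L²) for mean pairwise distance — and correlates
negatively with a sequence's mean Levenshtein distance to the repertoire
(sign verified in the tests; the magnitude is data-dependent).

**Gene variation** marginalises each path edge's joint gene counts to V
(resp. J): an allele's entry is its share of the edge's transitions, NaN
marking "never observed at this edge" (rendered black in the heat map).
Alleles absent from more than α percent of the path's **edges** are
dropped (α counts edges, not nodes, since alleles annotate edges); α=0
keeps exactly the full-path alleles, α=100 (and the display default 50)
keeps progressively more. α is a display filter only — it never affects
probabilities.

## The synthetic repertoire generator

The generator emulates the structure V(D)J recombination imposes on CDR3s:
a conserved 5' flank from the V segment (defaults are "CAS"-family amino
acid motifs — nearly all TCRB CDR3s start with CAS), a random junctional
middle, and a conserved 3' flank from the J segment; V allele labels are
tied to the 5' motif and J alleles to the 3' motif, so gene-constrained
analyses see realistic motif–allele coupling. Defaults: lengths 12–18
amino acids (the empirical CDR3 length distribution centres near 15);
nucleotide mode emits in-frame lengths 36–54; clone sizes follow a
Zipf-like distribution when replicating `n_unique` distinct sequences to
`n_sequences` records, mimicking clonal expansion. Everything is
deterministic for a fixed seed.

What the generator does **not** emulate: position-specific amino-acid
composition biases, insertion/deletion statistics of the junction, allele
frequencies matching any population, sequencing error, or the long-tailed
clone-size distributions of real blood draws. Tests passing on these
fixtures therefore establish the *algorithmic* properties of the methods
(losslessness, normalisation, distributional recovery, invariances), not
biological claims about real repertoires.

## Numerical and design notes

* Weight normalisation holds to 1e-12 by construction; Pgen agrees with a
  brute-force counts-ratio oracle to 1e-12 on small graphs.
* All stochastic operations take an explicit seed; there is no global
  random state. Draw order is fixed by lexicographic node ordering.
* Test-suite problem sizes (hundreds of sequences, thousands of simulated
  draws, 100 random repertoires per law) were chosen so the whole suite
  and the reproduction script each run in well under a minute while
  keeping every statistical check comfortably powered.
* Degenerate inputs: empty sequences and out-of-alphabet characters
  (including N/X/*) are rejected with the offending position named; a
  permissive reader mode drops such rows with a warning instead.
* Ambiguity about whether position annotation should use a subpattern's
  start or end index is resolved to the start (consistent with the "LF_7"
  convention above).

## Known limitations

* An LZGraph is specific to its source repertoire; two repertoires differ
  in both nodes and edges, and comparisons between shallow repertoires
  confound biology with undersampling. Pooling cohorts into one
  "master graph" is done by concatenating repertoires before construction
  (graphs are not merged after the fact).
* LZPgen is a structural, annotation-free quantity; it is not calibrated
  against mechanistic recombination models and should be compared between
  sequences under the same graph, not across graphs.
* Eigencentrality requires a cyclic naive graph (see above) and is
  intended for deep repertoires.
* Constrained generation can legitimately fail for gene pairs with no
  joint support (see above).
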