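# lzrep

Graph encodings of T-cell receptor beta (TCRB) CDR3 repertoires built on
the Lempel–Ziv 76 decomposition.

Adaptive immune receptor repertoires contain up to millions of CDR3
sequences produced by stochastic V(D)J recombination. `lzrep` turns such a
repertoire into a single compact probabilistic model — an **LZGraph** —
without any preliminary gene annotation or alignment, and derives from it:

- **LZPgen** — a generation probability for any sequence,
- **sequence simulation** — unconstrained or restricted to a drawn V/J
  gene pair,
- **repertoire feature vectors** — bag-of-words subpattern frequencies or
  node eigencentralities, for downstream classification,
- **K1000** — an abundance-free diversity index,
- **LZ-Centrality** and gene-variation profiles — per-sequence diagnostics
  against a repertoire.

## The model

Each CDR3 sequence is parsed by the LZ-76 procedure into an ordered list of
previously unseen subpatterns `X = (x1 … xn)`; the parse is lossless
(concatenating the subpatterns reproduces the sequence) and the subpattern
count is the sequence's Lempel–Ziv complexity. The LZGraph of a repertoire
is the triplet **(V, E, W)**: nodes are subpatterns (optionally annotated
with their 1-based start position, which makes the graph a DAG), edges
connect consecutive subpatterns along each sequence's parse, and

    w_ij = #(transitions i -> j) / #(all transitions leaving i),

so out-edge weights form a conditional distribution. The graph also counts
where paths begin (`Init`, normalising to P(X0)) and end (`Term`,
normalising to the termination mass Ψ). The generation probability of a
sequence is the path product

    Pgen(s) = P(X0) · Π_i w(x_{i-1}, x_i),

with transitions never observed during construction imputed by the
geometric mean of the observed edge weights of the same path. Simulation
walks the graph from an Init draw and, on reaching a terminal node T, stops
with probability

    PT(T) = Ψ(T) / (Ψ(T) + Σ_{x ∈ U} Ψ(x)),   U = other terminals reachable from T.

Three node encodings are available: `naive` (bare subpatterns, cyclic —
used for eigencentrality features), `ndp` (nucleotide subpattern + reading
frame + position) and `aap` (amino-acid subpattern + position).

## Worked example

```python
from lzrep import LZGraphModel, synth_repertoire

rep = synth_repertoire(n_sequences=1000, n_unique=500, seed=42)
res = LZGraphModel(rep, scheme="aap", with_genes=True).fit()
print(res.summary())
```

```
LZGraph model fit
=========================================
Scheme             aap
Scope              amino_acid
Sequences (depth)  1000
Unique sequences   500
Nodes |V|          869
Edges |E|          2733
Initial states     1
Terminal states    52
Gene layer         yes
```

The fitted results object carries every downstream analysis:

```python
seq = rep.records[0].sequence          # 'CASSPGFYGYTF'
r = res.pgen(seq)
print(r.probability, r.log10_probability, r.n_imputed)
# 4.056e-06  -5.392  0          <- generation probability of the sequence
print(res.lz_centrality(seq))
# 11.889                        <- mean out-degree along its subpattern path
print(res.generate_frame(3, mode="constrained", seed=7))
#              sequence     v_call     j_call  n_restarts
#    CASVAFTCVGWGKQEQYF TRBV5-1*01 TRBJ2-7*01           0
#     CASSCRANLLLLKEQYF TRBV7-9*01 TRBJ2-7*01           0
#      CASSDWSHMIWKDYTF  TRBV28*01 TRBJ1-2*01           0
print(res.k_diversity(k=400, repeats=20, seed=1).index_value)
# 775.9                         <- mean node count over 20 subsample graphs
```

A pgen of 4.1e-06 with zero imputed factors means the whole path was
observed while fitting; constrained simulation draws a V and a J allele
from the repertoire's frequencies and only walks edges supported by that
pair; the K index counts graph nodes over repeated subsamples of unique
sequences, so it measures structural (not abundance) diversity.

The same pipeline is available from the shell:

```bash
lzrep synth --seed 7 --n 1000 --n-unique 500 --out rep.tsv
lzrep build --input rep.tsv --scheme aap --with-genes --out graph.json
lzrep pgen --graph graph.json --input rep.tsv --out pgen.tsv
lzrep generate --graph graph.json --n 100 --mode constrained --seed 3 --out gen.tsv
lzrep k1000 --input rep.tsv --k 400 --repeats 20
```

Real repertoires are read from AIRR Rearrangement TSV (`junction` /
`junction_aa` / `v_call` / `j_call` / `duplicate_count`) or any CSV via
`--column-map`.

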