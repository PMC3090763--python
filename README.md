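# rbninfer

Constraint-based analysis of gene regulatory interactions from binary
time-series expression data, under the restricted (threshold) Boolean
network model.

## The problem

Reverse engineering a gene regulatory network from a short time course
is ill-posed: many networks reproduce the same observations. Rather than
returning one "inferred" network, this package characterises the whole
set of networks consistent with the data and summarises where they
agree. It is aimed at systems biologists triaging candidate
interactions for wet-lab follow-up: the output says which regulations
*every* consistent network shares, which are partially pinned down, and
which single experiment would constrain the most others.

## The model and the method

A network over genes `x_1 … x_n` is a signed matrix `A`,
`a_ij ∈ {−1, 0, 1}` (activation / none / inhibition of target `i` by
regulator `j`). With input `u_i(t) = Σ_j a_ij x_j(t)`, all genes update
synchronously: `x_i(t+1) = 1` if `u_i > 0`, `0` if `u_i < 0`, and on
`u_i = 0` either hold their value or decay to 0 (per-gene
*self-degradation* flag).

Each observed transition `S(t) → S(t+1)` forces the sign of every
gene's input, yielding integer inequalities over the active regulators,
e.g. `a_41 + a_43 ≥ 1` when gene 4 switches on while genes 1 and 3 are
active. Because row `i` of `A` affects only gene `i`, the data induce
`n` independent constraint satisfaction problems over `{−1,0,1}^n` —
`n·3^n` candidates instead of `3^(n²)` matrices. Each row problem is
solved exactly (vectorised enumeration, up to 13 genes) or by randomized
backtracking sampling. The surviving rows give per-entry frequencies of
−1/0/+1, from which connections are classified as **determined**
(frequency 1), **partially determined** (one value excluded) or
**undetermined**; undirected pairs are ranked by
`rank({i,j}) = 2 − freq0(a_ij) − freq0(a_ji)` and validated against a
reference edge set; and an induction scan finds the single assignment
`a_ij = v` that would determine the most other connections.

The package ships an 11-gene budding-yeast cell-cycle benchmark
(network, its 13-state biological trajectory, and its full
attractor/basin table) used throughout the tests, plus a seeded
generator of random networks and trajectories with known ground truth.
See `docs/methods.md` for the full model, conventions and limitations.

## Worked example

Export the packaged yeast benchmark and analyse its dynamics:

```
$ rbninfer fixture demo
$ rbninfer attractors --edges demo/yeast_edges.tsv --genes demo/yeast_genes.tsv
7 attractors over 2^11 states
  basin   1764  fixed point  00001000100
  basin    151  fixed point  00110000000
  basin    109  fixed point  01001000100
  basin      9  fixed point  00000000100
  basin      7  fixed point  00000000000
  basin      7  fixed point  01000000100
  basin      1  fixed point  00001000000
```

All seven attractors are fixed points; the dominant one (basin 1,764 of
the 2,048 states, ~86%) is the stationary G1 state — Cdh1 and Sic1 on,
everything else off. Now infer consistent regulator rows from the
13-state trajectory and rank the interactions:

```
$ rbninfer infer --trajectory demo/yeast_trajectory.tsv \
    --genes demo/yeast_genes.tsv --mode enumerate --outdir demo/run
determined (nonzero) 8, partially determined 15, undetermined 98

$ rbninfer rank --frequencies demo/run/frequencies.csv \
    --reference-edges demo/yeast_edges.tsv --reference-genes demo/yeast_genes.tsv \
    --out demo/ranks.csv
55 ranked pairs written to demo/ranks.csv
  true positives in top   5: 100.0%
  true positives in top  10: 100.0%
  true positives in top  15:  86.7%
  true positives in top  20:  75.0%
  true positives in top  25:  76.0%
```

Of the 121 possible connections, 8 are fully determined with a nonzero
sign by the 13 observed states — every one of the ~1.9M candidate rows
per gene that survives the constraints agrees on them — and 15 more have
one relationship type ruled out. The top-ranked pair (`demo/ranks.csv`)
is Clb5–Mcm1 at rank 1.64 of 2; every one of the ten highest-ranked
pairs is a real edge of the benchmark network, and the true-positive
rate never drops below 75% through the top 25.

The same pipeline is available as a library:

```python
from rbninfer import (yeast_fixture, infer_rowsets, connection_frequencies,
                      classify_connections, rank_interactions)

fx = yeast_fixture()
rowsets = infer_rowsets([fx.trajectory], fx.network.self_degradation)
table = connection_frequencies(rowsets, fx.network.panel)
print(classify_connections(table).determined_nonzero)   # 8
print(rank_interactions(table).pairs[0])                # (1.6438…, 'Clb5', 'Mcm1')
```

`rbninfer binarize` thresholds continuous expression at each gene's
mean, `rbninfer synth` draws seeded ground-truth benchmarks, and
`rbninfer induce` scores which single connection assignment would
determine the most others.

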