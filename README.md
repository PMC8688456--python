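# molconduct

Boiling points are hard to measure for many alkanes (impurities broaden the
experimental ranges, and data is simply missing for large parts of chemical
space), yet they matter for classifying and selecting lubricant components.
`molconduct` implements a single-variable quantitative structure–property
model for alkane boiling points built on one topological descriptor of the
carbon skeleton — the **conduction** of a molecular graph — together with the
tooling a user needs around it: a carbon-skeleton SMILES/edge-list reader,
generators and enumeration for alkane graph families, exact descriptor
computation, model fitting, and reproduction of the published reference
tables that are packaged as CSV fixtures.

It is intended for cheminformatics practitioners and graph-theory researchers
who want to compute the descriptor exactly, audit the published numbers, or
extend the model.

## The descriptor and the model

An alkane C<sub>n</sub>H<sub>2n+2</sub> is represented by its
hydrogen-suppressed carbon skeleton: a free tree *G* on *n* vertices with
maximum degree 4. For a vertex *v*, let *T<sub>v</sub>* be a breadth-first
search tree of *G* rooted at *v*, chosen among all BFS trees to minimise the
sum of distances from *v* to the end vertices (childless vertices)
*S<sub>v</sub>* of the tree. The score of *v* is

```
s(v) = deg²(v) · Σ_{x ∈ S_v} d(v, x)
```

and the conduction of the graph is the average `c(G) = (1/n) Σ_v s(v)`.
On a tree the minimising BFS tree is the tree itself and the end vertices are
the leaves other than the root; on a general graph the package minimises the
end-vertex sum exactly with a maximum bipartite matching between consecutive
BFS layers (validated against exhaustive enumeration). All descriptor
arithmetic is exact rational; e.g. 2,2,3,3-tetramethylbutane has
`c = 366/8 = 45.75`.

Four structural series have closed-form or fitted conduction values as a
function of the order *n*:

| series | alkane family | conduction |
|---|---|---|
| P<sub>n</sub> | normal alkanes | `4n − 10 + 6/n` |
| B<sub>n,2</sub> | 2-methyl | `6n − 21 + 27/n` |
| B<sub>n,3</sub> | 2,2-dimethyl | `8n − 38 + 78/n` |
| E<sub>n</sub> | high-conduction isomers | `(4/9)n² + 3.44857532·n − 14.95083692 + 18.25213877/n` (fitted) |

For each series a published model of the form
`b = α·c + β + α₁·log_{α₂}(α₃·c + α₄)` maps conduction to a boiling point.
To predict the boiling point of **any** alkane of order *n*, the package
evaluates the four series at that order to obtain four anchor points
(x<sub>i</sub>, y<sub>i</sub>), fits the ordinary-least-squares line
`b = λ·c + γ` through them, and applies it to the compound's conduction. The
coefficient of determination `R² = 1 − RSS/TSS` quantifies fit quality
throughout.

## Worked example

```
$ molconduct conduction --smiles "CC(C)(C)C(C)(C)C"
c = 45.75 (366/8)
```

The descriptor is reported as a decimal and as the exact fraction: the eight
vertex scores of 2,2,3,3-tetramethylbutane (13 for each of the six methyl
carbons, 144 for each quaternary carbon) sum to 366.

```
$ molconduct predict --smiles "CC(C)CCCCC"
n = 8  c = 30.375 (243/8)  lambda = -0.7152  gamma = 139.3630  bp = 117.6 C
```

For 2-methylheptane (order 8) the four anchors give the line
`b = −0.7152·c + 139.363`; at `c = 243/8` the predicted boiling point is
117.6 °C (experimental: 117.6 °C).

```
$ molconduct enumerate --n 6
5 alkanes of order 6:
  C(CCC)CC  c = 15 (90/6)
  ...
$ molconduct validate
T4 2-Methylbutane: printed 14.5, recomputed 72/5 = 14.40000
T9 3-Methylheptane: printed 25.875, recomputed 231/8 = 28.87500
2 discrepancies (known printed errata: 2)
```

`enumerate` lists the constitutional isomers of an order (free trees with
degree ≤ 4, one per isomorphism class); `validate` recomputes every printed
conduction value in the packaged tables exactly and reports the two rows of
the source tables that are arithmetically inconsistent with the descriptor's
own definition. `molconduct reproduce --table 7|8|9` rebuilds a full
prediction table and compares it cell by cell against the printed one.

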