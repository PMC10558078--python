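# hyperfix

Fixation probabilities for constant-selection birth-death dynamics on
hypergraphs.

## The problem

Evolutionary graph theory asks how population structure shapes the fate of
a mutant: a mutant type A with constant relative fitness *r* competes with
a resident type B (fitness 1) on a network, one fitness-proportional birth
replacing neighbours per step, until one type occupies every node. On
conventional networks under this birth-death updating, most structures are
*amplifiers* of selection: a single uniformly placed mutant fixates with
probability above the well-mixed (Moran) baseline for every *r* > 1 and
below it for every *r* < 1. `hyperfix` implements the corresponding
dynamics when interactions are grouped into hyperedges rather than
pairwise, where the picture reverses: the symmetric hypergraph families
analysed here — and degree/size-preserving randomizations of arbitrary
ones — turn out to be *suppressors* of selection.

Two update rules are provided. In each time step a parent is chosen with
probability proportional to fitness and selects one of its incident
hyperedges *e* uniformly at random (duplicated hyperedges act as integer
weights). Under **model 1** the parent converts every other member of *e*
to its own type. Under **model 2** (majority rule) the conversion happens
only if the parent's type is held by strictly more than half of the nodes
of *e*, parent included; ties and minority parents change nothing, and the
dynamics can be trapped forever in non-unanimous cycling configurations.

The baseline is the Moran fixation probability

    x_i = (1 − r^{−i}) / (1 − r^{−N}),          x_i → i/N  as  r → 1,

for *i* initial mutants among *N* individuals. Under model 1 neutral drift
obeys x_i = i/N on *every* connected hypergraph (proved by a coupling over
neutral type labels), which is what makes the amplifier/suppressor
comparison meaningful; model 2 violates it, and such curves are reported
as "neither amplifier nor suppressor".

## What the package computes

- **Exact, symmetry-reduced chains** for the complete, cyclic and star
  3-uniform hypergraph families: pentadiagonal or tridiagonal mutant-count
  chains, and a 2N-state (hub type, mutant leaf count) chain for the star,
  solved as banded or sparse absorbing linear systems (a PTRANS-II-style
  pentadiagonal solver is available behind a flag).
- **Printed closed forms** for small sizes (and any N for the
  majority-rule complete family), used as cross-checks.
- **A brute-force 2^N oracle** for arbitrary connected hypergraphs with
  N ≤ 14, valid for both models; closed recurrent classes (the model-2
  non-fixation pathology) are detected via strongly connected components.
- **Stochastic simulation** for hypergraphs of any size, with the per-node
  initialization protocol, reproducible counter-based substreams, and
  Wilson 95% intervals.
- **Structure tools**: generators for the symmetric families, plain-text
  hyperedge-list I/O, weighted/unweighted one-mode projection, and
  degree/size-preserving randomization by bipartite double-edge swaps.
- **Classification** of fixation curves as amplifier / suppressor /
  equivalent / neither against the Moran baseline.

## Worked example

```python
from hyperfix import (classify_selection, default_r_grid,
                      estimate_fixation, family_fixation,
                      fixation_curve_exact, make_model_hypergraph)

# exact single-mutant fixation probability, star 3-uniform hypergraph
curve = fixation_curve_exact("star3", 1, 1, default_r_grid(), N=20)
print(classify_selection(curve).classification)

# majority rule on the 5-node star: x_2 at neutrality
print(family_fixation("star3", 2, 5, 1.0, 2))   # 0.2571428571428571 = 9/35

# Monte-Carlo estimate vs exact value
H = make_model_hypergraph("star3", 8)
est = estimate_fixation(H, 1, 2.0, 1, runs_per_start=1000, seed=7)
print(est.estimate, family_fixation("star3", 1, 8, 2.0, 1))
```

prints

```
suppressor
0.2571428571428571
0.423125 0.42643596179655235
```

The verdict says the 20-node star 3-uniform hypergraph suppresses
selection (its x_1 is below Moran for every r > 1 on the grid and above it
for every r < 1). The value 9/35 ≈ 0.257 differs from the Moran 2/5: the
majority rule breaks the neutral anchor, so that structure is neither an
amplifier nor a suppressor. The last line shows an 8000-run estimate
within sampling error of the exact reduced-chain solution.

Narrative scripts in `examples/` cover each capability: exact curves and
verdicts, the brute-force oracle (including a 6-node majority-rule example
that provably never fixates), simulation calibration, and
projection/randomization. A thin CLI mirrors the library:

```sh
hyperfix exact --family complete3 --N 20 --out curve.csv
hyperfix classify curve.csv --N 20 --i 1
```

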