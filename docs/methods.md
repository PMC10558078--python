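# Methods

## Models

A population of N individuals occupies the nodes of a connected undirected
hypergraph H = (V, E). Each node carries type A (the mutant, fitness r > 0)
or type B (the resident, fitness 1); fitness is constant (no
frequency dependence, no mutation). One update step:

1. choose a parent node with probability proportional to fitness,
   i.e. r·i/(r·i + N − i) in total for the mutants when i of them are present;
2. the parent picks one hyperedge e uniformly at random from the
   hyperedges it belongs to, *regardless of the size of e* (a hyperedge
   stored with multiplicity m is picked with probability proportional
   to m — this is how integer weights are encoded);
3. **model 1**: every other node of e adopts the parent's type.
   **model 2**: the same, but only if the parent's type is held by strictly
   more than half of the nodes of e (parent included); ties on even-sized
   hyperedges and minority parents change nothing.

Fixation means unanimity. Model 1 on a connected hypergraph fixates with
probability 1. Model 2 need not: the chain can enter a closed recurrent
class of non-unanimous states (e.g. six nodes, hyperedges
{0,1,2},{2,3,4},{3,4,5},{0,1,5}, mutants on {0,1}: nodes 3,4 remain
resident and 2,5 toggle forever). On the complete graph (all 2-subsets)
model 1 is exactly the Moran process.

Initial conditions are uniform: i mutants placed uniformly at random.
Under model 1 at r = 1 the uniform-i fixation probability is i/N on every
connected hypergraph (coupling argument with N neutral labels), so curves
are compared against the Moran baseline x_i = (1 − r^{−i})/(1 − r^{−N}).
Model 2 breaks the i/N anchor (a lone mutant can never recruit, so
x_1 = 0 always), which restricts the amplifier/suppressor question there.

## Exact reduced chains

For three symmetric families the 2^N-state chain collapses:

- **complete 3-uniform** (all 3-subsets): the mutant count i is a Markov
  chain. A step changes i by at most 2 (model 1; pentadiagonal transition
  matrix) or 1 (model 2; tridiagonal). Transition probabilities are
  products of the parent-choice probability and hypergeometric
  hyperedge-composition probabilities with denominator (N−1)(N−2).
- **cyclic 3-uniform** (consecutive triples on a ring): from a single
  mutant, the mutant set stays a contiguous arc under model 1, so the arc
  length is Markov (pentadiagonal; the boundary rows differ from the
  interior ones). The reduction is valid only for i = 1 or an initially
  contiguous arc; the package therefore exposes uniform initialization
  only for i = 1 and raises otherwise.
- **star 3-uniform** (hub + all leaf pairs): the state is
  (hub type, number of mutant leaves), a 2N-state sparse chain for either
  model. The hub belongs to C(N−1, 2) hyperedges and each leaf to N−2
  (hub + itself + one of the other N−2 leaves). Uniform initialization
  mixes the solved vector: x_i = (i/N)·x̃(1, i−1) + ((N−i)/N)·x̃(0, i).

Fixation probabilities solve M x = b, where M equals P − I on transient
rows, the two absorbing rows are identity rows, and b selects the
all-mutant state. Banded systems go through `scipy.linalg.solve_banded`;
an optional PTRANS-II-style pentadiagonal elimination (`method="ptrans2"`)
is provided and tested to agree to 1e−10 (the original motivation for
PTRANS-type solvers is speed, not accuracy, so the generic banded LU is
the default). The star system uses sparse LU. The solver enforces a
residual ‖Mx − b‖∞ < 1e−10 and raises if probabilities leave [0, 1] by
more than 1e−12; smaller excursions are clipped.

Closed forms are implemented for N ∈ {4, 5} (model 1, i = 1; star and
cyclic model 2, i = 2) and for the majority-rule complete family at any N,
where the birth-death ratio γ_k = (N−k−1)/(r(k−1)) telescopes to
x_2 = (1 + 1/r)^{3−N} and partial sums give x_i, i ≤ N−2. The cyclic
model-2 expression is evaluated in the algebraically equivalent form
x_2 = (2/(N−1))·(2r+5)/((r+4)·S), S = Σ_{k=0}^{N−3} r^{−k}, which is
finite and stable at r = 1 (value 14/[5(N−1)(N−2)]). Closed forms were
accepted only after agreeing with the exhaustive solver at small N; the
derived star chain reproduces them at N ∈ {4, 5} for both models.

## Brute-force oracle

For any connected hypergraph with N ≤ 14 the full kernel over 2^N bitmask
states is assembled exactly as defined above. Closed recurrent classes are
found as strongly connected components without outgoing edges; every
closed class other than {all-A} gets absorption value 0 (this makes the
model-2 system well-posed), and the transient block is solved by sparse
LU. Uniform-i values average the solution over all C(N, i) initial
bitmasks. Resident-fixation probabilities follow by the type-relabelling
symmetry (swap A and B, replace r by 1/r).

## Simulation

The simulator executes the update rule literally on per-node incidence
lists. Parent selection draws the parent *type* from the fitness ratio and
then rejection-samples a uniform node of that type (cost O(N/n_type) per
draw, negligible at the sizes used). Single-mutant estimation follows the
per-node protocol: every node serves as the initial mutant in turn, with
`runs_per_start` runs each (defaults 3000 for r ≥ 1 and 40000 for r < 1,
where fixation is rare and needs more runs); for i ≥ 2 the mutant set is
redrawn uniformly per run (enumeration of all C(N, i) subsets is available
behind a flag for small N). Each run's RNG is seeded from
`SeedSequence(root, spawn_key=(start, run))`, so results are independent
of execution order and fully reproducible. Step caps: 10⁴·N for model 1
(fixation is almost sure; the cap only guards pathological inputs) and
10³·N² for model 2, whose runs can cycle forever; timed-out model-2 runs
are reported separately and excluded from the estimate's denominator.
Intervals are Wilson score at 95% (well-behaved near 0/1).

## Structure tools

Generators emit the three symmetric families and the complete graph;
`random_hypergraph` draws connected test fixtures with a given hyperedge
count and size support (disconnected draws rejected up to a retry cap).
Randomization performs bipartite double-edge swaps on incidence stubs —
two (hyperedge, slot) positions exchange nodes unless that would repeat a
node within a hyperedge — which preserves every node degree and every
hyperedge size; the default budget is 10× the total incidence count, a
standard mixing heuristic. Connectivity of the output is not enforced
(callers are told whether it held); the one-mode projection encodes edge
weights as duplicated 2-edges so the same dynamics code applies to
weighted projections unchanged.

## Classification

A curve is classified against the Moran baseline on a log-symmetric grid
(default: 25 points on [1/4, 4] with r = 1 snapped exactly). First the
neutral anchor: |x(1) − i/N| must be within tolerance, else the verdict is
`not_comparable` (reported as "neither amplifier nor suppressor" — the
model-2 situation). Then per-point signs of Δ(r) = x(r) − x_Moran(r). A
point is *signed* only when |Δ| exceeds (a) an absolute floor of 1e−11
(linear-solver noise), (b) a relative tolerance of 1e−9 against
max(x, x_Moran), and (c) for simulated curves the 95% half-width. The
relative component is essential: for r < 1 fixation probabilities decay
like r^{N−1}-scale quantities (≈10⁻¹²¹ at N = 200, r = 1/4), so no
absolute tolerance can resolve signs there, and at the smallest r values
the difference genuinely drops below double precision — those points are
treated as carrying no evidence. A suppressor verdict requires every
signed point above r = 1 to be negative, every signed point below to be
positive, and at least one signed point; amplifier mirrors it; a curve
with no signed point is `equivalent`. Refining the grid can only add
consistent or unsigned points, so verdicts are stable under refinement.

## Problem sizes and defaults

Exact family curves are computed at N up to 200 (the star chain solves
400-unknown systems; larger N remains cheap). Oracle cross-checks run the
2^N solver at N ∈ {4,…,8} and on random fixtures at N ≤ 10; projection
comparisons use N ≤ 8. Monte-Carlo calibration uses ≈10⁴ runs per
condition, which puts 3 binomial standard errors at ≈0.015 near p = 0.5
and proportionally tighter at the extremes. Random fixtures default to
hyperedge sizes {2, 3, 4} and ≈1.3N hyperedges — small mixed-size
hypergraphs that exercise multiset semantics, uneven degrees and
non-uniform sizes.

## What the synthetic generator does and does not emulate

`random_hypergraph` produces connected, small, roughly homogeneous
hypergraphs with user-chosen size support. It does not reproduce the
heavy-tailed degree and size distributions, clustering or temporal
structure of empirical interaction data (email, committee or contact
hypergraphs). Passing tests therefore demonstrate correctness of the
solvers and the robustness of the suppression result under
degree/size-preserving rewiring of such fixtures — not a survey claim
about real-world hypergraphs, whose analysis requires loading the actual
data through `read_hyperedge_list` and the simulation path.

## Known limitations

- Exact solutions for arbitrary hypergraphs stop at N = 14 (2^N states).
- Cyclic-family uniform initialization is exact only for i = 1 (model 1)
  and i = 2 (model 2, closed form); other i require brute force.
- Fixation *times*, death-birth updating and dynamic hypergraphs are out
  of scope.
- The randomizer does not guarantee a connected output; rare disconnected
  results are flagged, not repaired.
- Double precision bounds what the classifier can resolve at large N for
  r far below 1; such grid points are reported as unresolved.
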