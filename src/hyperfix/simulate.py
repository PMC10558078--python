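"""Monte-Carlo simulation of the two birth-death models on any hypergraph.

Each update step: a parent is drawn with probability proportional to its
fitness (r for the mutant type A, 1 for the resident type B); the parent
picks one of its incident hyperedges uniformly (duplicated hyperedges act
as integer weights); under model 1 every other member of the hyperedge
copies the parent's type, under model 2 only when the parent's type holds
a strict majority within the hyperedge (ties change nothing).

Runs are reproducible: every run's RNG is seeded from a counter-based
substream of a single root seed, so results do not depend on execution
order.  Model 2 can cycle forever, so runs carry a step cap and timeouts
are a distinct outcome, never silently counted as resident fixation.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .hypergraph import Hypergraph

logger = logging.getLogger(__name__)

__all__ = [
    "SimOutcome",
    "EstimateWithCI",
    "step",
    "run_to_fixation",
    "estimate_fixation",
    "default_max_steps",
]


def default_max_steps(N: int, model: int) -> int:
    """Step caps: model 1 fixates almost surely, model 2 may cycle forever."""
    return 10_000 * N if model == 1 else 1_000 * N * N


@dataclass(frozen=True)
class SimOutcome:
    """Result of a single run: which type fixated (or a timeout) and when."""

    result: str  # "A_fixed" | "B_fixed" | "timeout"
    steps: int
    seed: int


@dataclass(frozen=True)
class EstimateWithCI:
    """Fixation-probability estimate with a 95% Wilson score interval."""

    estimate: float
    ci_low: float
    ci_high: float
    fixations: int
    runs: int
    timeouts: int

    @property
    def stderr(self) -> float:
        p, n = self.estimate, max(self.runs, 1)
        return float(np.sqrt(p * (1 - p) / n))


def _prepare(H: Hypergraph):
    inc = H.incidence()
    if min(len(lst) for lst in inc) == 0:
        raise ValueError("every node must belong to at least one hyperedge")
    edges = [tuple(e) for e in H.hyperedges]
    return [tuple(edges[j] for j in lst) for lst in inc]


def step(
    H: Hypergraph,
    state: list[int] | np.ndarray,
    model: int,
    r: float,
    rng: random.Random | np.random.Generator,
) -> list[int]:
    """One update of the chosen model; returns the new state (input unchanged).

    ``state[v]`` is 1 if node v carries the mutant type A, else 0.
    """
    if r <= 0:
        raise ValueError("relative fitness r must be positive")
    if isinstance(rng, np.random.Generator):
        rng = random.Random(int(rng.integers(0, 2**63)))
    types = list(int(t) for t in state)
    if len(types) != H.N:
        raise ValueError("state length must equal the number of nodes")
    inc = _prepare(H)
    _step_inplace(types, sum(types), H.N, inc, model, r, rng)
    return types


def _step_inplace(types, nA, N, inc, model, r, rng) -> int:
    """Advance one step in place; returns the new mutant count."""
    wA = r * nA
    pick_A = rng.random() * (wA + (N - nA)) < wA
    pt = 1 if pick_A else 0
    while True:  # rejection-sample a uniform node of the parent type
        v = rng.randrange(N)
        if types[v] == pt:
            break
    edges = inc[v]
    e = edges[rng.randrange(len(edges))] if len(edges) > 1 else edges[0]
    if model == 1:
        for u in e:
            if types[u] != pt:
                types[u] = pt
                nA += 1 if pt else -1
    else:
        same = sum(1 for u in e if types[u] == pt)
        if 2 * same > len(e):
            for u in e:
                if types[u] != pt:
                    types[u] = pt
                    nA += 1 if pt else -1
    return nA


def run_to_fixation(
    H: Hypergraph,
    model: int,
    r: float,
    init: set[int] | frozenset[int] | tuple[int, ...] | list[int],
    seed: int = 0,
    max_steps: int | None = None,
) -> SimOutcome:
    """Iterate the dynamics from ``init`` (the set of mutant nodes) to fixation.

    Deterministic given ``seed``; stops with ``"timeout"`` after
    ``max_steps`` updates (default :func:`default_max_steps`).
    """
    if r <= 0:
        raise ValueError("relative fitness r must be positive")
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    N = H.N
    inc = _prepare(H)
    if max_steps is None:
        max_steps = default_max_steps(N, model)
    types = [0] * N
    for v in init:
        if not 0 <= v < N:
            raise ValueError(f"mutant node {v} outside [0, {N})")
        types[v] = 1
    nA = sum(types)
    rng = random.Random(seed)
    steps = 0
    while 0 < nA < N and steps < max_steps:
        nA = _step_inplace(types, nA, N, inc, model, r, rng)
        steps += 1
    if nA == N:
        result = "A_fixed"
    elif nA == 0:
        result = "B_fixed"
    else:
        result = "timeout"
    return SimOutcome(result=result, steps=steps, seed=seed)


def _substream_seed(root_seed: int, start: int, run: int) -> int:
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(start, run))
    return int(ss.generate_state(1, dtype=np.uint64)[0] & 0x7FFF_FFFF_FFFF_FFFF)


def estimate_fixation(
    H: Hypergraph,
    model: int,
    r: float,
    i: int,
    runs_per_start: int | None = None,
    seed: int = 0,
    max_steps: int | None = None,
    enumerate_starts: bool = False,
) -> EstimateWithCI:
    """Estimate the uniform-initialization fixation probability of ``i`` mutants.

    For ``i = 1`` every node serves as the initial mutant in turn, with
    ``runs_per_start`` runs each (the per-node protocol; defaults to 3000
    for r >= 1 and 40000 for r < 1).  For ``i >= 2`` the initial mutant set
    is redrawn uniformly for each of ``N * runs_per_start`` runs, or, with
    ``enumerate_starts`` and small N, cycled over all C(N, i) subsets.

    The estimate is the fraction of completed runs fixing the mutant type;
    under model 2 timed-out runs are excluded from the denominator (and
    logged), since the dynamics can cycle forever.
    """
    N = H.N
    if not 1 <= i <= N - 1:
        raise ValueError(f"i={i} outside [1, {N - 1}]")
    if runs_per_start is None:
        runs_per_start = 3_000 if r >= 1 else 40_000
    if max_steps is None:
        max_steps = default_max_steps(N, model)
    inc = _prepare(H)

    if i == 1:
        starts = [(v,) for v in range(N)]
        plan = [(s_idx, k) for s_idx, _ in enumerate(starts) for k in range(runs_per_start)]
    elif enumerate_starts:
        starts = list(combinations(range(N), i))
        plan = [(s_idx, k) for s_idx, _ in enumerate(starts) for k in range(runs_per_start)]
    else:
        starts = None
        plan = [(0, k) for k in range(N * runs_per_start)]

    fixations = 0
    timeouts = 0
    completed = 0
    for s_idx, k in plan:
        run_seed = _substream_seed(seed, s_idx, k)
        rng = random.Random(run_seed)
        types = [0] * N
        if starts is not None:
            init = starts[s_idx]
        else:
            init = rng.sample(range(N), i)
        for v in init:
            types[v] = 1
        nA = i
        steps = 0
        while 0 < nA < N and steps < max_steps:
            nA = _step_inplace(types, nA, N, inc, model, r, rng)
            steps += 1
        if nA == N:
            fixations += 1
            completed += 1
        elif nA == 0:
            completed += 1
        else:
            timeouts += 1
            if model == 1:
                completed += 1  # model 1 fixates a.s.; a capped run counts as no fixation

    if timeouts and model == 2:
        logger.info(
            "model 2: %d/%d runs timed out and were excluded from the denominator",
            timeouts, len(plan),
        )
    denom = max(completed, 1)
    est = fixations / denom
    lo, hi = proportion_confint(fixations, denom, alpha=0.05, method="wilson")
    return EstimateWithCI(
        estimate=est,
        ci_low=float(lo),
        ci_high=float(hi),
        fixations=fixations,
        runs=completed,
        timeouts=timeouts,
    )
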