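"""Hypergraph container, symmetric-family generators, I/O and rewiring.

A hypergraph is a node set together with a *multiset* of hyperedges, each a
set of one or more distinct nodes.  Duplicate hyperedges are allowed and are
how integer edge weights are encoded: dynamics that select a hyperedge
uniformly from a node's incidence list then automatically select
weight-proportionally.  Nodes are 0-based internally; external string labels
from files are preserved through a label table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Hypergraph",
    "DegreeSizeProfile",
    "make_model_hypergraph",
    "is_connected",
    "degree_size_profile",
    "one_mode_projection",
    "randomize_hypergraph",
    "random_hypergraph",
    "read_hyperedge_list",
    "write_hyperedge_list",
]


@dataclass(frozen=True)
class Hypergraph:
    """An undirected hypergraph on nodes ``0..N-1``.

    Parameters
    ----------
    N
        Number of nodes.
    hyperedges
        Ordered multiset of hyperedges; each hyperedge is stored as a sorted
        tuple of distinct node indices.  Duplicates are permitted.
    labels
        Optional external labels, ``labels[v]`` naming node ``v``.
    """

    N: int
    hyperedges: tuple[tuple[int, ...], ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"need at least one node, got N={self.N}")
        canon = []
        for e in self.hyperedges:
            t = tuple(sorted(e))
            if len(set(t)) != len(t):
                raise ValueError(f"hyperedge {e} contains a repeated node")
            if not t:
                raise ValueError("empty hyperedge")
            if t[0] < 0 or t[-1] >= self.N:
                raise ValueError(f"hyperedge {e} has node outside [0, {self.N})")
            if len(t) == 1:
                warnings.warn(
                    "size-1 hyperedge accepted; reproduction through it is a no-op",
                    stacklevel=2,
                )
            canon.append(t)
        object.__setattr__(self, "hyperedges", tuple(canon))
        if self.labels is not None:
            if len(self.labels) != self.N:
                raise ValueError("labels must have one entry per node")
            object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def M(self) -> int:
        """Number of hyperedges (with multiplicity)."""
        return len(self.hyperedges)

    def incidence(self) -> list[list[int]]:
        """Per-node list of incident hyperedge indices (with multiplicity)."""
        inc: list[list[int]] = [[] for _ in range(self.N)]
        for j, e in enumerate(self.hyperedges):
            for v in e:
                inc[v].append(j)
        return inc

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.N, dtype=int)
        for e in self.hyperedges:
            for v in e:
                deg[v] += 1
        return deg

    def edge_multiset(self) -> dict[tuple[int, ...], int]:
        counts: dict[tuple[int, ...], int] = {}
        for e in self.hyperedges:
            counts[e] = counts.get(e, 0) + 1
        return counts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypergraph):
            return NotImplemented
        return (
            self.N == other.N
            and self.edge_multiset() == other.edge_multiset()
            and self.labels == other.labels
        )

    def __hash__(self) -> int:  # frozen dataclass requires explicit pair
        return hash((self.N, tuple(sorted(self.hyperedges)), self.labels))


@dataclass(frozen=True)
class DegreeSizeProfile:
    """Per-node degrees and per-hyperedge sizes (both with multiplicity)."""

    degrees: tuple[int, ...]
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.degrees) != sum(self.sizes):
            raise ValueError("sum of degrees must equal sum of sizes")


def make_model_hypergraph(family: str, N: int) -> Hypergraph:
    """Build one of the symmetric model (hyper)graphs.

    ``complete3``: every 3-subset of nodes is a hyperedge (N >= 3).
    ``cyclic3``: hyperedges are all triples of consecutive nodes on a ring
    (N >= 4; at N = 3 it would coincide with complete3).
    ``star3``: node 0 is the hub; hyperedges are {hub, leaf, leaf} over all
    leaf pairs (N >= 4).
    ``complete_graph``: the ordinary complete graph, i.e. all 2-subsets
    (N >= 2); birth-death dynamics on it is the Moran process.
    """
    if family == "complete3":
        if N < 3:
            raise ValueError("complete3 requires N >= 3")
        edges = [tuple(c) for c in combinations(range(N), 3)]
    elif family == "cyclic3":
        if N < 4:
            raise ValueError("cyclic3 requires N >= 4 (N = 3 is complete3)")
        edges = [tuple(sorted(((k) % N, (k + 1) % N, (k + 2) % N))) for k in range(N)]
    elif family == "star3":
        if N < 4:
            raise ValueError("star3 requires N >= 4 (N = 3 is complete3)")
        edges = [(0, a, b) for a, b in combinations(range(1, N), 2)]
    elif family == "complete_graph":
        if N < 2:
            raise ValueError("complete_graph requires N >= 2")
        edges = [tuple(c) for c in combinations(range(N), 2)]
    else:
        raise ValueError(
            f"unknown family {family!r}; expected one of "
            "complete3, cyclic3, star3, complete_graph"
        )
    return Hypergraph(N=N, hyperedges=tuple(edges))


def is_connected(H: Hypergraph) -> bool:
    """True iff every bipartition of the nodes is crossed by some hyperedge.

    Equivalent to connectivity of the bipartite node-hyperedge incidence
    graph once every node is required to be reachable; an isolated node
    (degree 0) with N >= 2 makes the hypergraph disconnected.
    """
    if H.N == 1:
        return True
    G = nx.Graph()
    G.add_nodes_from(range(H.N))
    for j, e in enumerate(H.hyperedges):
        he = ("e", j)
        for v in e:
            G.add_edge(v, he)
    return nx.is_connected(G)


def degree_size_profile(H: Hypergraph) -> DegreeSizeProfile:
    return DegreeSizeProfile(
        degrees=tuple(int(d) for d in H.degrees()),
        sizes=tuple(len(e) for e in H.hyperedges),
    )


def one_mode_projection(H: Hypergraph, weighted: bool = True) -> Hypergraph:
    """Project onto an ordinary graph: nodes adjacent iff they co-occur.

    The weighted variant emits the pair {u, v} once per hyperedge shared by
    u and v (weights as duplicated 2-edges); the unweighted variant emits
    each adjacent pair exactly once.
    """
    counts: dict[tuple[int, int], int] = {}
    for e in H.hyperedges:
        for u, v in combinations(e, 2):
            counts[(u, v)] = counts.get((u, v), 0) + 1
    edges: list[tuple[int, int]] = []
    for pair in sorted(counts):
        mult = counts[pair] if weighted else 1
        edges.extend([pair] * mult)
    return Hypergraph(N=H.N, hyperedges=tuple(edges), labels=H.labels)


def randomize_hypergraph(
    H: Hypergraph, n_swaps: int | None = None, seed: int | np.random.Generator = 0
) -> Hypergraph:
    """Shuffle hyperedge membership preserving node degrees and edge sizes.

    Performs bipartite double-edge swaps on the incidence structure: two
    incidence stubs (hyperedge slot, node) are chosen at random and their
    nodes exchanged.  A proposal that would duplicate a node inside a
    hyperedge, or that swaps a node with itself, is rejected and does not
    count as an accepted swap.  Connectivity of the output is not enforced.

    ``n_swaps`` defaults to 10x the total number of incidences.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = [list(e) for e in H.hyperedges]
    total_inc = sum(len(e) for e in edges)
    if n_swaps is None:
        n_swaps = 10 * total_inc
    if len(edges) < 2 or total_inc < 2:
        if n_swaps > 0:
            logger.warning("no feasible swap exists; returning an unchanged copy")
        return Hypergraph(N=H.N, hyperedges=tuple(tuple(e) for e in edges), labels=H.labels)

    # flat stub list: stub k sits in hyperedge owner[k] at slot slot[k]
    owner = np.repeat(np.arange(len(edges)), [len(e) for e in edges])
    slot = np.concatenate([np.arange(len(e)) for e in edges])
    accepted = 0
    attempts = 0
    max_attempts = 100 * n_swaps + 100
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        k1, k2 = rng.integers(0, total_inc, size=2)
        e1, s1 = owner[k1], slot[k1]
        e2, s2 = owner[k2], slot[k2]
        if e1 == e2:
            continue
        u, v = edges[e1][s1], edges[e2][s2]
        if u == v or u in edges[e2] or v in edges[e1]:
            continue
        edges[e1][s1], edges[e2][s2] = v, u
        accepted += 1
    if accepted == 0 and n_swaps > 0:
        logger.warning("no swap was ever feasible; returning an unchanged copy")
    return Hypergraph(
        N=H.N, hyperedges=tuple(tuple(sorted(e)) for e in edges), labels=H.labels
    )


def random_hypergraph(
    N: int,
    M: int,
    sizes: tuple[int, ...] = (2, 3, 4),
    seed: int | np.random.Generator = 0,
    max_retries: int = 200,
) -> Hypergraph:
    """Draw a connected random hypergraph with ``M`` hyperedges.

    Each hyperedge's size is drawn uniformly from ``sizes`` (clipped to N)
    and its members uniformly without replacement.  Disconnected draws are
    rejected up to ``max_retries``.
    """
    if N < 2 or M < 1:
        raise ValueError("need N >= 2 and M >= 1")
    sizes = tuple(s for s in sizes if 2 <= s <= N)
    if not sizes:
        raise ValueError("no feasible hyperedge size in [2, N]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_retries):
        edges = []
        for _ in range(M):
            k = int(rng.choice(sizes))
            edges.append(tuple(sorted(rng.choice(N, size=k, replace=False).tolist())))
        H = Hypergraph(N=N, hyperedges=tuple(edges))
        if is_connected(H):
            return H
    raise RuntimeError(
        f"failed to draw a connected hypergraph in {max_retries} tries; "
        "increase M or allow larger hyperedges"
    )


def read_hyperedge_list(path) -> Hypergraph:
    """Read a plain-text hyperedge list: one hyperedge per line.

    Tokens are whitespace-separated node labels; blank lines and lines
    starting with ``#`` are skipped.  Labels map to 0-based indices in order
    of first appearance and are retained on the result.
    """
    label_to_idx: dict[str, int] = {}
    edges: list[tuple[int, ...]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(set(tokens)) != len(tokens):
                raise ValueError(f"{path}:{lineno}: repeated label within a hyperedge")
            idx = []
            for tok in tokens:
                if tok not in label_to_idx:
                    label_to_idx[tok] = len(label_to_idx)
                idx.append(label_to_idx[tok])
            edges.append(tuple(sorted(idx)))
    if not edges:
        raise ValueError(f"{path}: no hyperedges found")
    labels = tuple(sorted(label_to_idx, key=label_to_idx.get))
    return Hypergraph(N=len(labels), hyperedges=tuple(edges), labels=labels)


def write_hyperedge_list(H: Hypergraph, path) -> None:
    """Write ``H`` in the one-hyperedge-per-line text format."""
    labels = H.labels or tuple(str(v) for v in range(H.N))
    with open(path, "w", encoding="utf-8") as fh:
        for e in H.hyperedges:
            fh.write(" ".join(labels[v] for v in e) + "\n")


def profile_to_csv(H: Hypergraph, path) -> None:
    """Export the degree/size profile as two CSV tables in one file."""
    import pandas as pd

    prof = degree_size_profile(H)
    deg = pd.DataFrame({"node": range(H.N), "degree": prof.degrees})
    siz = pd.DataFrame({"hyperedge": range(H.M), "size": prof.sizes})
    with open(path, "w", encoding="utf-8") as fh:
        deg.to_csv(fh, index=False)
        fh.write("\n")
        siz.to_csv(fh, index=False)
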