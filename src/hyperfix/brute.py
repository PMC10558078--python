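"""Brute-force 2^N absorption solver, valid for arbitrary hypergraphs.

Enumerates every type configuration as a bitmask (bit v set = node v
carries the mutant type A), builds the exact one-step transition kernel
from the model definition, and solves the absorption problem for the
all-A state.  Under the majority-rule model the chain can possess closed
recurrent classes other than the two unanimous states (the dynamics then
never fixates from some initial conditions); every closed class other than
{all-A} is assigned absorption probability 0 before the transient states
are solved.

Exponential in N; capped at N <= 14.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .hypergraph import Hypergraph, is_connected

__all__ = ["brute_force_vector", "brute_force_fixation"]

_N_CAP = 14


def _transition_matrix(H: Hypergraph, model: int, r: float) -> sp.csr_matrix:
    N = H.N
    nstates = 1 << N
    inc = H.incidence()
    deg = [len(lst) for lst in inc]
    if min(deg) == 0:
        raise ValueError("every node must belong to at least one hyperedge")
    edge_masks = []
    edge_sizes = []
    for e in H.hyperedges:
        m = 0
        for v in e:
            m |= 1 << v
        edge_masks.append(m)
        edge_sizes.append(len(e))

    rows, cols, vals = [], [], []
    for s in range(nstates):
        a = s.bit_count()
        F = r * a + (N - a)
        for v in range(N):
            is_A = (s >> v) & 1
            pv = (r if is_A else 1.0) / (F * deg[v])
            for j in inc[v]:
                m = edge_masks[j]
                if model == 1:
                    t = (s | m) if is_A else (s & ~m)
                else:
                    k = edge_sizes[j]
                    in_e_A = (s & m).bit_count()
                    same = in_e_A if is_A else k - in_e_A
                    if 2 * same > k:
                        t = (s | m) if is_A else (s & ~m)
                    else:
                        t = s
                rows.append(s)
                cols.append(t)
                vals.append(pv)
    P = sp.csr_matrix((vals, (rows, cols)), shape=(nstates, nstates))
    P.sum_duplicates()
    return P


def brute_force_vector(H: Hypergraph, model: int, r: float) -> np.ndarray:
    """Fixation probability of the mutant type from every one of the 2^N states.

    Returns a vector indexed by the bitmask state (bit v = node v mutant).
    """
    if H.N > _N_CAP:
        raise ValueError(f"brute force capped at N <= {_N_CAP}, got N={H.N}")
    if r <= 0:
        raise ValueError("relative fitness r must be positive")
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    if not is_connected(H):
        raise ValueError("hypergraph must be connected")

    N = H.N
    nstates = 1 << N
    all_A = nstates - 1
    P = _transition_matrix(H, model, r)

    # closed recurrent classes: strongly connected components with no
    # outgoing edge; {all-A} and {all-B} are always among them
    n_comp, labels = connected_components(P, directed=True, connection="strong")
    has_exit = np.zeros(n_comp, dtype=bool)
    Pc = P.tocoo()
    off_diag = labels[Pc.row] != labels[Pc.col]
    np.logical_or.at(has_exit, labels[Pc.row[off_diag]], True)

    x = np.full(nstates, np.nan)
    known = np.zeros(nstates, dtype=bool)
    closed = ~has_exit[labels]
    x[closed] = 0.0
    known[closed] = True
    x[all_A] = 1.0  # the all-A class is {all_A} itself

    trans = ~known
    if trans.any():
        idx = np.flatnonzero(trans)
        Ptt = P[idx][:, idx]
        Ptk = P[idx][:, known]
        A = sp.identity(len(idx), format="csc") - Ptt.tocsc()
        rhs = Ptk @ x[known]
        x[idx] = spsolve(A, rhs)

    if x.min() < -1e-10 or x.max() > 1 + 1e-10:
        raise ArithmeticError("brute-force probabilities escaped [0, 1]")
    return np.clip(x, 0.0, 1.0)


def brute_force_fixation(
    H: Hypergraph,
    model: int,
    r: float,
    mutants: set[int] | frozenset[int] | tuple[int, ...] | None = None,
    i: int | None = None,
) -> float:
    """Exact fixation probability by full-state enumeration.

    Either ``mutants`` (an explicit set of initially mutant nodes) or ``i``
    (uniform initialization: average over all C(N, i) placements) must be
    given.
    """
    if (mutants is None) == (i is None):
        raise ValueError("give exactly one of `mutants` or `i`")
    x = brute_force_vector(H, model, r)
    if mutants is not None:
        s = 0
        for v in mutants:
            if not 0 <= v < H.N:
                raise ValueError(f"mutant node {v} outside [0, {H.N})")
            s |= 1 << v
        return float(x[s])
    if not 0 <= i <= H.N:
        raise ValueError(f"i={i} outside [0, {H.N}]")
    counts = np.array([s.bit_count() for s in range(1 << H.N)])
    return float(x[counts == i].mean())
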