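"""Symmetry-reduced Markov chains and absorption-probability solvers.

For the three symmetric 3-uniform families (complete, cyclic, star) the
2^N-state evolutionary dynamics collapses onto a small chain: the mutant
count ``i`` for the complete and cyclic families, and the pair
``(hub type, number of mutant leaves)`` for the star.  Fixation
probabilities are absorption probabilities of these chains, obtained by
solving ``M x = b`` where ``M`` agrees with ``P - I`` on transient rows and
is the identity on the two absorbing rows, and ``b`` selects the all-mutant
absorbing state.

The complete-family chain is pentadiagonal under model 1 (a single update
can move the mutant count by up to 2) and tridiagonal under model 2; the
cyclic chain is pentadiagonal; the star chain is a general sparse 2N x 2N
matrix.  Banded systems are solved with a banded LU
(``scipy.linalg.solve_banded``) or, optionally, a PTRANS-II-style
pentadiagonal elimination; the star system uses sparse LU.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solve_banded
from scipy.sparse.linalg import spsolve

__all__ = [
    "ReducedChain",
    "AbsorptionSystem",
    "moran_fixation",
    "build_reduced_chain",
    "solve_absorption",
    "star_uniform_mix",
    "family_fixation",
]

_ROW_SUM_TOL = 1e-12
_RESIDUAL_TOL = 1e-10
_CLIP_SLACK = 1e-12


def moran_fixation(N: int, r: float, i: int) -> float:
    """Fixation probability of ``i`` mutants of fitness ``r`` in the Moran process.

    ``x_i = (1 - r^{-i}) / (1 - r^{-N})``, with the neutral limit ``i/N`` at
    ``r = 1``.  Computed via ``expm1`` so the ratio stays accurate for ``r``
    near 1.
    """
    if N < 2:
        raise ValueError("need N >= 2")
    if not 0 <= i <= N:
        raise ValueError(f"initial mutant count i={i} outside [0, {N}]")
    if r <= 0:
        raise ValueError("relative fitness r must be positive")
    if i == 0:
        return 0.0
    if i == N:
        return 1.0
    logr = np.log(r)
    if logr == 0.0:
        return i / N
    return float(np.expm1(-i * logr) / np.expm1(-N * logr))


@dataclass(frozen=True)
class ReducedChain:
    """A symmetry-reduced transition matrix with its absorbing states.

    ``P`` is row-stochastic; ``states`` describes each index (mutant count
    for the linear chains, ``(hub_type, mutant_leaves)`` for the star);
    ``bandwidth`` is the half-bandwidth for banded chains and ``None`` for
    the star chain.
    """

    family: str
    model: int
    N: int
    r: float
    P: sp.csr_matrix
    absorbing: tuple[int, ...]
    fixation_state: int
    states: tuple
    bandwidth: int | None

    @property
    def S(self) -> int:
        return self.P.shape[0]

    def validate(self) -> None:
        P = self.P
        if (P.data < -_ROW_SUM_TOL).any() or (P.data > 1 + _ROW_SUM_TOL).any():
            raise ValueError("transition probabilities outside [0, 1]")
        rows = np.asarray(P.sum(axis=1)).ravel()
        if np.max(np.abs(rows - 1.0)) > _ROW_SUM_TOL:
            raise ValueError("rows of P must sum to 1")
        for a in self.absorbing:
            row = P.getrow(a)
            if row.nnz != 1 or row[0, a] != 1.0:
                raise ValueError(f"absorbing state {a} is not an identity row")


def _linear_chain(family: str, model: int, N: int, r: float) -> ReducedChain:
    """Chains indexed by the mutant count i = 0..N (complete3, cyclic3)."""
    S = N + 1
    rows, cols, vals = [], [], []

    def put(i: int, j: int, p: float) -> None:
        if p != 0.0:
            rows.append(i)
            cols.append(j)
            vals.append(p)

    put(0, 0, 1.0)
    put(N, N, 1.0)
    if family == "complete3":
        D = (N - 1) * (N - 2)
        for i in range(1, N):
            F = r * i + (N - i)
            pA = r * i / F          # a mutant parent is chosen
            pB = (N - i) / F        # a resident parent is chosen
            if model == 1:
                pm2 = pB * i * (i - 1) / D if i >= 2 else 0.0
                pm1 = pB * 2 * i * (N - i - 1) / D
                pp1 = pA * 2 * (i - 1) * (N - i) / D
                pp2 = pA * (N - i) * (N - i - 1) / D if i <= N - 2 else 0.0
            else:
                # majority rule: at most one node flips per step
                pm2 = pp2 = 0.0
                pm1 = pB * 2 * i * (N - i - 1) / D
                pp1 = pA * 2 * (i - 1) * (N - i) / D
            put(i, i - 2, pm2)
            put(i, i - 1, pm1)
            put(i, i + 1, pp1)
            put(i, i + 2, pp2)
            put(i, i, 1.0 - pm2 - pm1 - pp1 - pp2)
    elif family == "cyclic3":
        if model != 1:
            raise NotImplementedError(
                "cyclic3 model 2 has no reduced chain here; use closed_form_fixation"
            )
        # valid when the mutants occupy a contiguous arc (always true from i=1)
        F1 = r + N - 1
        put(1, 0, 2.0 / F1)
        put(1, 3, r / F1)
        put(1, 1, (N - 3) / F1)
        for i in range(2, N - 1):
            F = r * i + (N - i)
            pm2 = 2.0 / (3.0 * F)
            pm1 = 4.0 / (3.0 * F)
            pp1 = 4.0 * r / (3.0 * F)
            pp2 = 2.0 * r / (3.0 * F)
            put(i, i - 2, pm2)
            put(i, i - 1, pm1)
            put(i, i + 1, pp1)
            put(i, i + 2, pp2)
            put(i, i, 1.0 - pm2 - pm1 - pp1 - pp2)
        FN = r * (N - 1) + 1
        put(N - 1, N - 3, 1.0 / FN)
        put(N - 1, N, 2.0 * r / FN)
        put(N - 1, N - 1, r * (N - 3) / FN)
    else:  # pragma: no cover - guarded by build_reduced_chain
        raise ValueError(family)

    P = sp.csr_matrix((vals, (rows, cols)), shape=(S, S))
    bandwidth = 1 if (family, model) == ("complete3", 2) else 2
    chain = ReducedChain(
        family=family,
        model=model,
        N=N,
        r=r,
        P=P,
        absorbing=(0, N),
        fixation_state=N,
        states=tuple(range(S)),
        bandwidth=bandwidth,
    )
    chain.validate()
    return chain


def _star_chain(model: int, N: int, r: float) -> ReducedChain:
    """2N-state chain for the star family, states (i1, i2).

    ``i1`` is 1 if the hub carries the mutant type, ``i2`` counts mutant
    leaves.  Transition rules follow from the model definition: the hub is
    incident to all C(N-1, 2) leaf-pair hyperedges, each leaf to the N-2
    hyperedges pairing it with another leaf.
    """
    L = N - 1
    CL2 = comb(L, 2)
    S = 2 * N

    def idx(i1: int, i2: int) -> int:
        return i1 * N + i2

    rows, cols, vals = [], [], []

    def put(s: int, t: int, p: float) -> None:
        if p != 0.0:
            rows.append(s)
            cols.append(t)
            vals.append(p)

    absorbing = (idx(0, 0), idx(1, L))
    for i1 in (0, 1):
        for i2 in range(N):
            s = idx(i1, i2)
            if s in absorbing:
                put(s, s, 1.0)
                continue
            i = i1 + i2
            F = r * i + (N - i)
            w_hub = (r if i1 else 1.0) / F
            w_A = r * i2 / F
            w_B = (L - i2) / F
            off = 0.0

            def move(t: int, p: float) -> None:
                nonlocal off
                if p > 0.0 and t != s:
                    put(s, t, p)
                    off += p

            # leaf-pair composition seen by the hub
            p_bb = comb(L - i2, 2) / CL2
            p_mix = i2 * (L - i2) / CL2
            p_aa = comb(i2, 2) / CL2
            if model == 1:
                if i1 == 1:
                    move(idx(1, i2 + 2), w_hub * p_bb)
                    move(idx(1, i2 + 1), w_hub * p_mix)
                else:
                    move(idx(0, i2 - 2), w_hub * p_aa)
                    move(idx(0, i2 - 1), w_hub * p_mix)
                if i2 > 0:
                    # mutant leaf parent: hyperedge {hub, parent, other leaf}
                    move(idx(1, i2), w_A * (i2 - 1) / (L - 1) if i1 == 0 else 0.0)
                    move(idx(1, i2 + 1), w_A * (L - i2) / (L - 1))
                if i2 < L:
                    move(idx(0, i2), w_B * (L - i2 - 1) / (L - 1) if i1 == 1 else 0.0)
                    move(idx(0, i2 - 1), w_B * i2 / (L - 1))
            else:
                # majority rule inside {hub, leaf, leaf}
                if i1 == 1:
                    move(idx(1, i2 + 1), w_hub * p_mix)
                else:
                    move(idx(0, i2 - 1), w_hub * p_mix)
                if i2 > 0:
                    if i1 == 1:
                        move(idx(1, i2 + 1), w_A * (L - i2) / (L - 1))
                    else:
                        move(idx(1, i2), w_A * (i2 - 1) / (L - 1))
                if i2 < L:
                    if i1 == 0:
                        move(idx(0, i2 - 1), w_B * i2 / (L - 1))
                    else:
                        move(idx(0, i2), w_B * (L - i2 - 1) / (L - 1))
            diag = 1.0 - off
            if -1e-12 < diag < 0.0:  # roundoff when the stay-probability is 0
                diag = 0.0
            put(s, s, diag)

    P = sp.csr_matrix((vals, (rows, cols)), shape=(S, S))
    P.sum_duplicates()
    states = tuple((i1, i2) for i1 in (0, 1) for i2 in range(N))
    chain = ReducedChain(
        family="star3",
        model=model,
        N=N,
        r=r,
        P=P,
        absorbing=absorbing,
        fixation_state=idx(1, L),
        states=states,
        bandwidth=None,
    )
    chain.validate()
    return chain


def build_reduced_chain(family: str, model: int, N: int, r: float) -> ReducedChain:
    """Build the reduced transition matrix for a symmetric family.

    Supported pairs: (complete3, 1), (complete3, 2), (cyclic3, 1),
    (star3, 1), (star3, 2).  The cyclic model-2 fixation probability is
    available in closed form only (`closed_form_fixation`).  The cyclic
    model-1 chain describes a contiguous arc of mutants, which covers the
    single-mutant initial condition.
    """
    if r <= 0:
        raise ValueError("relative fitness r must be positive")
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    if family in ("complete3", "cyclic3"):
        nmin = 3 if family == "complete3" else 4
        if N < nmin:
            raise ValueError(f"{family} requires N >= {nmin}")
        return _linear_chain(family, model, N, r)
    if family == "star3":
        if N < 4:
            raise ValueError("star3 requires N >= 4")
        return _star_chain(model, N, r)
    raise NotImplementedError(
        f"no reduced chain for family={family!r}, model={model}; supported: "
        "(complete3, 1|2), (cyclic3, 1), (star3, 1|2)"
    )


@dataclass(frozen=True)
class AbsorptionSystem:
    """Solved absorption system ``M x = b`` for a reduced chain."""

    chain: ReducedChain
    M: sp.csr_matrix
    b: np.ndarray
    x: np.ndarray
    residual: float


def _ptrans2_plain(d, a, b, c, e, y):
    """Solve a pentadiagonal system by PTRANS-II-style elimination.

    Diagonals by row index: ``d[i]=M[i,i]``, ``a[i]=M[i,i+1]``,
    ``b[i]=M[i,i+2]``, ``c[i]=M[i,i-1]``, ``e[i]=M[i,i-2]``.  A backward
    elimination sweep removes the subdiagonals, then forward substitution;
    no pivoting (the absorption matrices are diagonally dominant up to
    their identity rows).
    """
    n = len(y)
    psi = np.zeros(n)
    sigma = np.zeros(n)
    phi = np.zeros(n)
    w = np.zeros(n)
    psi[n - 1] = d[n - 1]
    sigma[n - 1] = c[n - 1] / psi[n - 1]
    phi[n - 1] = e[n - 1] / psi[n - 1]
    w[n - 1] = y[n - 1] / psi[n - 1]
    psi[n - 2] = d[n - 2] - a[n - 2] * sigma[n - 1]
    sigma[n - 2] = (c[n - 2] - a[n - 2] * phi[n - 1]) / psi[n - 2]
    phi[n - 2] = e[n - 2] / psi[n - 2]
    w[n - 2] = (y[n - 2] - a[n - 2] * w[n - 1]) / psi[n - 2]
    for i in range(n - 3, -1, -1):
        psi[i] = d[i] - b[i] * phi[i + 2] - sigma[i + 1] * (a[i] - b[i] * sigma[i + 2])
        if i >= 1:
            sigma[i] = (c[i] - phi[i + 1] * (a[i] - b[i] * sigma[i + 2])) / psi[i]
        if i >= 2:
            phi[i] = e[i] / psi[i]
        w[i] = (y[i] - b[i] * w[i + 2] - w[i + 1] * (a[i] - b[i] * sigma[i + 2])) / psi[i]
    x = np.zeros(n)
    x[0] = w[0]
    x[1] = w[1] - sigma[1] * x[0]
    for i in range(2, n):
        x[i] = w[i] - sigma[i] * x[i - 1] - phi[i] * x[i - 2]
    return x


def solve_absorption(chain: ReducedChain, method: str = "auto") -> AbsorptionSystem:
    """Solve for the fixation probability of every reduced state.

    ``method``: ``"auto"`` picks a banded LU for banded chains and sparse LU
    for the star chain; ``"banded"``, ``"ptrans2"``, ``"sparse"`` and
    ``"dense"`` force a particular path.  The solution must satisfy
    ``|M x - b|_inf < 1e-10`` and lie in [0, 1] up to 1e-12 slack.
    """
    chain.validate()
    S = chain.S
    M = sp.lil_matrix(chain.P - sp.identity(S, format="csr"))
    for astate in chain.absorbing:
        M.rows[astate] = [astate]
        M.data[astate] = [1.0]
    M = sp.csr_matrix(M)
    b = np.zeros(S)
    b[chain.fixation_state] = 1.0

    if method == "auto":
        method = "banded" if chain.bandwidth is not None else "sparse"
    if method in ("banded", "ptrans2"):
        if chain.bandwidth is None:
            raise ValueError("banded solve requested for a non-banded chain")
        lw = uw = chain.bandwidth
        ab = np.zeros((lw + uw + 1, S))
        Md = M.todia()
        for off, row in zip(Md.offsets, Md.data):
            if -lw <= off <= uw:
                ab[uw - off] = row
        if method == "banded" or lw == 1:
            x = solve_banded((lw, uw), ab, b)
        else:
            x = _ptrans2_plain(
                d=ab[2],
                a=np.r_[ab[1][1:], 0.0],
                b=np.r_[ab[0][2:], 0.0, 0.0],
                c=np.r_[0.0, ab[3][:-1]],
                e=np.r_[0.0, 0.0, ab[4][:-2]],
                y=b,
            )
    elif method == "sparse":
        x = spsolve(M.tocsc(), b)
    elif method == "dense":
        x = np.linalg.solve(M.toarray(), b)
    else:
        raise ValueError(f"unknown method {method!r}")

    residual = float(np.max(np.abs(M @ x - b)))
    if not np.isfinite(residual) or residual > _RESIDUAL_TOL:
        raise ArithmeticError(
            f"absorption solve residual {residual:.3e} exceeds {_RESIDUAL_TOL:.0e}; "
            "the system may be ill-conditioned"
        )
    if x.min() < -_CLIP_SLACK or x.max() > 1 + _CLIP_SLACK:
        raise ArithmeticError(
            f"absorption probabilities outside [0,1] beyond slack: "
            f"min={x.min():.3e}, max={x.max():.3e}"
        )
    x = np.clip(x, 0.0, 1.0)
    return AbsorptionSystem(chain=chain, M=M, b=b, x=x, residual=residual)


def star_uniform_mix(xtilde: np.ndarray, N: int, i: int) -> float:
    """Uniform-initialization mixture over star states with ``i`` mutants.

    Of the C(N, i) placements of i mutants, a fraction i/N put a mutant on
    the hub (state ``(1, i-1)``) and (N-i)/N do not (state ``(0, i)``).
    """
    if not 1 <= i <= N - 1:
        raise ValueError(f"i={i} outside [1, {N - 1}]")
    if len(xtilde) != 2 * N:
        raise ValueError("xtilde must have 2N entries ordered (0,0)..(0,N-1),(1,0)..(1,N-1)")
    x_hub = xtilde[N + (i - 1)]   # (1, i-1)
    x_leaf = xtilde[i]            # (0, i)
    return float(i / N * x_hub + (N - i) / N * x_leaf)


def family_fixation(
    family: str, model: int, N: int, r: float, i: int, method: str = "auto"
) -> float:
    """Exact uniform-initialization fixation probability on a symmetric family.

    Dispatches to the reduced chain (plus the star mixture), or to the
    closed form for cyclic model 2 where no reduced chain is exposed.
    """
    if i == 0:
        return 0.0
    if i == N:
        return 1.0
    if family == "complete_graph":
        return moran_fixation(N, r, i)
    if family == "cyclic3" and model == 2:
        from .closed_forms import closed_form_fixation

        return closed_form_fixation(family, model, N, r, i)
    if family == "cyclic3" and model == 1 and i > 1:
        raise NotImplementedError(
            "cyclic3 model-1 reduced chain covers uniform initialization only "
            "for i = 1 (mutant arcs); use brute force for i >= 2"
        )
    chain = build_reduced_chain(family, model, N, r)
    sol = solve_absorption(chain, method=method)
    if family == "star3":
        return star_uniform_mix(sol.x, N, i)
    return float(sol.x[i])
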