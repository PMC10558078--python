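"""Printed closed-form fixation probabilities for the symmetric families.

These are the exact rational functions of the relative fitness ``r`` for
small symmetric hypergraphs (and, for the complete family under the
majority-rule model, arbitrary ``N``).  They serve both as a fast path and
as the oracle against which the reduced-chain and brute-force solvers are
checked.

Coverage (family, model, N, i):
  model 1, i = 1: complete3 / cyclic3 / star3 at N in {4, 5}
  model 2, i = 2: complete3 any N >= 4 (also i in 3..N-2 via the
      telescoping product), cyclic3 any N >= 4, star3 at N in {4, 5}
Anything else raises ``NotImplementedError`` — use ``solve_absorption`` or
``brute_force_fixation`` instead.
"""

from __future__ import annotations

__all__ = ["closed_form_fixation"]


def _complete3_m1(N: int, r: float) -> float:
    if N == 4:
        return r**2 / (r**2 + 2 * r + 1)
    if N == 5:
        return (
            r**2 * (8 * r**2 + 12 * r + 1)
            / (8 * r**4 + 28 * r**3 + 33 * r**2 + 28 * r + 8)
        )
    raise NotImplementedError("complete3 model-1 closed form printed only for N in {4, 5}")


def _cyclic3_m1(N: int, r: float) -> float:
    if N == 4:
        # coincides with the complete 3-uniform hypergraph at N = 4
        return r**2 / (r**2 + 2 * r + 1)
    if N == 5:
        return (
            r**2 * (6 * r**2 + 8 * r + 1)
            / (6 * r**4 + 20 * r**3 + 23 * r**2 + 20 * r + 6)
        )
    raise NotImplementedError("cyclic3 model-1 closed form printed only for N in {4, 5}")


def _star3_m1(N: int, r: float) -> float:
    if N == 4:
        return r**2 * (3 * r + 5) / (4 * (3 * r**3 + 14 * r**2 + 18 * r + 9)) + (
            9 * r**2 / (4 * (3 * r**2 + 5 * r + 3))
        )
    if N == 5:
        return r**2 * (72 * r**3 + 202 * r**2 + 145 * r + 6) / (
            5 * (72 * r**5 + 490 * r**4 + 1025 * r**3 + 1070 * r**2 + 880 * r + 288)
        ) + 4 * r**2 * (72 * r**2 + 94 * r + 4) / (
            5 * (72 * r**4 + 202 * r**3 + 217 * r**2 + 202 * r + 72)
        )
    raise NotImplementedError("star3 model-1 closed form printed only for N in {4, 5}")


def _complete3_m2(N: int, r: float, i: int) -> float:
    """Majority-rule dynamics on the complete 3-uniform hypergraph.

    The mutant-count chain is a birth-death chain with backward/forward
    ratio ``gamma_k = (N-k-1) / (r (k-1))``; telescoping gives
    ``x_2 = (1 + 1/r)^(3-N)`` and partial sums give ``x_i`` for larger i.
    """
    if not 2 <= i <= N - 2:
        raise NotImplementedError("complete3 model-2 closed form covers i in 2..N-2")
    x2 = (1 + 1 / r) ** (3 - N)
    if i == 2:
        return x2
    # x_i = x2 * (1 + sum_{j=2}^{i-1} prod_{k=2}^{j} gamma_k), products built
    # incrementally for numerical stability
    total = 1.0
    prod = 1.0
    for j in range(2, i):
        prod *= (N - j - 1) / (r * (j - 1))
        total += prod
    return x2 * total


def _cyclic3_m2(N: int, r: float) -> float:
    """Two uniformly placed mutants on the cyclic 3-uniform hypergraph.

    Written in the form x_2 = (2/(N-1)) (2r+5) / ((r+4) S) with
    S = sum_{k=0}^{N-3} r^{-k}, which is algebraically identical to the
    geometric-ratio form and finite at r = 1, where it reduces to
    14 / (5 (N-1) (N-2)).
    """
    if N == 4:
        return r / (1 + r)
    S = sum(r**-k for k in range(N - 2))
    return (2 / (N - 1)) * (2 * r + 5) / ((r + 4) * S)


def _star3_m2(N: int, r: float) -> float:
    if N == 4:
        return 5 * r / (2 * (5 * r + 3)) + 3 * r / (2 * (3 * r + 5))
    if N == 5:
        return 6 * (r**3 + 3 * r**2) / (5 * (3 * r**3 + 13 * r**2 + 15 * r + 4)) + (
            3 * r**2 / (5 * (r**2 + 3 * r + 1))
        )
    raise NotImplementedError("star3 model-2 closed form printed only for N in {4, 5}")


def closed_form_fixation(family: str, model: int, N: int, r: float, i: int) -> float:
    """Evaluate a printed closed-form fixation probability.

    Raises ``NotImplementedError`` outside the coverage table in the module
    docstring; the caller should then fall back to the reduced-chain solver
    or the brute-force oracle.
    """
    if r <= 0:
        raise ValueError("relative fitness r must be positive")
    if model == 1:
        if i != 1:
            raise NotImplementedError("model-1 closed forms are printed for i = 1 only")
        if family == "complete3":
            return _complete3_m1(N, r)
        if family == "cyclic3":
            return _cyclic3_m1(N, r)
        if family == "star3":
            return _star3_m1(N, r)
    elif model == 2:
        if family == "complete3":
            return _complete3_m2(N, r, i)
        if family == "cyclic3":
            if i != 2:
                raise NotImplementedError("cyclic3 model-2 closed form covers i = 2 only")
            if N < 4:
                raise ValueError("cyclic3 requires N >= 4")
            return _cyclic3_m2(N, r)
        if family == "star3":
            if i != 2:
                raise NotImplementedError("star3 model-2 closed form covers i = 2 only")
            return _star3_m2(N, r)
    raise NotImplementedError(
        f"no closed form for family={family!r}, model={model}, N={N}, i={i}"
    )
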