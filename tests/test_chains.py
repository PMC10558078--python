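"""Reduced-chain construction, absorption solvers and the Moran baseline."""

import numpy as np
import pytest

from hyperfix import (
    build_reduced_chain,
    family_fixation,
    moran_fixation,
    solve_absorption,
    star_uniform_mix,
)

CHAIN_CASES = [
    ("complete3", 1), ("complete3", 2), ("cyclic3", 1), ("star3", 1), ("star3", 2),
]


class TestMoran:
    @pytest.mark.parametrize(
        "N,r,i,expected",
        [
            (5, 1.0, 2, 2 / 5),
            (4, 2.0, 1, 8 / 15),
            (7, 3.0, 7, 1.0),
            (7, 3.0, 0, 0.0),
        ],
    )
    def test_known_values(self, N, r, i, expected):
        assert moran_fixation(N, r, i) == pytest.approx(expected, abs=1e-14)

    def test_continuous_at_neutrality(self):
        # the expm1 form must not lose accuracy as r -> 1
        for eps in (1e-6, 1e-9, 1e-12):
            assert moran_fixation(10, 1 + eps, 3) == pytest.approx(0.3, abs=1e-5)
            assert moran_fixation(10, 1 - eps, 3) == pytest.approx(0.3, abs=1e-5)

    def test_invalid_fitness(self):
        with pytest.raises(ValueError):
            moran_fixation(5, -1.0, 1)


class TestChainStructure:
    @pytest.mark.parametrize("family,model", CHAIN_CASES)
    @pytest.mark.parametrize("N", [4, 5, 20, 200])
    @pytest.mark.parametrize("r", [0.1, 0.5, 1.0, 2.0, 10.0])
    def test_rows_sum_to_one(self, family, model, N, r):
        chain = build_reduced_chain(family, model, N, r)
        rows = np.asarray(chain.P.sum(axis=1)).ravel()
        assert np.max(np.abs(rows - 1.0)) < 1e-12
        assert chain.P.min() >= 0.0
        for a in chain.absorbing:
            row = chain.P.getrow(a)
            assert row.nnz == 1 and row[0, a] == 1.0

    def test_complete3_m1_jump_probability(self):
        # from a single mutant every mutant-parent event adds two converts
        chain = build_reduced_chain("complete3", 1, 4, 1.0)
        assert chain.P[1, 3] == pytest.approx(1 / 4, abs=1e-15)
        assert chain.P[1, 2] == 0.0

    def test_cyclic3_m1_single_mutant_extinction(self):
        chain = build_reduced_chain("cyclic3", 1, 5, 1.0)
        # p_{1,0} = 2/(r + N - 1): both ring neighbours of the lone mutant
        # can erase it through any of their covering hyperedges
        assert chain.P[1, 0] == pytest.approx(2 / 5, abs=1e-15)
        assert chain.P[1, 3] == pytest.approx(1 / 5, abs=1e-15)
        assert chain.P[1, 2] == 0.0

    def test_complete3_m2_single_mutant_cannot_grow(self):
        # majority rule: a lone mutant never recruits, so x_1 = 0
        N, r = 6, 2.0
        chain = build_reduced_chain("complete3", 2, N, r)
        assert chain.P[1, 2] == 0.0
        assert chain.P[1, 0] == pytest.approx(
            (N - 1) / (r + N - 1) * 2 * (N - 2) / ((N - 1) * (N - 2)), abs=1e-15
        )
        assert solve_absorption(chain).x[1] == 0.0

    def test_unsupported_pair_names_supported_set(self):
        with pytest.raises(NotImplementedError, match="closed_form"):
            build_reduced_chain("cyclic3", 2, 6, 1.0)
        with pytest.raises(NotImplementedError, match="supported"):
            build_reduced_chain("complete_graph", 1, 6, 1.0)


class TestAbsorption:
    def test_neutral_drift_complete3_n4(self):
        sol = solve_absorption(build_reduced_chain("complete3", 1, 4, 1.0))
        assert sol.x == pytest.approx([0, 1 / 4, 1 / 2, 3 / 4, 1], abs=1e-12)

    def test_matches_printed_rational_function(self):
        for r in (0.3, 1.7, 5.0):
            sol = solve_absorption(build_reduced_chain("complete3", 1, 4, r))
            assert sol.x[1] == pytest.approx(r**2 / (r**2 + 2 * r + 1), abs=1e-12)

    @pytest.mark.parametrize("family,model", CHAIN_CASES)
    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_banded_sparse_dense_agree(self, family, model, r):
        chain = build_reduced_chain(family, model, 200, r)
        x_dense = solve_absorption(chain, method="dense").x
        methods = ["sparse"] if chain.bandwidth is None else ["banded", "sparse"]
        if chain.bandwidth == 2:
            methods.append("ptrans2")
        for m in methods:
            assert np.max(np.abs(solve_absorption(chain, method=m).x - x_dense)) < 1e-10

    def test_residual_is_checked(self):
        sol = solve_absorption(build_reduced_chain("star3", 2, 30, 1.3))
        assert sol.residual < 1e-10
        assert sol.x.min() >= 0.0 and sol.x.max() <= 1.0


class TestStarMix:
    def test_constant_vector_is_fixed_point(self):
        xt = np.full(2 * 6, 0.37)
        assert star_uniform_mix(xt, 6, 3) == pytest.approx(0.37)

    def test_neutral_drift_through_mixture(self):
        sol = solve_absorption(build_reduced_chain("star3", 1, 4, 1.0))
        assert star_uniform_mix(sol.x, 4, 1) == pytest.approx(1 / 4, abs=1e-12)

    def test_index_bounds(self):
        with pytest.raises(ValueError):
            star_uniform_mix(np.zeros(8), 4, 4)


class TestFamilyFixation:
    def test_cyclic_m1_uniform_init_limited_to_single_mutant(self):
        with pytest.raises(NotImplementedError, match="i = 1"):
            family_fixation("cyclic3", 1, 8, 2.0, 3)

    def test_monotone_in_fitness_model1(self, r_grid):
        for family in ("complete3", "cyclic3", "star3"):
            x = [family_fixation(family, 1, 8, r, 1) for r in r_grid]
            assert all(b - a > -1e-9 for a, b in zip(x, x[1:]))
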