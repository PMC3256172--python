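import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirnapair import (
    DiscretizedProfile,
    NullCellProbs,
    PermutationConfig,
    TargetPair,
    build_contingency,
    chisq_pvalue,
    exact_multinomial_pvalue,
    null_cell_probs,
    ud_test_pair,
)
from scipy.stats import chi2


def nested_loop_counts(a, b):
    """Independent brute-force counting oracle."""
    counts = np.zeros((3, 3), dtype=int)
    for r in (-1, 0, 1):
        for c in (-1, 0, 1):
            n = 0
            for x, y in zip(a, b):
                if x == r and y == c:
                    n += 1
            counts[r + 1, c + 1] = n
    return counts


def enumeration_pvalue(obs_counts, probs):
    """Independent exact-test oracle: enumerate every ordered assignment of
    the C conditions to the 9 cells and aggregate probabilities by table."""
    C = int(np.sum(obs_counts))
    probs = np.asarray(probs, dtype=float).ravel()
    pmf: dict[tuple, float] = {}
    for assign in itertools.product(range(9), repeat=C):
        table = [0] * 9
        pr = 1.0
        for cell in assign:
            table[cell] += 1
            pr *= probs[cell]
        key = tuple(table)
        pmf[key] = pmf.get(key, 0.0) + pr
    obs_key = tuple(int(v) for v in np.asarray(obs_counts).ravel())
    p_obs = pmf.get(obs_key, 0.0)
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


def profile(values, prefix="g"):
    values = np.asarray(values)
    return DiscretizedProfile(
        feature_ids=[f"{prefix}{i}" for i in range(values.shape[0])],
        conditions=[f"c{j}" for j in range(values.shape[1])],
        values=values,
    )


class TestBuildContingency:
    def test_all_zero_vectors(self):
        t = build_contingency([0, 0, 0, 0], [0, 0, 0, 0])
        assert t.counts[1, 1] == 4 and t.counts.sum() == 4

    def test_anti_diagonal_example(self):
        t = build_contingency([-1, 0, 1], [1, 0, -1])
        assert t.counts[0, 2] == 1 and t.counts[1, 1] == 1 and t.counts[2, 0] == 1
        assert t.counts.sum() == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_contingency([0, 1], [0])

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError, match="miRNA"):
            build_contingency([2, 0], [0, 0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.sampled_from([-1, 0, 1]), st.sampled_from([-1, 0, 1])),
            min_size=1,
            max_size=15,
        )
    )
    def test_matches_nested_loop_oracle(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        np.testing.assert_array_equal(
            build_contingency(a, b).counts, nested_loop_counts(a, b)
        )


class TestNullCellProbs:
    def test_all_zero_pool_concentrates_in_middle_column(self):
        mirna = np.array([1, 1, 0, -1])
        prof = profile(np.zeros((10, 4), int))
        probs = null_cell_probs(mirna, prof, PermutationConfig(n_rep=500, seed=1)).probs
        # only the mRNA-value-0 column can be populated; row masses are the
        # empirical frequencies of the miRNA values
        assert probs[:, 0].sum() == 0 and probs[:, 2].sum() == 0
        np.testing.assert_allclose(probs[:, 1], [0.25, 0.25, 0.5])

    def test_all_zero_mirna_empties_outer_rows(self):
        mirna = np.zeros(5, dtype=int)
        prof = profile(np.array([[1, -1, 0, 0, 1], [0, 0, 1, -1, 0]]))
        probs = null_cell_probs(mirna, prof, PermutationConfig(n_rep=500, seed=2)).probs
        assert probs[0].sum() == 0 and probs[2].sum() == 0 and probs[1].sum() == 1

    def test_product_form_limit(self):
        # pool 50% zeros, 25% each sign; miRNA (1,1,0,0): expected cell
        # probability = row frequency x pool frequency
        z, c = 400, 4
        n_each = z * c // 4
        pool = np.array([0] * (2 * n_each) + [1] * n_each + [-1] * n_each).reshape(z, c)
        prof = profile(pool)
        mirna = np.array([1, 1, 0, 0])
        n_rep = 100_000
        probs = null_cell_probs(mirna, prof, PermutationConfig(n_rep=n_rep, seed=3)).probs
        row_freq = np.array([0.0, 0.5, 0.5])
        pool_freq = np.array([0.25, 0.5, 0.25])
        expected = row_freq[:, None] * pool_freq[None, :]
        # dominant error: column composition of the stage-1 redraw (Z draws
        # per column, averaged over the 2 columns of each row value)
        se = np.sqrt(pool_freq * (1 - pool_freq) / z) * np.sqrt(2) / c
        tol = 3 * np.maximum(se, 1.5 / np.sqrt(n_rep))
        assert np.all(np.abs(probs - expected) <= tol + 1e-12)

    def test_reproducible_for_fixed_seed(self, rng):
        prof = profile(rng.choice([-1, 0, 1], size=(20, 6)))
        mirna = rng.choice([-1, 0, 1], size=6)
        cfg = PermutationConfig(n_rep=1000, seed=77)
        p1 = null_cell_probs(mirna, prof, cfg).probs
        p2 = null_cell_probs(mirna, prof, cfg).probs
        np.testing.assert_array_equal(p1, p2)

    def test_unit_sum(self, rng):
        prof = profile(rng.choice([-1, 0, 1], size=(30, 9)))
        mirna = rng.choice([-1, 0, 1], size=9)
        probs = null_cell_probs(mirna, prof, PermutationConfig(n_rep=2000, seed=5))
        assert abs(probs.probs.sum() - 1.0) < 1e-12


class TestExactMultinomial:
    def test_degenerate_single_cell(self):
        p = np.zeros((3, 3))
        p[0, 0] = 1.0
        probs = NullCellProbs(p)
        t = build_contingency([-1, -1, -1], [-1, -1, -1])
        assert exact_multinomial_pvalue(t, probs) == pytest.approx(1.0)

    def test_c_equals_one_closed_form(self):
        p = np.array([[0.5, 0.2, 0.1], [0.05, 0.05, 0.04], [0.03, 0.02, 0.01]])
        probs = NullCellProbs(p / p.sum())
        t = build_contingency([0], [-1])  # falls in cell (0, -1) with prob 0.05
        expected = probs.probs[probs.probs <= probs.probs[1, 0] * (1 + 1e-9)].sum()
        assert exact_multinomial_pvalue(t, probs) == pytest.approx(expected, abs=1e-12)

    def test_occupied_zero_probability_cell_gives_zero(self, caplog):
        p = np.zeros((3, 3))
        p[1, 1] = 1.0
        probs = NullCellProbs(p)
        t = build_contingency([1, 0], [0, 0])
        with caplog.at_level("WARNING"):
            assert exact_multinomial_pvalue(t, probs) == 0.0

    @pytest.mark.parametrize("case", range(5))
    def test_uniform_c3_matches_enumeration(self, case, rng):
        probs = NullCellProbs(np.full((3, 3), 1 / 9))
        a = rng.choice([-1, 0, 1], size=3)
        b = rng.choice([-1, 0, 1], size=3)
        t = build_contingency(a, b)
        expected = enumeration_pvalue(t.counts, probs.probs)
        assert exact_multinomial_pvalue(t, probs) == pytest.approx(expected, abs=1e-12)

    def test_monte_carlo_fallback_close_to_exact(self, rng):
        p = rng.dirichlet(np.ones(9)).reshape(3, 3)
        probs = NullCellProbs(p)
        a = rng.choice([-1, 0, 1], size=6)
        b = rng.choice([-1, 0, 1], size=6)
        t = build_contingency(a, b)
        exact = exact_multinomial_pvalue(t, probs)
        mc = exact_multinomial_pvalue(
            t, probs, rng=np.random.default_rng(0), max_enumeration=10, n_mc=100_000
        )
        assert abs(mc - exact) < 4 * np.sqrt(exact * (1 - exact) / 100_000) + 1e-4


class TestChisq:
    def test_perfect_fit_gives_p_one(self):
        p = np.full((3, 3), 1 / 9)
        probs = NullCellProbs(p)
        t = build_contingency(
            np.repeat([-1, 0, 1], 3), np.tile([-1, 0, 1], 3)
        )  # one count per cell, C = 9, expected = 1 everywhere
        assert chisq_pvalue(t, probs) == pytest.approx(1.0)

    def test_matches_reference_upper_tail(self):
        counts = np.array([[20, 5, 10], [9, 11, 12], [8, 13, 12]])
        mirna_vec = np.repeat([-1, 0, 1], counts.sum(axis=1))
        mrna_vec = np.concatenate([np.repeat([-1, 0, 1], row) for row in counts])
        t_obj = build_contingency(mirna_vec, mrna_vec)
        probs = NullCellProbs(np.full((3, 3), 1 / 9))
        C = counts.sum()
        stat = ((counts - C / 9) ** 2 / (C / 9)).sum()
        assert chisq_pvalue(t_obj, probs) == pytest.approx(chi2.sf(stat, 8), rel=1e-12)

    def test_zero_probability_empty_cell_excluded(self):
        p = np.full((3, 3), 1 / 8)
        p[0, 0] = 0.0
        probs = NullCellProbs(p)
        t = build_contingency([0, 0, 1, 1], [0, 1, 0, 1])
        assert 0 <= chisq_pvalue(t, probs) <= 1  # no division by zero


class TestUdTestPair:
    def test_all_zero_pair_flagged_not_testable(self):
        mi = profile(np.zeros((1, 4), int), prefix="m")
        mr = profile(np.zeros((1, 4), int))
        r = ud_test_pair(
            TargetPair("m0", "g0"), mi, mr, PermutationConfig(n_rep=100, seed=1)
        )
        assert r.status == "not_testable" and r.p_raw == 1.0

    def test_planted_opposite_pair_is_significant(self, rng):
        # background pool mostly zeros; the pair is opposite in 6 of 8 groups
        C = 8
        mr_vals = rng.choice([-1, 0, 1], size=(100, C), p=[0.05, 0.9, 0.05])
        mi_vec = np.array([1, 1, 1, -1, -1, 1, 0, 0])
        mr_vec = np.array([-1, -1, -1, 1, 1, -1, 0, 0])
        mr_vals[0] = mr_vec
        mi = DiscretizedProfile(["mirX"], [f"c{j}" for j in range(C)], mi_vec[None, :])
        mr = profile(mr_vals)
        r = ud_test_pair(
            TargetPair("mirX", "g0"), mi, mr, PermutationConfig(n_rep=10000, seed=9)
        )
        assert r.p_raw < 0.05
        assert len(r.direction_conditions) == 6

    def test_large_c_uses_chisq_branch(self, rng):
        C = 20
        mi_vec = rng.choice([-1, 0, 1], size=C)
        mr_vals = rng.choice([-1, 0, 1], size=(50, C), p=[0.1, 0.8, 0.1])
        mi = DiscretizedProfile(["mirX"], [f"c{j}" for j in range(C)], mi_vec[None, :])
        mr = profile(mr_vals)
        cfg = PermutationConfig(n_rep=2000, seed=4)
        r = ud_test_pair(TargetPair("mirX", "g0"), mi, mr, cfg)
        # recompute through the chi-square path with the identical null
        probs = null_cell_probs(mi_vec, mr, cfg, rng=cfg.rng())
        expected = chisq_pvalue(build_contingency(mi_vec, mr_vals[0]), probs)
        assert r.p_raw == pytest.approx(expected, abs=1e-12)

    def test_unknown_id_is_named(self):
        mi = profile(np.zeros((1, 3), int), prefix="m")
        mr = profile(np.zeros((1, 3), int))
        with pytest.raises(KeyError, match="nope"):
            ud_test_pair(TargetPair("nope", "g0"), mi, mr, PermutationConfig(10, 0))

    def test_joint_condition_permutation_leaves_p_unchanged(self, rng):
        # the table, and hence p against fixed null probabilities, is
        # invariant to a joint permutation of the condition order
        C = 7
        mi_vec = rng.choice([-1, 0, 1], size=C)
        mr_vec = rng.choice([-1, 0, 1], size=C)
        perm = rng.permutation(C)
        probs = NullCellProbs(rng.dirichlet(np.ones(9)).reshape(3, 3))
        p1 = exact_multinomial_pvalue(build_contingency(mi_vec, mr_vec), probs)
        p2 = exact_multinomial_pvalue(
            build_contingency(mi_vec[perm], mr_vec[perm]), probs
        )
        assert p1 == p2

    def test_null_pvalues_conservative(self, rng):
        # independent pairs drawn from the pool: p-value distribution must be
        # stochastically >= uniform
        C = 9
        pool = rng.choice([-1, 0, 1], size=(150, C), p=[0.1, 0.8, 0.1])
        mr = profile(pool)
        cfg = PermutationConfig(n_rep=1000, seed=21)
        mi_vec = rng.choice([-1, 0, 1], size=C, p=[0.2, 0.6, 0.2])
        mi = DiscretizedProfile(["mirX"], [f"c{j}" for j in range(C)], mi_vec[None, :])
        probs = null_cell_probs(mi_vec, mr, cfg)
        ps = []
        for _ in range(300):
            b = pool[rng.integers(0, 150)]
            t = build_contingency(mi_vec, b)
            ps.append(exact_multinomial_pvalue(t, probs))
        assert np.mean(np.asarray(ps) <= 0.05) <= 0.08
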