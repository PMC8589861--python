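"""Permutation tests, dosage correlation and the selection rule."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from scnadriver import association


def enumeration_oracle(a, b):
    """Exact two-sided permutation p for Welch's t by full enumeration."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)

    def welch(x, y):
        denom = np.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
        return (x.mean() - y.mean()) / denom if denom > 0 else 0.0

    t_obs = welch(np.asarray(a, float), np.asarray(b, float))
    count = total = 0
    for idx in combinations(range(n), na):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        if abs(welch(pooled[mask], pooled[~mask])) >= abs(t_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestPermutationTTest:
    def test_identical_groups_give_p_one(self):
        t, p = association.permutation_t_test([1.0, 1.0, 1.0], [1.0, 1.0], B=99)
        assert (t, p) == (0.0, 1.0)

    def test_exhaustive_enumeration_separated_groups(self):
        # 20 label arrangements; only the observed split and its mirror are as extreme
        t, p = association.permutation_t_test([1, 2, 3], [101, 102, 103], B=9999)
        assert p == pytest.approx(2 / 20)
        assert p == pytest.approx(enumeration_oracle([1, 2, 3], [101, 102, 103]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-5, 5), min_size=2, max_size=4),
           st.lists(st.integers(-5, 5), min_size=2, max_size=4))
    def test_exhaustive_matches_oracle(self, a, b):
        if np.ptp(a + b) == 0:
            return
        _, p = association.permutation_t_test(a, b, B=10_000)
        assert p == pytest.approx(enumeration_oracle(a, b))

    def test_symmetry_in_group_exchange(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=6)
        _, p_ab = association.permutation_t_test(a, b, B=10_000)
        _, p_ba = association.permutation_t_test(b, a, B=10_000)
        assert p_ab == p_ba

    def test_monte_carlo_p_respects_add_one_bound(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(10.0, 1.0, size=30)  # far more than B arrangements: MC path
        _, p = association.permutation_t_test(a, b, B=199, rng=rng)
        assert p >= 1 / 200
        assert p == pytest.approx(1 / 200)

    def test_tiny_group_is_error(self):
        with pytest.raises(ValueError):
            association.permutation_t_test([1.0], [2.0, 3.0])


class TestPermutationScreen:
    def test_matrix_screen_agrees_with_scalar_test_in_distribution(self, rng):
        # same shared-plan machinery, one gene: p within MC error of scalar MC test
        a = rng.normal(0, 1, size=(1, 25))
        b = rng.normal(1.2, 1, size=(1, 25))
        t, p = association.permutation_t_screen(a, b, B=1999, rng=np.random.default_rng(1))
        t_ref = stats.ttest_ind(a[0], b[0], equal_var=False).statistic
        assert t[0] == pytest.approx(t_ref)
        assert p[0] < 0.01

    def test_null_type_one_error_calibrated(self, rng):
        x = rng.normal(size=(500, 60))
        _, p = association.permutation_t_screen(x[:, :30], x[:, 30:], B=999,
                                                rng=np.random.default_rng(5))
        rate = float((p < 0.05).mean())
        assert 0.02 < rate < 0.09

    def test_constant_rows_get_p_one(self):
        x = np.ones((3, 10))
        t, p = association.permutation_t_screen(x[:, :5], x[:, 5:], B=99,
                                                rng=np.random.default_rng(0))
        assert (t == 0).all() and (p == 1.0).all()


class TestGeneWiseCorrelation:
    def _frames(self, x, y):
        de = pd.DataFrame([x], index=["g"], columns=[f"s{i}" for i in range(len(x))])
        scna = pd.DataFrame([y], index=["g"], columns=de.columns)
        return de, scna

    @pytest.mark.parametrize("y_of_x,expected", [
        (lambda x: x, 1.0),
        (lambda x: -x, -1.0),
    ])
    def test_perfect_correlation(self, y_of_x, expected):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        de, scna = self._frames(x, y_of_x(x))
        out = association.gene_wise_correlation(de, scna)
        assert out.loc["g", "cor_r"] == pytest.approx(expected)

    def test_hand_computed_example(self):
        de, scna = self._frames([1, 2, 3, 4], [2, 1, 4, 3])
        out = association.gene_wise_correlation(de, scna)
        assert out.loc["g", "cor_r"] == pytest.approx(0.6)
        r, p = stats.pearsonr([1, 2, 3, 4], [2, 1, 4, 3])
        assert out.loc["g", "cor_p"] == pytest.approx(p)

    def test_too_few_pairs_reported_missing(self):
        de, scna = self._frames([1.0, 2.0, np.nan, np.nan], [1.0, 2.0, 3.0, 4.0])
        out = association.gene_wise_correlation(de, scna)
        assert np.isnan(out.loc["g", "cor_r"])
        assert out.loc["g", "n_pairs"] == 2

    def test_zero_variance_missing(self):
        de, scna = self._frames([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        out = association.gene_wise_correlation(de, scna)
        assert np.isnan(out.loc["g", "cor_r"])


class TestSelectionRule:
    def _records(self, **kw):
        base = dict(de_fc=0.5, perm_p=0.001, scna_fc=0.2, cor_r=0.7, cor_p=1e-5)
        base.update(kw)
        return pd.DataFrame(base, index=["g"])

    def test_concordant_upregulated_gene_selected(self):
        out = association.select_scna_dependent_genes(self._records())
        assert bool(out.loc["g", "selected"]) and out.loc["g", "direction"] == 1

    @pytest.mark.parametrize("kw", [
        {"cor_r": 0.4},                      # correlation below the gate
        {"scna_fc": -0.1},                   # discordant DE and SCNA signs
        {"de_fc": 0.2},                      # fold change inside the band
        {"perm_p": 0.01},                    # DE not significant
        {"cor_p": 0.5},                      # correlation not significant
        {"de_fc": -0.5},                     # down gene must have SCNA loss
    ])
    def test_each_gate_can_reject(self, kw):
        out = association.select_scna_dependent_genes(self._records(**kw))
        assert not bool(out.loc["g", "selected"])

    def test_downregulated_concordant_gene_selected_down(self):
        out = association.select_scna_dependent_genes(
            self._records(de_fc=-0.5, scna_fc=-0.2))
        assert bool(out.loc["g", "selected"]) and out.loc["g", "direction"] == -1


class TestGroupDifferentialExpression:
    def test_identical_groups_flag_nothing(self, rng):
        de = pd.DataFrame(np.tile(rng.normal(size=(20, 1)), (1, 8)),
                          index=[f"g{i}" for i in range(20)],
                          columns=[f"s{i}" for i in range(8)])
        out = association.group_differential_expression(
            de, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
            B=99, rng=rng)
        assert (out["direction"] == "").all()

    def test_planted_shift_recovered(self, rng):
        n_genes, n = 300, 40
        de = pd.DataFrame(rng.normal(0, 0.3, size=(n_genes, 2 * n)),
                          index=[f"g{i}" for i in range(n_genes)],
                          columns=[f"s{i}" for i in range(2 * n)])
        low = [f"s{i}" for i in range(n)]
        high = [f"s{i}" for i in range(n, 2 * n)]
        planted = [f"g{i}" for i in range(30)]
        de.loc[planted, low] += 1.0
        out = association.group_differential_expression(de, high, low, B=4999,
                                                        p_thresh=0.001, fd_thresh=0.5,
                                                        rng=rng, top_k=10)
        assert (out.loc[planted, "direction"] == "up").mean() >= 0.95
        nulls = out.drop(index=planted)
        assert (nulls["direction"] != "").mean() <= 0.01
        assert out["rank"].notna().sum() == 10

    def test_infinite_threshold_flags_nothing(self, rng):
        de = pd.DataFrame(rng.normal(size=(10, 8)), columns=[f"s{i}" for i in range(8)])
        out = association.group_differential_expression(
            de, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
            B=99, fd_thresh=np.inf, rng=rng)
        assert (out["direction"] == "").all()

    def test_overlapping_groups_rejected(self, rng):
        de = pd.DataFrame(rng.normal(size=(5, 6)), columns=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError, match="overlap"):
            association.group_differential_expression(de, ["s0", "s1"], ["s1", "s2"], B=9)
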