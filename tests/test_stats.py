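"""Pathway statistics: FDR, group tests, variability, deviation, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pasqc.expression import ExpressionMatrix
from pasqc.pas import PASMatrix
from pasqc.stats import (
    StatsError,
    bh_fdr,
    cluster_pas,
    deviation_correlation,
    pathway_group_test,
    permutation_group_test,
    shared_top,
    significant_pathways,
    variability_rank,
)

from conftest import random_db


def _pas(values, pathways=None, lines=None):
    values = np.asarray(values, dtype=float)
    pathways = pathways or [f"P{i}" for i in range(values.shape[0])]
    lines = lines or [f"L{j}" for j in range(values.shape[1])]
    return PASMatrix(pd.DataFrame(values, index=pathways, columns=lines))


class TestBhFdr:
    def test_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_hand_example_non_monotone_raw(self):
        # q_(i) = min_{j>=i} m p_(j)/j
        q = bh_fdr([0.005, 0.009, 0.05, 0.5])
        assert np.allclose(q, [0.018, 0.018, 0.2 / 3, 0.5])

    def test_preserves_input_order(self):
        p = np.array([0.5, 0.001, 0.03])
        q = bh_fdr(p)
        assert q[1] == q.min()
        assert q[0] == q.max()

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 40))
    def test_matches_statsmodels(self, seed, n):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, n)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), expected, rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(StatsError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(StatsError):
            bh_fdr([0.5, np.nan])

    def test_empty_is_empty(self):
        assert bh_fdr([]).size == 0


class TestPathwayGroupTest:
    def test_matches_scipy_ttest(self):
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        pas = _pas(rng.normal(0.2, 0.3, size=(5, 6)))
        out = pathway_group_test(pas, list(pas.lines))
        expected = sps.ttest_1samp(pas.data, 0.0, axis=1).pvalue
        assert np.allclose(out["p_value"], expected)
        assert np.allclose(out["q_value"], bh_fdr(expected))
        assert out.attrs["n"] == 6

    def test_degenerate_rows(self):
        pas = _pas([[0.0, 0.0, 0.0], [0.5, 0.5, 0.5]])
        out = pathway_group_test(pas, ["L0", "L1", "L2"])
        assert out.loc["P0", "p_value"] == 1.0
        assert out.loc["P1", "p_value"] < 1e-300

    def test_requires_three_lines(self):
        pas = _pas(np.zeros((2, 2)))
        with pytest.raises(StatsError, match=">= 3"):
            pathway_group_test(pas, ["L0", "L1"])

    def test_significant_pathways_filter(self):
        out = pd.DataFrame(
            {"p_value": [0.001, 0.2], "q_value": [0.01, 0.3]},
            index=["A", "B"],
        )
        assert significant_pathways(out, q_max=0.05) == ["A"]
        assert significant_pathways(out, q_max=0.5, p_max=0.1) == ["A"]


class TestPermutationGroupTest:
    def _study(self, seed, shift):
        """4 control + 4 case lines; P0 genes shifted in cases by `shift`."""
        rng = np.random.default_rng(seed)
        db = random_db(rng, n_pathways=4, max_genes=6)
        genes = sorted(db.all_genes())
        logs = rng.normal(2.0, 0.05, size=(len(genes), 8))
        p0_genes = set(db[db.names[0]].genes)
        arr = {m.gene: m.arr for m in db[db.names[0]].members}
        for gi, g in enumerate(genes):
            if g in p0_genes:
                logs[gi, 4:] += shift * arr[g]
        data = pd.DataFrame(
            np.power(10.0, logs),
            index=genes,
            columns=[f"C{i}" for i in range(4)] + [f"X{i}" for i in range(4)],
        )
        return ExpressionMatrix(data), db

    def test_detects_planted_shift(self):
        m, db = self._study(seed=5, shift=0.5)
        out = permutation_group_test(
            m, db, [f"X{i}" for i in range(4)], [f"C{i}" for i in range(4)],
            n_permutations=200, seed=1,
        )
        assert out.loc[db.names[0], "p_value"] <= 0.05
        # p-values bounded below by 1/(n+1)
        assert (out["p_value"] >= 1 / 201).all()

    def test_null_pathways_not_small(self):
        m, db = self._study(seed=5, shift=0.0)
        out = permutation_group_test(
            m, db, [f"X{i}" for i in range(4)], [f"C{i}" for i in range(4)],
            n_permutations=200, seed=1,
        )
        assert (out["p_value"] > 0.05).sum() >= 3

    def test_deterministic_under_seed(self):
        m, db = self._study(seed=7, shift=0.3)
        kwargs = dict(
            group_lines=[f"X{i}" for i in range(4)],
            control_lines=[f"C{i}" for i in range(4)],
            n_permutations=50,
            seed=3,
        )
        a = permutation_group_test(m, db, **kwargs)
        b = permutation_group_test(m, db, **kwargs)
        assert a.equals(b)

    def test_overlapping_groups_rejected(self):
        m, db = self._study(seed=5, shift=0.0)
        with pytest.raises(StatsError, match="disjoint"):
            permutation_group_test(m, db, ["C0", "X0", "X1"], ["C0", "C1"])


class TestVariability:
    def test_rank_is_permutation_and_sd_ordered(self):
        rng = np.random.default_rng(1)
        pas = _pas(rng.normal(size=(6, 5)) * np.arange(1, 7)[:, None])
        out = variability_rank(pas, list(pas.lines))
        assert sorted(out["rank"]) == list(range(1, 7))
        ordered = out.sort_values("rank")
        assert (ordered["sd"].diff().dropna() <= 0).all()

    def test_ties_broken_by_name(self):
        pas = _pas(
            [[1.0, -1.0], [1.0, -1.0]], pathways=["B", "A"], lines=["L0", "L1"]
        )
        out = variability_rank(pas, ["L0", "L1"])
        assert out.loc["A", "rank"] == 1
        assert out.loc["B", "rank"] == 2

    def test_shared_top_most_and_least(self):
        a = pd.DataFrame({"sd": [3.0, 2.0, 1.0], "rank": [1, 2, 3]},
                         index=["P0", "P1", "P2"])
        b = pd.DataFrame({"sd": [1.0, 3.0, 2.0], "rank": [3, 1, 2]},
                         index=["P0", "P1", "P2"])
        n, common = shared_top(a, b, k=2, end="most")
        assert (n, common) == (1, ["P1"])
        n, common = shared_top(a, b, k=2, end="least")
        assert (n, common) == (1, ["P2"])

    def test_shared_top_k_bounds(self):
        a = pd.DataFrame({"sd": [1.0], "rank": [1]}, index=["P0"])
        with pytest.raises(StatsError):
            shared_top(a, a, k=2)


class TestDeviationCorrelation:
    def test_identical_dispersion_gives_one(self):
        rng = np.random.default_rng(2)
        sd = np.array([1.0, 2.0, 3.0, 4.0])
        a = _pas(rng.normal(0, 1, size=(4, 50)) * sd[:, None])
        b = _pas(rng.normal(0, 1, size=(4, 50)) * sd[:, None])
        r2 = deviation_correlation(a, b)
        assert r2 > 0.95

    def test_exact_when_dispersion_vectors_proportional(self):
        a = _pas([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]])
        b = _pas([[2.0, -2.0], [4.0, -4.0], [6.0, -6.0]])
        assert np.isclose(deviation_correlation(a, b), 1.0)

    def test_constant_dispersion_rejected(self):
        a = _pas([[1.0, -1.0], [1.0, -1.0], [1.0, -1.0]])
        b = _pas([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]])
        with pytest.raises(StatsError, match="zero variance"):
            deviation_correlation(a, b)

    def test_mismatched_universes_rejected(self):
        a = _pas(np.ones((3, 2)) * [[1], [2], [3]], pathways=["A", "B", "C"])
        b = _pas(np.ones((3, 2)) * [[1], [2], [3]], pathways=["A", "B", "D"])
        with pytest.raises(StatsError, match="universe"):
            deviation_correlation(a, b)


class TestCluster:
    def test_orders_are_permutations(self):
        rng = np.random.default_rng(3)
        pas = _pas(rng.normal(size=(8, 6)))
        res = cluster_pas(pas)
        assert sorted(res.pathway_order) == sorted(pas.pathways)
        assert sorted(res.line_order) == sorted(pas.lines)

    def test_identical_lines_adjacent(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=8)
        data = np.column_stack(
            [base, base + rng.normal(0, 1e-6, 8), rng.normal(5, 1, 8),
             rng.normal(-5, 1, 8)]
        )
        res = cluster_pas(_pas(data))
        order = list(res.line_order)
        assert abs(order.index("L0") - order.index("L1")) == 1

    def test_top_n_restricts_to_most_variable(self):
        rng = np.random.default_rng(5)
        pas = _pas(rng.normal(size=(6, 5)) * np.arange(1, 7)[:, None])
        res = cluster_pas(pas, top_n=2)
        ranking = variability_rank(pas, list(pas.lines))
        expected = set(ranking.index[ranking["rank"] <= 2])
        assert set(res.pathways) == expected

    def test_top_n_too_large_rejected(self):
        pas = _pas(np.eye(3))
        with pytest.raises(StatsError):
            cluster_pas(pas, top_n=4)
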