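"""Fisher-exact differential prevalence, BH-FDR and permutation exclusivity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcrep.cluster import ClusterMatrix
from tcrep.da import (
    ContingencyTable,
    ExclusivityResult,
    bh_fdr,
    differential_abundance,
    exclusivity,
    fisher_exact,
    permutation_exclusivity_test,
    prevalence_tables,
    select_candidates,
)


class TestFisherExact:
    def test_diagonal_three_table(self):
        assert fisher_exact(ContingencyTable(3, 0, 0, 3)) == pytest.approx(0.1, abs=1e-12)

    def test_modal_table_is_one(self):
        assert fisher_exact(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0, abs=1e-12)

    def test_zero_margin_is_one(self):
        assert fisher_exact(ContingencyTable(0, 5, 0, 5)) == 1.0
        assert fisher_exact(ContingencyTable(0, 0, 3, 4)) == 1.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 25, 4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            mine = fisher_exact(ContingencyTable(int(a), int(b), int(c), int(d)))
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_invariant_to_group_relabeling(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, 4))
            assert fisher_exact(ContingencyTable(a, b, c, d)) == pytest.approx(
                fisher_exact(ContingencyTable(d, c, b, a)), abs=1e-12
            )


class TestPrevalenceTables:
    def _matrix(self):
        rng = np.random.default_rng(2)
        idx = [f"d{i}" for i in range(50)] + [f"h{i}" for i in range(50)]
        ab = pd.DataFrame(0.0, index=pd.Index(idx, name="sample_id"), columns=[0, 1, 2])
        ab.loc[[f"d{i}" for i in range(10)], 0] = 0.01
        ab.loc[[f"h{i}" for i in range(2)], 0] = 0.01
        ab[1] = 0.005  # present everywhere
        labels = pd.Series(
            ["diseased"] * 50 + ["healthy"] * 50, index=idx, dtype="object"
        )
        return ClusterMatrix(abundance=ab), labels

    def test_example_counts(self):
        m, labels = self._matrix()
        tables = prevalence_tables(m, labels)
        assert tables[0] == ContingencyTable(10, 40, 2, 48)

    def test_everywhere_present_cluster_has_p_one(self):
        m, labels = self._matrix()
        t = prevalence_tables(m, labels)[1]
        assert t.b == t.d == 0
        assert fisher_exact(t) == 1.0

    def test_absent_cluster_dropped_and_margins_match_group_sizes(self):
        m, labels = self._matrix()
        tables = prevalence_tables(m, labels)
        assert 2 not in tables
        for t in tables.values():
            assert t.a + t.b == 50 and t.c + t.d == 50

    def test_single_class_labels_error(self):
        m, labels = self._matrix()
        with pytest.raises(ValueError):
            prevalence_tables(m, pd.Series("healthy", index=labels.index))


class TestBHFDR:
    def test_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_monotone_in_sorted_order_and_order_preserved(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestSelection:
    def test_selection_invariant_to_cluster_ordering(self):
        rng = np.random.default_rng(4)
        idx = [f"d{i}" for i in range(30)] + [f"h{i}" for i in range(30)]
        ab = pd.DataFrame(
            rng.random((60, 40)) < 0.3, index=pd.Index(idx, name="sample_id"),
            columns=range(40), dtype=float,
        )
        ab.loc[: "d29", 5] = 1.0  # strongly disease-associated
        labels = pd.Series(["diseased"] * 30 + ["healthy"] * 30, index=idx)
        res_fwd = differential_abundance(ClusterMatrix(abundance=ab), labels)
        rev = ab[list(ab.columns[::-1])]
        res_rev = differential_abundance(ClusterMatrix(abundance=rev), labels)
        assert set(select_candidates(res_fwd)) == set(select_candidates(res_rev))

    def test_q_at_least_p_and_direction_consistent(self, small_analysis):
        for r in small_analysis.da_results:
            assert r.q >= r.p - 1e-15
            if r.selected:
                assert r.p < 0.001


class TestExclusivity:
    def _presence(self):
        idx = ["h1", "h2", "m1", "m2"]
        df = pd.DataFrame(False, index=pd.Index(idx, name="sample_id"),
                          columns=[0, 1, 2])
        df.loc["h1", 0] = True                  # exclusive to healthy
        df.loc[["h1", "m1"], 1] = True          # shared
        df.loc[["m1", "m2"], 2] = True          # exclusive to MM
        groups = pd.Series(["healthy", "healthy", "MM", "MM"], index=idx)
        return df, groups

    def test_single_carrier_cluster_is_exclusive(self):
        df, groups = self._presence()
        pct = exclusivity(df, groups)
        assert pct["healthy"] == pytest.approx(100 / 3)
        assert pct["MM"] == pytest.approx(100 / 3)

    def test_cross_group_cluster_counts_for_no_one(self):
        df, groups = self._presence()
        counts = exclusivity(df, groups) * 3 / 100
        assert counts.sum() <= 3  # shared cluster excluded from both groups

    def test_constant_statistic_gives_p_one(self):
        idx = ["h1", "h2", "m1", "m2"]
        df = pd.DataFrame(True, index=pd.Index(idx, name="sample_id"), columns=[0])
        groups = pd.Series(["healthy", "healthy", "MM", "MM"], index=idx)
        res = permutation_exclusivity_test(df, groups, n_permutations=50, seed=0)
        for r in res:
            assert r.p_upper == 1.0 and r.p_lower == 1.0

    def test_minimum_attainable_p_is_add_one_bound(self):
        rng = np.random.default_rng(5)
        idx = [f"h{i}" for i in range(10)] + [f"m{i}" for i in range(10)]
        df = pd.DataFrame(rng.random((20, 50)) < 0.2,
                          index=pd.Index(idx, name="sample_id"), columns=range(50))
        groups = pd.Series(["healthy"] * 10 + ["MM"] * 10, index=idx)
        B = 99
        res = permutation_exclusivity_test(df, groups, n_permutations=B, seed=1)
        for r in res:
            assert r.p_upper >= 1 / (B + 1) and r.p_lower >= 1 / (B + 1)

    def test_null_calibration_p_uniformish(self):
        # exchangeable labels: upper-tail empirical p approximately U(0,1)
        rng = np.random.default_rng(6)
        ps = []
        for run in range(100):
            idx = [f"s{i}" for i in range(30)]
            df = pd.DataFrame(rng.random((30, 150)) < 0.15,
                              index=pd.Index(idx, name="sample_id"),
                              columns=range(150))
            groups = pd.Series(["healthy"] * 15 + ["MM"] * 15, index=idx)
            res = permutation_exclusivity_test(df, groups, n_permutations=99,
                                               seed=1000 + run)
            ps.append(res[0].p_upper)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
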