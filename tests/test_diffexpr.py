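import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirforge.diffexpr import (CountMatrix, NormalizationError, bh_adjust,
                               call_demirnas, chi2_2x2,
                               fisher_exact_two_sided, normalize_cpm)
from mirforge.diffexpr import test_anova as anova_battery
from mirforge.diffexpr import test_differential as differential_battery
from oracles import fisher_two_sided_oracle


def _matrix(data, groups):
    df = pd.DataFrame(data)
    return CountMatrix(df, groups)


class TestCPM:
    def test_basic_scaling(self):
        counts = pd.DataFrame({"a": [500, 999_500]})
        cpm = normalize_cpm(counts)
        assert cpm.loc[0, "a"] == pytest.approx(500.0)

    def test_column_sums_are_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 4)),
                              columns=list("abcd"))
        cpm = normalize_cpm(counts)
        assert np.allclose(cpm.sum(axis=0), 1e6)

    def test_zero_count_is_zero_cpm(self):
        cpm = normalize_cpm(pd.DataFrame({"a": [0, 10]}))
        assert cpm.loc[0, "a"] == 0.0

    def test_zero_library_size_names_the_library(self):
        with pytest.raises(NormalizationError, match="libB"):
            normalize_cpm(pd.DataFrame({"libA": [1], "libB": [0]}))


class TestFisher:
    @pytest.mark.parametrize("table", [
        (12, 988, 3, 997), (1, 9, 9, 1), (0, 10, 10, 0),
        (5, 5, 5, 5), (2, 0, 0, 2), (7, 3, 2, 8), (0, 0, 3, 7),
    ])
    def test_matches_exact_enumeration(self, table):
        a, b, c, d = table
        ours = fisher_exact_two_sided([[a, b], [c, d]])
        oracle = float(fisher_two_sided_oracle(a, b, c, d))
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy_reference(self):
        from scipy.stats import fisher_exact
        for table in [[[12, 988], [3, 997]], [[4, 16], [16, 4]]]:
            assert fisher_exact_two_sided(table) == pytest.approx(
                fisher_exact(table, alternative="two-sided")[1], rel=1e-9)

    def test_exhaustive_small_margins(self):
        for r1 in range(0, 9):
            for r2 in range(0, 9):
                for c1 in range(0, r1 + r2 + 1):
                    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                        t = (a, r1 - a, c1 - a, r2 - (c1 - a))
                        ours = fisher_exact_two_sided([t[:2], t[2:]])
                        oracle = float(fisher_two_sided_oracle(*t))
                        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided([[1, -1], [0, 2]])


class TestChi2:
    def test_homogeneous_table_gives_p_one(self):
        stat, p = chi2_2x2([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)


class TestDifferential:
    GROUPS6 = {f"CON_{i}": "CON" for i in range(3)} | \
              {f"TRT_{i}": "TRT" for i in range(3)}

    def test_identical_replicates_give_p_one(self):
        data = {lib: [50, 100] for lib in self.GROUPS6}
        res = differential_battery(_matrix(data, self.GROUPS6), "CON", "TRT")
        assert (res["p"] == 1.0).all()
        assert (res["log2fc"] == 0.0).all()

    def test_all_zero_mirna_flagged_degenerate(self):
        data = {lib: [0, 100] for lib in self.GROUPS6}
        res = differential_battery(_matrix(data, self.GROUPS6), "CON", "TRT")
        assert res.loc[0, "degenerate"]
        assert res.loc[0, "p"] == 1.0 and res.loc[0, "log2fc"] == 0.0

    def test_group_swap_negates_log2fc_and_keeps_p(self, rng):
        data = {lib: rng.integers(1, 500, size=30) for lib in self.GROUPS6}
        m = _matrix(data, self.GROUPS6)
        ab = differential_battery(m, "CON", "TRT")
        ba = differential_battery(m, "TRT", "CON")
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["p"], ba["p"])

    def test_unreplicated_uses_count_tests(self):
        groups = {"CON_1": "CON", "TRT_1": "TRT"}
        data = {"CON_1": [12, 988], "TRT_1": [3, 997]}
        res = differential_battery(_matrix(data, groups), "CON", "TRT")
        assert set(res["test"]) <= {"fisher", "chi2_2x2"}
        fisher_rows = res[res["test"] == "fisher"]
        for _, r in fisher_rows.iterrows():
            assert 0 < r["p"] <= 1

    def test_q_at_least_p(self, rng):
        data = {lib: rng.integers(0, 500, size=40) for lib in self.GROUPS6}
        res = differential_battery(_matrix(data, self.GROUPS6), "CON", "TRT")
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_anova_identical_groups_p_one(self):
        groups = {f"{g}_{i}": g for g in ("A", "B", "C") for i in range(2)}
        data = {lib: [10, 20] for lib in groups}
        res = anova_battery(CountMatrix(pd.DataFrame(data), groups),
                         ["A", "B", "C"])
        assert (res["p"] == 1.0).all()


class TestCallDE:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["mirna", "log2fc", "p"]).assign(
            group_a="CON", group_b="TRT", q=lambda d: d["p"])

    def test_fold_change_gate(self):
        table, tallies = call_demirnas(
            self._results([("m1", 0.8, 0.001)]), alpha=0.05)
        assert not table.loc[0, "de"]
        assert tallies["total_de"] == 0

    def test_passing_both_gates_called_up(self):
        table, tallies = call_demirnas(
            self._results([("m1", 1.5, 0.03)]), alpha=0.05)
        assert table.loc[0, "de"] and table.loc[0, "direction"] == "up"
        assert tallies == {"up": 1, "down": 0, "total_de": 1}

    def test_boundary_fc_inclusive_p_exclusive(self):
        table, _ = call_demirnas(
            self._results([("m1", 1.0, 0.05), ("m2", 1.0, 0.049)]))
        assert not table.set_index("mirna").loc["m1", "de"]  # p not < alpha
        assert table.set_index("mirna").loc["m2", "de"]

    def test_alpha_outside_band_warns(self):
        with pytest.warns(UserWarning):
            call_demirnas(self._results([("m1", 2.0, 0.001)]), alpha=0.10)

    def test_sorted_by_p_then_name(self):
        table, _ = call_demirnas(self._results(
            [("b", 2.0, 0.01), ("a", 2.0, 0.01), ("c", 2.0, 0.001)]))
        assert list(table["mirna"]) == ["c", "a", "b"]


class TestBH:
    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        assert (q >= p - 1e-12).all()
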