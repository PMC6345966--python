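import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from oracles import balanced_two_way_anova, pearson_chi2_2x2

from altimir.diffexp import (
    altitude_monotone_units,
    anova_pop_tmt,
    chisq_de,
    cluster_libraries,
    de_table,
    jaccard,
    log2_fold_change,
)
from altimir.quantify import ExpressionMatrix, normalize_rpm


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "a,b,expected", [(20, 40, 1.0), (0.01, 10.24, 10.0), (3.7, 3.7, 0.0)]
    )
    def test_reference_values(self, a, b, expected):
        assert log2_fold_change(a, b) == pytest.approx(expected)

    @given(
        a=st.floats(min_value=0.01, max_value=1e6),
        b=st.floats(min_value=0.01, max_value=1e6),
    )
    def test_antisymmetry(self, a, b):
        assert log2_fold_change(a, b) == pytest.approx(-log2_fold_change(b, a))

    def test_requires_positive_inputs(self):
        with pytest.raises(ValueError):
            log2_fold_change(0.0, 5.0)


class TestChiSquare:
    def test_example_table(self):
        chi2, p, tested = chisq_de(20, 10**6, 40, 10**6)
        assert chi2 == pytest.approx(6.6667, rel=1e-3)
        assert p == pytest.approx(0.0098, abs=2e-4)
        assert tested

    def test_low_count_gate(self):
        _, _, tested = chisq_de(5, 10**6, 8, 10**6)
        assert not tested
        _, _, tested = chisq_de(11, 10**6, 0, 10**6)
        assert tested  # more than 10 in one library suffices

    def test_equal_proportions_give_zero(self):
        chi2, p, _ = chisq_de(30, 10**6, 30, 10**6)
        assert chi2 == 0.0 and p == 1.0

    def test_count_above_total_rejected(self):
        with pytest.raises(ValueError):
            chisq_de(11, 10, 0, 10)

    def test_matches_closed_form_and_scipy_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            ta, tb = int(rng.integers(100, 10**6)), int(rng.integers(100, 10**6))
            a, b = int(rng.integers(0, 90)), int(rng.integers(0, 90))
            chi2, p, _ = chisq_de(a, ta, b, tb)
            closed = pearson_chi2_2x2(a, ta - a, b, tb - b)
            assert chi2 == pytest.approx(closed, rel=1e-9, abs=1e-12)
            table = [[a, ta - a], [b, tb - b]]
            if min(min(r) for r in table) > 0:
                ref = scipy.stats.chi2_contingency(table, correction=False)
                assert chi2 == pytest.approx(ref.statistic, rel=1e-9)
                assert p == pytest.approx(ref.pvalue, rel=1e-6, abs=1e-12)

    @given(a=st.integers(0, 500), b=st.integers(0, 500))
    def test_symmetric_under_library_swap(self, a, b):
        c1, _, _ = chisq_de(a, 10**5, b, 10**5)
        c2, _, _ = chisq_de(b, 10**5, a, 10**5)
        assert c1 == pytest.approx(c2)


class TestJaccard:
    def test_point_estimates(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}, n_boot=10).point == 0.5
        assert jaccard(set(), {"a"}, n_boot=10).point == 0.0

    def test_identical_sets_collapse_the_ci(self):
        r = jaccard({"a", "b"}, {"a", "b"}, n_boot=100, seed=1)
        assert (r.point, r.ci_low, r.ci_high) == (1.0, 1.0, 1.0)

    def test_disjoint_sets(self):
        r = jaccard({"a"}, {"b"}, n_boot=50)
        assert r.point == 0.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard(set(), set())

    def test_ci_width_shrinks_with_set_size(self):
        def sets(n):
            half = n // 2
            a = {f"x{i}" for i in range(n)}
            b = {f"x{i}" for i in range(half, half + n)}
            return a, b

        small = jaccard(*sets(20), n_boot=500, seed=7)
        large = jaccard(*sets(200), n_boot=500, seed=7)
        assert (large.ci_high - large.ci_low) < (small.ci_high - small.ci_low)

    def test_seed_makes_the_bootstrap_reproducible(self):
        a, b = {"a", "b", "c", "d"}, {"c", "d", "e"}
        r1 = jaccard(a, b, n_boot=200, seed=3)
        r2 = jaccard(a, b, n_boot=200, seed=3)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)


def _rpm_matrix(data: dict[str, dict[str, float]]) -> ExpressionMatrix:
    rpm = pd.DataFrame(data)  # libraries as columns
    raw = (rpm * 10).round().astype(int)
    m = ExpressionMatrix(raw=raw)
    m.rpm = rpm
    m.library_totals = pd.Series({c: 10_000_000 for c in rpm.columns})
    return m


class TestClustering:
    def test_identical_libraries_merge_first_at_zero_distance(self):
        rng = np.random.default_rng(0)
        prof = rng.lognormal(3, 1, size=8)
        m = _rpm_matrix(
            {"A": prof, "B": prof, "C": rng.lognormal(3, 1, size=8)}
        )
        z, labels, newick = cluster_libraries(m)
        first = z[0]
        assert {labels[int(first[0])], labels[int(first[1])]} == {"A", "B"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_scaled_library_is_at_zero_correlation_distance(self):
        # doubling every RPM shifts the log2 profile by +1: r stays 1
        rng = np.random.default_rng(1)
        prof = rng.lognormal(3, 1, size=10)
        m = _rpm_matrix({"A": prof, "B": prof * 2, "C": rng.lognormal(3, 1, size=10)})
        z, labels, _ = cluster_libraries(m)
        assert z[0][2] == pytest.approx(0.0, abs=1e-9)

    def test_constant_profile_is_rejected_by_name(self):
        m = _rpm_matrix({"A": [1.0, 1.0, 1.0], "B": [1, 2, 3], "C": [3, 1, 2]})
        with pytest.raises(ValueError, match="A"):
            cluster_libraries(m)

    def test_condition_effect_groups_libraries_by_condition(self):
        """With a growing-condition effect much larger than the population
        effect, the top split separates field from glasshouse profiles."""
        rng = np.random.default_rng(2)
        base = rng.lognormal(4, 0.8, size=40)
        libs = {}
        for pop_shift, pop in zip((1.0, 1.15, 1.3), ("Deh", "Mun", "Chit")):
            for cond in ("FD", "GH"):
                prof = base.copy() * pop_shift
                if cond == "GH":
                    prof[:12] *= 8.0  # strong shared condition response
                libs[f"{pop}_{cond}"] = prof * rng.lognormal(0, 0.05, size=40)
        m = _rpm_matrix(libs)
        z, labels, _ = cluster_libraries(m)
        two = sch.fcluster(z, t=2, criterion="maxclust")
        groups = {}
        for lab, cl in zip(labels, two):
            groups.setdefault(cl, set()).add(lab.split("_")[1])
        assert sorted(map(tuple, (sorted(g) for g in groups.values()))) == [("FD",), ("GH",)]


class TestAnova:
    def _simulate(self, seed, pop_delta=4.0, tmt_delta=0.0, n_rep=3):
        rng = np.random.default_rng(seed)
        rows, pops, tmts = [], [], []
        libs = []
        design = {}
        for p_i, pop in enumerate(("P1", "P2", "P3")):
            for tmt in ("FD", "GH"):
                for r in range(n_rep):
                    lib = f"{pop}_{tmt}_{r}"
                    libs.append(lib)
                    design[lib] = (pop, tmt)
                    rows.append(
                        p_i * pop_delta + (tmt == "GH") * tmt_delta + rng.normal(0, 1)
                    )
        responses = pd.DataFrame([rows], index=["u"], columns=libs)
        return responses, design

    def test_planted_population_effect_is_detected(self):
        responses, design = self._simulate(0, pop_delta=4.0)
        out = anova_pop_tmt(responses, design)
        assert out.loc[0, "p_pop"] < 0.01
        assert out.loc[0, "p_tmt"] > 0.01  # no planted condition effect

    def test_matches_textbook_sums_of_squares(self):
        responses, design = self._simulate(3, pop_delta=1.0, tmt_delta=2.0)
        out = anova_pop_tmt(responses, design)
        libs = list(responses.columns)
        oracle = balanced_two_way_anova(
            responses.loc["u", libs].to_numpy(),
            [design[l][0] for l in libs],
            [design[l][1] for l in libs],
        )
        assert out.loc[0, "F_pop"] == pytest.approx(oracle["F_pop"], rel=1e-6)
        assert out.loc[0, "F_tmt"] == pytest.approx(oracle["F_tmt"], rel=1e-6)
        assert out.loc[0, "F_interaction"] == pytest.approx(oracle["F_interaction"], rel=1e-6)

    def test_swapping_factor_labels_exchanges_the_p_values(self):
        responses, design = self._simulate(1, pop_delta=0.0, tmt_delta=3.0)
        out = anova_pop_tmt(responses, design)
        swapped = {l: (t, p) for l, (p, t) in design.items()}
        out_sw = anova_pop_tmt(responses, swapped)
        assert out.loc[0, "p_tmt"] == pytest.approx(out_sw.loc[0, "p_pop"])
        assert out.loc[0, "p_pop"] == pytest.approx(out_sw.loc[0, "p_tmt"])

    def test_constant_response_gives_p_one(self):
        responses, design = self._simulate(2)
        responses.loc["u"] = 5.0
        out = anova_pop_tmt(responses, design)
        assert out.loc[0, "p_pop"] == 1.0 and out.loc[0, "p_tmt"] == 1.0

    def test_single_replicate_drops_interaction_with_warning(self):
        responses, design = self._simulate(4, n_rep=1)
        with pytest.warns(UserWarning, match="interaction"):
            out = anova_pop_tmt(responses, design)
        assert np.isnan(out.loc[0, "p_interaction"])


class TestMonotone:
    def _de(self, rows):
        return pd.DataFrame(
            [
                {"unit": u, "log2fc": fc, "significant": sig}
                for u, fc, sig in rows
            ]
        )

    def test_rule_application(self):
        low_mid = self._de([("u", 2.0, True), ("v", 2.0, True), ("w", -2.0, True)])
        mid_high = self._de([("u", 2.0, True), ("v", -2.0, True), ("w", -1.5, True)])
        up, down = altitude_monotone_units(low_mid, mid_high)
        assert up == {"u"}
        assert down == {"w"}
        assert "v" not in up | down  # up then down is not monotone

    def test_non_significant_steps_do_not_count(self):
        low_mid = self._de([("u", 2.0, False)])
        mid_high = self._de([("u", 2.0, True)])
        up, down = altitude_monotone_units(low_mid, mid_high)
        assert up == set() and down == set()


class TestDETable:
    def test_gate_combines_test_flag_p_and_fold_change(self):
        raw = pd.DataFrame({"a": [100, 8, 2000], "b": [400, 5, 2010]}, index=["u", "v", "w"])
        m = ExpressionMatrix(raw=raw)
        normalize_rpm(m, {"a": 1_000_000, "b": 1_000_000})
        df = de_table(m, "a", "b").set_index("unit")
        assert df.loc["u", "significant"]  # 4x change, well-tested
        assert not df.loc["v", "significant"]  # below the count gate
        assert not df.loc["v", "tested"]
        assert not df.loc["w", "significant"]  # tiny fold change
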