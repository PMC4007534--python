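import numpy as np
import pytest

from endoshrink.curation import OrthologSet
from endoshrink.decomposition import LengthDecomposition
from endoshrink.io_formats import ProteinRecord, SpeciesMeta
from endoshrink.variability import (
    GroupDispersion,
    bubble_table,
    classify,
    compare_groups,
    dispersion,
    fit_regression,
    mann_whitney,
    per_species_average_lengths,
    summarize_classification,
    tukey_range,
    variance_of_averages,
)

from oracles import exact_mann_whitney_p, ols_normal_equations, tukey_oracle


class TestTukeyRange:
    def test_constant_data(self):
        rng, outliers = tukey_range([5, 5, 5, 5])
        assert rng == 0 and outliers == []

    def test_single_extreme_point_excluded(self):
        # type-7 quartiles of {1,2,3,4,100}: Q1=2, Q3=4 → fences [-1, 7]
        rng, outliers = tukey_range([1, 2, 3, 4, 100])
        assert rng == 3 and outliers == [100]

    def test_small_sample_keeps_all_points(self):
        # {1,2,3,4}: Q1=1.75, Q3=3.25, fences [-0.5, 5.5] contain everything
        rng, outliers = tukey_range([1, 2, 3, 4])
        assert rng == 3 and outliers == []

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tukey_range([])

    def test_matches_sorted_array_oracle_on_random_vectors(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n = int(rng.integers(2, 40))
            vals = rng.normal(0, 50, n)
            if rng.random() < 0.5:
                vals = np.round(vals)
            got_range, got_out = tukey_range(vals)
            exp_range, exp_out = tukey_oracle(vals)
            assert got_range == pytest.approx(exp_range, abs=1e-9)
            assert got_out == pytest.approx(exp_out)


def _mini_set(oie_lengths, nonoie_lengths):
    members = []
    decomp = {}
    for i, ln in enumerate(oie_lengths):
        m = SpeciesMeta(f"o{i}", "F", "OIE", 0.3)
        p = ProteinRecord(f"o{i}_p", f"o{i}", "A" * ln)
        members.append((m, p))
        decomp[p.protein_id] = LengthDecomposition(p.protein_id, ln, 0, ln)
    for i, ln in enumerate(nonoie_lengths):
        m = SpeciesMeta(f"n{i}", "F", "nonOIE", 3.0)
        p = ProteinRecord(f"n{i}_p", f"n{i}", "A" * ln)
        members.append((m, p))
        decomp[p.protein_id] = LengthDecomposition(p.protein_id, ln, 0, ln)
    oset = OrthologSet("g1", tuple(members), (), 0.0, {})
    return oset, decomp


class TestDispersion:
    def test_arithmetic_sequence_sd(self):
        oset, decomp = _mini_set([100, 110, 120], [105, 105, 105])
        out = dispersion(oset, decomp, "total")
        assert out["OIE"].sd == pytest.approx(10.0)
        assert out["nonOIE"].sd == 0.0
        assert out["OIE"].n == 3 and out["nonOIE"].n == 3

    def test_identical_lengths_all_metrics_zero(self):
        oset, decomp = _mini_set([200, 200, 200], [200, 200, 200])
        for d in dispersion(oset, decomp, "total").values():
            assert d.range_excl_outliers == d.sd == d.iqr == 0

    def test_linker_target_applies_same_contract(self):
        oset, decomp = _mini_set([100, 110, 120], [105, 105, 105])
        out = dispersion(oset, decomp, "linker")  # all-linker decompositions
        assert out["OIE"].sd == pytest.approx(10.0)

    def test_single_member_lifestyle_rejected(self):
        oset, decomp = _mini_set([100], [105, 106])
        with pytest.raises(ValueError, match="≥2"):
            dispersion(oset, decomp, "total")

    def test_iqr_and_trimmed_range_bounded_by_full_range(self, pipeline_results):
        for d in pipeline_results["variability"]["dispersions"]:
            assert d.iqr >= 0 and d.sd >= 0
            assert d.range_excl_outliers >= d.iqr  # trimmed range still ≥ IQR


def _disp(gid, lifestyle, rng_, sd, iqr_):
    return GroupDispersion(gid, lifestyle, "total", 5, rng_, sd, iqr_)


class TestClassification:
    def test_larger_oie_range_wins(self):
        cats = classify({"OIE": _disp("g", "OIE", 12, 1, 1),
                         "nonOIE": _disp("g", "nonOIE", 3, 1, 1)})
        assert cats[0].category == "OIE_more_variable"
        assert {c.category for c in cats[1:]} == {"variable_in_both"}

    def test_both_zero_is_no_variability(self):
        cats = classify({"OIE": _disp("g", "OIE", 0, 0, 0),
                         "nonOIE": _disp("g", "nonOIE", 0, 0, 0)})
        assert all(c.category == "no_variability" for c in cats)

    def test_nonzero_tie_is_variable_in_both(self):
        cats = classify({"OIE": _disp("g", "OIE", 5, 5, 5),
                         "nonOIE": _disp("g", "nonOIE", 5, 5, 5)})
        assert all(c.category == "variable_in_both" for c in cats)

    def test_summary_counts_partition_the_sets(self, pipeline_results):
        res = pipeline_results["variability"]
        n_sets = len(pipeline_results["sets"])
        for metric in ("range", "sd", "iqr"):
            rows = [r for r in res["summary"] if r["metric"] == metric]
            assert sum(r["count"] for r in rows) == n_sets
            assert sum(r["percent"] for r in rows) == pytest.approx(100, abs=0.01)

    def test_summary_rejects_empty(self):
        with pytest.raises(ValueError):
            summarize_classification([])


class TestCompareGroups:
    def test_identical_samples_mann_whitney_p_one(self):
        res = compare_groups([1, 2, 3], [1, 2, 3])
        assert res["mann_whitney_p"] == pytest.approx(1.0)

    def test_disjoint_tiny_samples_match_exact_enumeration(self):
        res = compare_groups([1, 2], [10, 11])
        assert res["mann_whitney_p"] == pytest.approx(1 / 3, abs=1e-12)
        assert res["mann_whitney_p"] == pytest.approx(
            exact_mann_whitney_p([1, 2], [10, 11])
        )

    def test_means_are_arithmetic_means(self):
        res = compare_groups([1.0, 2.0, 6.0], [4.0, 8.0])
        assert res["oie_mean"] == pytest.approx(3.0)
        assert res["nonoie_mean"] == pytest.approx(6.0)

    def test_degenerate_all_equal_inputs(self):
        res = compare_groups([2, 2, 2], [2, 2])
        assert np.isnan(res["t_test_p"])
        assert res["mann_whitney_p"] == 1.0

    def test_tied_inputs_use_corrected_normal_approximation(self):
        # frozen from R: wilcox.test(c(1,2,2,3), c(2,3,3,4), exact=FALSE,
        # correct=TRUE)$p.value == 0.1720337
        assert mann_whitney([1, 2, 2, 3], [2, 3, 3, 4]) == pytest.approx(
            0.1720337, abs=1e-6
        )


class TestRegression:
    def test_exact_line(self):
        x = [1, 2, 3, 4, 5]
        fit = fit_regression(x, [2 * v for v in x])
        assert fit.slope == pytest.approx(2) and fit.r_squared == pytest.approx(1)

    def test_constant_response(self):
        fit = fit_regression([1, 2, 3, 4], [7, 7, 7, 7])
        assert fit.slope == 0 and fit.r_squared == 0

    def test_matches_normal_equations_on_random_data(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 3, 10)
        y = 1.5 * x + rng.normal(0, 1, 10)
        fit = fit_regression(x, y)
        slope, intercept, r2 = ols_normal_equations(list(x), list(y))
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_regression([1, 1, 1], [1, 2, 3])


class TestSpeciesAverages:
    META = [
        SpeciesMeta("o1", "F", "OIE", 0.3), SpeciesMeta("o2", "F", "OIE", 0.5),
        SpeciesMeta("n1", "F", "nonOIE", 3.0),
    ]

    def test_sample_variance_of_two_points(self):
        var = variance_of_averages({"o1": 1.0, "o2": 3.0, "n1": 5.0}, self.META)
        assert var["OIE"] == pytest.approx(2.0)
        assert np.isnan(var["nonOIE"])  # singleton lifestyle → undefined

    def test_constant_averages_zero_variance(self):
        var = variance_of_averages({"o1": 4.0, "o2": 4.0, "n1": 5.0}, self.META)
        assert var["OIE"] == 0.0

    def test_per_species_average_uses_curated_sets_only(self, pipeline_results):
        sets = pipeline_results["sets"]
        avgs = per_species_average_lengths(sets)
        sid = sets[0].members[0][0].species_id
        manual = np.mean(
            [p.length for s in sets for m, p in s.members if m.species_id == sid]
        )
        assert avgs[sid] == pytest.approx(manual)


class TestBubbleTable:
    def test_proportions_over_distinct_lengths(self):
        oset, _ = _mini_set([100, 100, 101, 102], [200, 200])
        rows = {
            (r["length"]): r["proportion"]
            for r in bubble_table(oset)
            if r["lifestyle"] == "OIE"
        }
        assert rows == {100: 0.5, 101: 0.25, 102: 0.25}

    def test_per_lifestyle_proportions_sum_to_one(self, pipeline_results):
        for s in pipeline_results["sets"][:10]:
            rows = bubble_table(s)
            for lifestyle in ("OIE", "nonOIE"):
                total = sum(
                    r["proportion"] for r in rows if r["lifestyle"] == lifestyle
                )
                assert total == pytest.approx(1.0)
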