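"""Normalization, grouping and the enrichment call statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from matescreen.enrichment_stats import (
    call_enrichment,
    call_enrichment_grouped,
    group_library_on_library,
    normalize_to_control,
    proportions,
    student_t_test,
)
from matescreen.screen_model import ScreenDesign


def _design(**kw):
    kw.setdefault("experimental_groups", ["868"])
    kw.setdefault("control_groups", ["A6", "2C"])
    kw.setdefault("internal_control", "3*")
    return ScreenDesign(**kw)


def _random_counts(rng, n_var=6, n_rep=4, low=1, high=500):
    idx = [f"v{i}" for i in range(n_var)]
    cols = [f"rep{j}" for j in range(n_rep)]
    return pd.DataFrame(
        rng.integers(low, high, size=(n_var, n_rep)), index=idx, columns=cols
    )


class TestProportions:
    def test_arithmetic(self):
        df = pd.DataFrame({"rep1": [50, 50]}, index=["A", "B"])
        out = proportions(df)
        assert out.loc["A", "rep1"] == 0.5

    def test_single_variant_degenerate(self):
        df = pd.DataFrame({"rep1": [7]}, index=["A"])
        assert proportions(df).loc["A", "rep1"] == 1.0

    def test_columns_sum_to_one(self, rng):
        for _ in range(20):
            out = proportions(_random_counts(rng))
            assert np.allclose(out.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_total_replicate_rejected(self):
        df = pd.DataFrame({"rep1": [0, 0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="zero assigned"):
            proportions(df)


class TestNormalization:
    def test_ratio_arithmetic(self):
        df = pd.DataFrame({"rep1": [300, 100]}, index=["SL9", "3*"])
        ratios = normalize_to_control(df, "3*")
        assert ratios.loc["SL9", "rep1"] == 3.0

    def test_control_ratio_is_one_everywhere(self, rng):
        for _ in range(20):
            counts = _random_counts(rng)
            ratios = normalize_to_control(counts, "v0")
            assert np.allclose(ratios.loc["v0"], 1.0)

    def test_counts_and_proportions_give_same_ratios(self, rng):
        counts = _random_counts(rng)
        from_counts = normalize_to_control(counts, "v0")
        from_props = proportions(counts) / proportions(counts).loc["v0"]
        assert np.allclose(from_counts, from_props)

    def test_scale_invariance(self, rng):
        counts = _random_counts(rng)
        scaled = counts * 17
        assert np.allclose(
            normalize_to_control(counts, "v0"), normalize_to_control(scaled, "v0")
        )

    def test_missing_control_rejected(self):
        df = pd.DataFrame({"rep1": [1]}, index=["A"])
        with pytest.raises(ValueError, match="absent"):
            normalize_to_control(df, "3*")

    def test_zero_control_needs_pseudocount(self):
        df = pd.DataFrame({"rep1": [5, 0]}, index=["A", "3*"])
        with pytest.raises(ValueError, match="pseudocount"):
            normalize_to_control(df, "3*")
        ratios = normalize_to_control(df, "3*", pseudocount=0.5)
        assert ratios.loc["A", "rep1"] == pytest.approx(5.5 / 0.5)


class TestStudentT:
    def test_textbook_oracle(self):
        # frozen values from an independent hand computation of the pooled
        # formula: t = (3.0 - 1.0) / sqrt(0.025 * 2/3), df = 4
        t, p = student_t_test([3.1, 2.9, 3.0], [1.0, 1.2, 0.8], tails="two")
        assert t == pytest.approx(15.49193338482967, rel=1e-12)
        assert p == pytest.approx(1.0133520168590366e-4, rel=1e-9)

    def test_identical_groups(self):
        t, p = student_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_swap_negates_t_preserves_p(self, rng):
        x = rng.normal(2, 1, size=5)
        y = rng.normal(0, 1, size=4)
        t1, p1 = student_t_test(x, y)
        t2, p2 = student_t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(50):
            x = rng.normal(0, 1, size=int(rng.integers(2, 8)))
            y = rng.normal(0.5, 1, size=int(rng.integers(2, 8)))
            t, p = student_t_test(x, y, tails="two")
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert t == pytest.approx(float(ref.statistic), rel=1e-10)
            assert p == pytest.approx(float(ref.pvalue), rel=1e-10)

    def test_one_tailed_is_upper_tail(self):
        t2, p2 = student_t_test([3.0, 3.1], [1.0, 1.1], tails="two")
        t1, p1 = student_t_test([3.0, 3.1], [1.0, 1.1], tails="one")
        assert t1 == t2
        assert p1 == pytest.approx(p2 / 2)

    def test_zero_variance_conventions(self):
        t, p = student_t_test([2.0, 2.0], [1.0, 1.0])
        assert math.isinf(t) and t > 0
        assert p == 0.0

    def test_insufficient_observations(self):
        with pytest.raises(ValueError):
            student_t_test([1.0], [1.0, 2.0])


class TestCalls:
    def _ratios(self):
        cols = ["e1", "e2", "e3", "c1", "c2", "c3"]
        arms = {c: ("experimental" if c.startswith("e") else "control") for c in cols}
        data = {
            "up": [3.0, 3.2, 2.8, 1.0, 1.1, 0.9],  # FC ~3, tiny p -> called
            "down": [0.8, 0.82, 0.78, 1.0, 1.02, 0.98],  # FC < 1 -> not called
            "noisy": [5.0, 0.1, 1.4, 1.0, 1.1, 0.9],  # FC > 1 but p large
            "3*": [1.0] * 6,
        }
        df = pd.DataFrame(data).T
        df.columns = cols
        return df, arms

    def test_cutoff_logic(self):
        ratios, arms = self._ratios()
        out = call_enrichment(ratios, arms, _design())
        assert bool(out.loc["up", "call"])
        assert not bool(out.loc["down", "call"])
        assert out.loc["down", "p_value"] < 0.05  # fails only the FC cutoff
        assert not bool(out.loc["noisy", "call"])
        assert out.loc["noisy", "fold_change"] > 1
        assert not bool(out.loc["3*", "call"])

    def test_call_equals_conjunction_of_cutoffs(self, rng):
        design = _design()
        for _ in range(10):
            counts = _random_counts(rng, n_var=8, n_rep=6)
            counts.columns = ["e1", "e2", "e3", "c1", "c2", "c3"]
            arms = {c: ("experimental" if c.startswith("e") else "control")
                    for c in counts.columns}
            ratios = normalize_to_control(counts, "v0")
            out = call_enrichment(ratios, arms, design)
            expected = (out["fold_change"] > design.fold_change_cutoff) & (
                out["p_value"] < design.p_cutoff
            )
            assert (out["call"] == expected).all()

    def test_bh_column_opt_in(self):
        ratios, arms = self._ratios()
        out = call_enrichment(ratios, arms, _design(), bh=True)
        assert "adjusted_p" in out.columns
        assert (out["adjusted_p"] >= out["p_value"] - 1e-15).all()

    def test_rows_sorted_lexicographically(self):
        ratios, arms = self._ratios()
        out = call_enrichment(ratios, arms, _design())
        assert list(out.index) == sorted(out.index)


class TestLibraryOnLibraryGrouping:
    @pytest.fixture()
    def registry(self, make_record):
        bcs = iter(["A" * 15, "C" * 15, "G" * 15, "T" * 15, "AC" * 7 + "A", "AG" * 7 + "A"])
        recs = [
            make_record("868-1", "GAHDYALN", kind="TCR", group_id="868",
                        barcodes=(next(bcs),)),
            make_record("868-2", "GAHDYALN", kind="TCR", group_id="868",
                        barcodes=(next(bcs),)),
            make_record("A6-1", "GTHDYALN", kind="TCR", group_id="A6",
                        barcodes=(next(bcs),)),
        ]
        recs.append(
            make_record("SL9", "SLYNTVATL", barcodes=(next(bcs),))
        )
        recs.append(make_record("3*", "SL*NTVATL", barcodes=(next(bcs),)))
        return recs

    def _counts(self):
        idx = pd.MultiIndex.from_tuples(
            [
                ("868-1", "SL9"), ("868-1", "3*"),
                ("868-2", "SL9"), ("868-2", "3*"),
                ("A6-1", "SL9"), ("A6-1", "3*"),
            ],
            names=["a_strain", "alpha_strain"],
        )
        return pd.DataFrame({"rep1": [60, 40, 80, 20, 10, 90]}, index=idx)

    def test_mean_of_barcode_proportions_then_normalize(self, registry):
        # clone proportions 0.6/0.4 and 0.8/0.2 average to 0.7/0.3
        ratios = group_library_on_library(self._counts(), registry, "3*")
        assert ratios.loc[("868", "SL9"), "rep1"] == pytest.approx(0.7 / 0.3)
        assert ratios.loc[("868", "3*"), "rep1"] == pytest.approx(1.0)
        assert ratios.loc[("A6", "SL9"), "rep1"] == pytest.approx(0.1 / 0.9)

    def test_single_clone_group_is_identity(self, registry):
        counts = self._counts().loc[[("A6-1", "SL9"), ("A6-1", "3*")]]
        ratios = group_library_on_library(counts, registry, "3*")
        assert ratios.loc[("A6", "SL9"), "rep1"] == pytest.approx(10 / 90)

    def test_zero_read_strain_rejected(self, registry):
        counts = self._counts()
        counts.loc[("A6-1", "SL9"), "rep1"] = 0
        counts.loc[("A6-1", "3*"), "rep1"] = 0
        with pytest.raises(ValueError, match="zero reads"):
            group_library_on_library(counts, registry, "3*")

    def test_grouped_calls_compare_arms_per_peptide(self, registry, rng):
        idx = pd.MultiIndex.from_product(
            [["868-1", "868-2", "A6-1"], ["SL9", "3*"]],
            names=["a_strain", "alpha_strain"],
        )
        cols = ["rep1", "rep2", "rep3"]
        base = rng.integers(50, 150, size=(6, 3))
        counts = pd.DataFrame(base, index=idx, columns=cols)
        counts.loc[("868-1", "SL9")] = [900, 950, 920]
        counts.loc[("868-2", "SL9")] = [880, 940, 910]
        design = _design(control_groups=["A6"])
        ratios = group_library_on_library(counts, registry, "3*")
        out = call_enrichment_grouped(ratios, design)
        assert bool(out.loc["SL9", "call"])
        assert not bool(out.loc["3*", "call"])
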