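import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from copath import (
    DesignError,
    ExperimentDesign,
    NormalizationError,
    bh_adjust,
    estimate_size_factors,
    normalized_counts,
    differential_expression,
)
from conftest import make_dataset
from _oracles import bh_stepup_literal


class TestSizeFactors:
    def test_doubled_sample_gives_sqrt2_split(self):
        """B = 2 x A elementwise => factors (1/sqrt2, sqrt2) exactly."""
        ds = make_dataset(
            {"A": [10, 20, 5, 7], "B": [20, 40, 10, 14]},
            {"A": "c1", "B": "c2"},
        )
        factors = estimate_size_factors(ds)
        assert factors["A"] == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert factors["B"] == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_identical_samples_all_one(self):
        ds = make_dataset(
            {"A": [3, 9, 1], "B": [3, 9, 1], "C": [3, 9, 1]},
            {"A": "c", "B": "c", "C": "c"},
        )
        assert np.allclose(estimate_size_factors(ds), 1.0)

    def test_single_sample_is_one(self):
        ds = make_dataset({"A": [5, 2, 8]}, {"A": "c"})
        assert estimate_size_factors(ds)["A"] == pytest.approx(1.0)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(4)
        ds = make_dataset(
            {f"s{i}": rng.poisson(50, 30) + 1 for i in range(5)},
            {f"s{i}": "c" for i in range(5)},
        )
        factors = estimate_size_factors(ds)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0)

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(9)
        base = {f"s{i}": rng.poisson(100, 200) + 1 for i in range(4)}
        conditions = {f"s{i}": "c" for i in range(4)}
        before = estimate_size_factors(make_dataset(dict(base), conditions))
        scaled = dict(base)
        scaled["s0"] = [4 * v for v in base["s0"]]
        after = estimate_size_factors(make_dataset(scaled, conditions))
        # the scaled sample's factor moves ~4x relative to the others
        rel = (after["s0"] / after["s1"]) / (before["s0"] / before["s1"])
        assert rel == pytest.approx(4.0, rel=0.01)

    def test_no_universally_expressed_gene_raises(self):
        ds = make_dataset(
            {"A": [5, 0], "B": [0, 3]}, {"A": "c1", "B": "c2"}
        )
        with pytest.raises(NormalizationError, match="pseudocount"):
            estimate_size_factors(ds)


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        assert np.allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_of_one(self):
        assert bh_adjust([1.0]) == pytest.approx([1.0])

    @pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.2], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=60,
        )
    )
    def test_matches_literal_stepup_oracle(self, pvals):
        assert np.allclose(bh_adjust(pvals), bh_stepup_literal(pvals), rtol=1e-12)

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 400))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected, rtol=1e-10)

    def test_monotone_nondecreasing_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, 500)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


@pytest.fixture
def two_group_ds():
    rng = np.random.default_rng(123)
    counts = {}
    conditions = {}
    for cond, shift in (("ref", 0), ("alt", 0)):
        for r in range(4):
            name = f"{cond}{r}"
            counts[name] = rng.poisson(100, 50)
            conditions[name] = cond
    return make_dataset(counts, conditions)


class TestTestDe:
    def test_identical_counts_gene_is_unchanged(self):
        ds = make_dataset(
            {"a1": [50, 80], "a2": [50, 80], "b1": [50, 80], "b2": [50, 80]},
            {"a1": "ref", "a2": "ref", "b1": "alt", "b2": "alt"},
        )
        design = ExperimentDesign("ref", ("alt",))
        de = differential_expression(ds, design, min_mean_count=0)
        assert (de["log2fc"] == 0).all()
        assert (de["call"] == "unchanged").all()
        assert (de["p"] == 1.0).all()

    def test_replicate_label_permutation_is_invariant(self, two_group_ds):
        design = ExperimentDesign("ref", ("alt",))
        de1 = differential_expression(two_group_ds, design)
        # swap the two ref replicates' column order
        permuted = two_group_ds.counts[
            ["ref1", "ref0", "ref2", "ref3", "alt0", "alt1", "alt2", "alt3"]
        ]
        meta = two_group_ds.sample_meta.loc[permuted.columns]
        from copath import CountDataset

        ds2 = CountDataset(counts=permuted, sample_meta=meta)
        de2 = differential_expression(ds2, design)
        pd.testing.assert_frame_equal(de1, de2)

    def test_missing_condition_raises_design_error(self, two_group_ds):
        design = ExperimentDesign("ref", ("missing",))
        with pytest.raises(DesignError, match="missing"):
            differential_expression(two_group_ds, design)

    def test_single_replicate_requires_fold_change_only(self):
        ds = make_dataset(
            {"a1": [10, 400], "b1": [40, 100]}, {"a1": "ref", "b1": "alt"}
        )
        design = ExperimentDesign("ref", ("alt",))
        with pytest.raises(DesignError, match="fold_change_only"):
            differential_expression(ds, design, min_mean_count=0)
        de = differential_expression(ds, design, min_mean_count=0, fold_change_only=True)
        assert (de["p"] == 1.0).all() and (de["q"] == 1.0).all()
        assert set(de["call"]) <= {"up", "down", "unchanged"}
        assert (de["call"] != "unchanged").any()

    def test_min_mean_count_filters_universe(self, two_group_ds):
        design = ExperimentDesign("ref", ("alt",))
        norm = normalized_counts(two_group_ds)
        threshold = float(norm.mean(axis=1).median())
        de = differential_expression(two_group_ds, design, min_mean_count=threshold)
        expected = set(norm.index[norm.mean(axis=1) >= threshold])
        assert set(de["gene"]) == expected
        with pytest.raises(DesignError, match="min_mean_count"):
            differential_expression(two_group_ds, design, min_mean_count=1e9)

    def test_call_consistency_invariant(self, default_sim):
        """call=up iff log2fc >= 1 and q <= 0.05; down symmetric."""
        spec, ds, _, _ = default_sim
        de = differential_expression(ds, spec.design)
        up = de["call"] == "up"
        down = de["call"] == "down"
        assert ((de.loc[up, "log2fc"] >= 1) & (de.loc[up, "q"] <= 0.05)).all()
        assert ((de.loc[down, "log2fc"] <= -1) & (de.loc[down, "q"] <= 0.05)).all()
        rest = de[~up & ~down]
        assert (
            (rest["q"] > 0.05) | (rest["log2fc"].abs() < 1)
        ).all()
        assert de["q"].between(0, 1).all() and (de["p"] > 0).all()

    def test_welch_mode_available(self, two_group_ds):
        design = ExperimentDesign("ref", ("alt",))
        de = differential_expression(two_group_ds, design, variance_mode="welch")
        assert set(de.columns) == {"gene", "contrast", "log2fc", "p", "q", "call"}
        with pytest.raises(ValueError, match="variance_mode"):
            differential_expression(two_group_ds, design, variance_mode="bogus")


class TestNormalizationInvariance:
    def test_proportional_scaling_leaves_calls_unchanged(self, small_sim_spec_kwargs):
        from copath import SimulationSpec, simulate_dataset, CountDataset

        spec = SimulationSpec(**small_sim_spec_kwargs)
        ds, _, _ = simulate_dataset(spec)
        de1 = differential_expression(ds, spec.design)
        scaled_counts = ds.counts.copy()
        sample = scaled_counts.columns[0]
        scaled_counts[sample] = scaled_counts[sample] * 3
        ds2 = CountDataset(counts=scaled_counts, sample_meta=ds.sample_meta)
        f1, f2 = estimate_size_factors(ds), estimate_size_factors(ds2)
        rel = (f2[sample] / f2.iloc[1]) / (f1[sample] / f1.iloc[1])
        assert rel == pytest.approx(3.0, rel=0.02)
        de2 = differential_expression(ds2, spec.design)
        agree = (de1["call"].values == de2["call"].values).mean()
        assert agree > 0.995
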