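import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from copath import (
    CoexpressionPath,
    DesignError,
    ExperimentDesign,
    IncompletenessError,
    classify_paths,
    extract_restoration_sets,
    path_table,
    restoration_table,
)
from _oracles import classify_one_gene_at_a_time

CALLS = ("up", "down", "unchanged")


def de_table(calls: dict[str, tuple[str, ...]], conditions) -> pd.DataFrame:
    rows = [
        {"gene": g, "contrast": c, "log2fc": 0.0, "p": 1.0, "q": 1.0, "call": call}
        for g, gene_calls in calls.items()
        for c, call in zip(conditions, gene_calls)
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def conditions3():
    return ("NI_C286", "SNL_vehicle", "SNL_C286")


@pytest.fixture
def design3(conditions3):
    return ExperimentDesign("NI_vehicle", conditions3)


class TestClassifyPaths:
    def test_label_is_ordered_call_tuple(self, design3, conditions3):
        de = de_table({"g1": ("unchanged", "up", "unchanged")}, conditions3)
        (path,) = classify_paths(de, design3)
        assert path.label == ("unchanged", "up", "unchanged")
        assert path.label_str == "unchanged|up|unchanged"
        assert path.genes == {"g1"}

    def test_singleton_paths_one_condition(self):
        design = ExperimentDesign("ref", ("alt",))
        de = de_table({"g1": ("up",), "g2": ("down",)}, ("alt",))
        paths = classify_paths(de, design)
        assert {p.label_str for p in paths} == {"up", "down"}
        assert all(len(p) == 1 for p in paths)

    def test_flat_path_flagged(self, design3, conditions3):
        de = de_table({"g1": ("unchanged",) * 3, "g2": ("up",) * 3}, conditions3)
        flat = [p for p in classify_paths(de, design3) if p.is_flat]
        assert len(flat) == 1 and flat[0].genes == {"g1"}

    def test_partition_and_oracle_agreement(self, design3, conditions3):
        rng = np.random.default_rng(17)
        calls = {
            f"g{i}": tuple(rng.choice(CALLS, 3)) for i in range(80)
        }
        de = de_table(calls, conditions3)
        paths = classify_paths(de, design3)
        # partition: disjoint and exhaustive
        assert sum(len(p) for p in paths) == 80
        union = set().union(*(p.genes for p in paths))
        assert union == set(calls)
        # brute-force one-gene-at-a-time oracle
        oracle = classify_one_gene_at_a_time(de, conditions3)
        assert {p.label: set(p.genes) for p in paths} == oracle
        assert len(paths) <= 3**3

    def test_missing_contrast_row_names_gene(self, design3, conditions3):
        de = de_table({"g1": ("up", "up", "up"), "g2": ("up", "up", "up")},
                      conditions3)
        de = de[~((de["gene"] == "g2") & (de["contrast"] == "SNL_C286"))]
        with pytest.raises(IncompletenessError, match="g2"):
            classify_paths(de, design3)

    def test_absent_condition_is_design_error(self, conditions3):
        design = ExperimentDesign("ref", ("not_measured",))
        de = de_table({"g1": ("up", "up", "up")}, conditions3)
        with pytest.raises(DesignError):
            classify_paths(de, design)

    def test_path_table_round_trip(self, design3, conditions3):
        rng = np.random.default_rng(3)
        calls = {f"g{i}": tuple(rng.choice(CALLS, 3)) for i in range(30)}
        paths = classify_paths(de_table(calls, conditions3), design3)
        table = path_table(paths)
        assert len(table) == 30
        rebuilt = {
            tuple(label.split("|")): set(group["gene"])
            for label, group in table.groupby("path_label")
        }
        assert rebuilt == {p.label: set(p.genes) for p in paths}


class TestRestorationSets:
    @pytest.mark.parametrize(
        "label, bucket",
        [
            (("unchanged", "up", "unchanged"), "up_restored"),
            (("unchanged", "up", "up"), "up_persistent"),
            (("unchanged", "down", "unchanged"), "down_restored"),
            (("down", "down", "down"), "down_persistent"),
            (("up", "unchanged", "up"), None),       # not injury-responsive
            (("unchanged", "up", "down"), None),     # overshoot: neither
        ],
    )
    def test_projection_rules(self, design3, label, bucket):
        paths = [CoexpressionPath(label=label, genes=frozenset({"g1"}))]
        sets = extract_restoration_sets(paths, design3, "SNL_vehicle", "SNL_C286")
        for name, genes in sets.as_dict().items():
            assert genes == ({"g1"} if name == bucket else frozenset())

    def test_sets_are_unions_of_whole_paths_and_disjoint(self, design3, conditions3):
        rng = np.random.default_rng(23)
        calls = {f"g{i}": tuple(rng.choice(CALLS, 3)) for i in range(200)}
        paths = classify_paths(de_table(calls, conditions3), design3)
        sets = extract_restoration_sets(paths, design3, "SNL_vehicle", "SNL_C286")
        d = sets.as_dict()
        assert d["up_restored"] & d["up_persistent"] == frozenset()
        assert d["down_restored"] & d["down_persistent"] == frozenset()
        path_by_gene = {g: p.label for p in paths for g in p.genes}
        for genes in d.values():
            labels = {path_by_gene[g] for g in genes}
            for p in paths:
                if p.label in labels:
                    assert p.genes <= genes

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        at_injury=st.sampled_from(CALLS),
        at_treated=st.sampled_from(CALLS),
        other1=st.sampled_from(CALLS),
        other2=st.sampled_from(CALLS),
    )
    def test_only_projected_positions_matter(
        self, at_injury, at_treated, other1, other2
    ):
        """Changing the non-projected call never changes the sets."""
        design = ExperimentDesign(
            "NI_vehicle", ("NI_C286", "SNL_vehicle", "SNL_C286")
        )
        a = [CoexpressionPath((other1, at_injury, at_treated), frozenset({"g"}))]
        b = [CoexpressionPath((other2, at_injury, at_treated), frozenset({"g"}))]
        sa = extract_restoration_sets(a, design, "SNL_vehicle", "SNL_C286")
        sb = extract_restoration_sets(b, design, "SNL_vehicle", "SNL_C286")
        assert sa == sb

    def test_unknown_condition_is_design_error(self, design3):
        with pytest.raises(DesignError, match="no_such"):
            extract_restoration_sets([], design3, "no_such", "SNL_C286")

    def test_restoration_table_lists_each_membership(self, design3):
        paths = [
            CoexpressionPath(("unchanged", "up", "unchanged"), frozenset({"g2", "g1"})),
            CoexpressionPath(("unchanged", "down", "down"), frozenset({"g3"})),
        ]
        sets = extract_restoration_sets(paths, design3, "SNL_vehicle", "SNL_C286")
        table = restoration_table(sets)
        assert table.to_dict("records") == [
            {"gene": "g1", "set_name": "up_restored"},
            {"gene": "g2", "set_name": "up_restored"},
            {"gene": "g3", "set_name": "down_persistent"},
        ]
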