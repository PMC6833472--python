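import numpy as np
import pandas as pd
import pytest

from copath import CountDataset, ExperimentDesign, SimulationSpec, simulate_dataset


def make_dataset(counts: dict[str, list[int]], conditions: dict[str, str],
                 genes: list[str] | None = None) -> CountDataset:
    """Small literal dataset: counts maps sample -> column of counts."""
    frame = pd.DataFrame(counts)
    frame.index = genes or [f"g{i + 1}" for i in range(len(frame))]
    replicate: dict[str, int] = {}
    rows = []
    for sample in frame.columns:
        cond = conditions[sample]
        replicate[cond] = replicate.get(cond, 0) + 1
        rows.append({"condition": cond, "replicate": replicate[cond]})
    meta = pd.DataFrame(rows, index=pd.Index(frame.columns, name="sample"))
    return CountDataset(counts=frame, sample_meta=meta)


@pytest.fixture
def three_condition_design() -> ExperimentDesign:
    return ExperimentDesign(
        reference_condition="NI_vehicle",
        path_conditions=("NI_C286", "SNL_vehicle", "SNL_C286"),
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared by the recovery tests."""
    spec = SimulationSpec(seed=11)
    ds, sets, truth = simulate_dataset(spec)
    return spec, ds, sets, truth


@pytest.fixture(scope="session")
def small_sim_spec_kwargs():
    """A desk-scale spec for pipeline-level tests that exercise every stage."""
    return dict(
        n_genes=1200,
        n_terms=30,
        term_size_range=(15, 40),
        seed=5,
    )
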