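import numpy as np
import pandas as pd
import pytest

from igaseq import (
    Cohort,
    CountTable,
    SampleMetadata,
    SimulationConfig,
    TaxonomyTable,
    simulate_cohort,
)


@pytest.fixture
def tiny_counts() -> CountTable:
    return CountTable(pd.DataFrame(
        [[10, 0], [5, 5], [0, 20]],
        index=["t1", "t2", "t3"], columns=["S1", "S2"]))


@pytest.fixture
def tiny_taxonomy() -> TaxonomyTable:
    rows = {
        "t1": ["Bacteria", "Firmicutes", "", "", "", "Dialister", ""],
        "t2": ["Bacteria", "Firmicutes", "", "", "", "Dialister", ""],
        "t3": ["Bacteria", "Bacteroidota", "", "", "", "", ""],
    }
    return TaxonomyTable(pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["kingdom", "phylum", "class", "order", "family", "genus",
                 "species"]))


def make_metadata(subjects, age=2.5, sorted_pairs=True) -> SampleMetadata:
    """Cohort metadata for a list of (subject_id, group) pairs."""
    rows = []
    fractions = ["presort"] + (["igapos", "iganeg"] if sorted_pairs else [])
    for subj, group in subjects:
        for frac in fractions:
            rows.append(dict(sample_id=f"{subj}_{frac}", subject_id=subj,
                             group=group, age=age, fraction=frac))
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture
def small_cohort() -> tuple:
    """Simulated 4v4-subject cohort, 30 taxa, modest depth, with truth."""
    config = SimulationConfig(
        n_taxa=30, seed=42, mean_depth=5000,
        group_sizes={2.5: {"control": 4, "celiac": 4}})
    return simulate_cohort(config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
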