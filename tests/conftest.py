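import numpy as np
import pytest

from lowbiome import OtuTable, SampleRecord, SimConfig, generate_ct_records, generate_dataset


@pytest.fixture
def tiny_table():
    return OtuTable(
        ["t1", "t2", "t3"],
        ["s1", "s2"],
        [[3.0, 0.0], [1.0, 2.0], [5.0, 5.0]],
    )


@pytest.fixture
def tiny_metadata():
    return [
        SampleRecord("s1", "fetal_tissue", organ="gut", fetus_id="F01", ega_weeks=14.0),
        SampleRecord("s2", "pbs", fetus_id="F01"),
    ]


@pytest.fixture(scope="session")
def sim_dataset():
    """One default signal-bearing synthetic dataset, shared across tests."""
    config = SimConfig(seed=42)
    table, meta, taxonomy, tree, truth = generate_dataset(config)
    ct = generate_ct_records(meta, truth, config)
    return {
        "config": config, "table": table, "metadata": meta,
        "taxonomy": taxonomy, "tree": tree, "truth": truth, "ct": ct,
    }


def random_table(rng, n_taxa, n_samples, max_count=50, min_total=1):
    """Random integer OtuTable where every sample has a positive total."""
    while True:
        counts = rng.integers(0, max_count + 1, size=(n_taxa, n_samples))
        if np.all(counts.sum(axis=0) >= min_total):
            return OtuTable(
                [f"t{i}" for i in range(n_taxa)],
                [f"s{j}" for j in range(n_samples)],
                counts.astype(float),
            )
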