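import pandas as pd
import pytest

from mirstab.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A small but fully featured synthetic configuration."""
    return SyntheticConfig(
        n_mirnas=60,
        n_experiments=3000,
        n_genes=120,
        n_cancers=5,
        n_plant_seqs=30,
        n_human_seqs=60,
        n_planted_similar_pairs=5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def toy_records() -> pd.DataFrame:
    """Hand-sized expression records: miR-a 3 down / 1 up, miR-b 5 up."""
    rows = [
        ("miR-a", "brca", "rna_seq", -2.0),
        ("miR-a", "brca", "rna_seq", -0.5),
        ("miR-a", "luad", "qpcr", -1.0),
        ("miR-a", "luad", "qpcr", 0.7),
        ("miR-b", "brca", "rna_seq", 0.3),
        ("miR-b", "brca", "qpcr", 1.2),
        ("miR-b", "luad", "rna_seq", 2.0),
        ("miR-b", "luad", "qpcr", 0.1),
        ("miR-b", "prad", "rna_seq", 0.9),
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "cancer_type", "experiment_type", "logfc"])
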