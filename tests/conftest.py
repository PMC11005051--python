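import numpy as np
import pytest

from hyperqsar.data_model_io import EmbeddingStore, InteractionRecord, InteractionTable
from hyperqsar.synthetic_data import SynthConfig, generate


@pytest.fixture
def tiny_table():
    records = [
        InteractionRecord("d1", "t1", 6.4),
        InteractionRecord("d2", "t1", 6.5),
        InteractionRecord("d1", "t2", 7.1),
        InteractionRecord("d3", "t2", 5.0),
    ]
    return InteractionTable(records, label_kind="continuous")


@pytest.fixture
def small_dataset():
    """10 targets x 12 drugs, dim 6, noiseless."""
    cfg = SynthConfig(n_targets=10, n_drugs=12, d_target=6, d_drug=6, seed=11)
    return generate(cfg)


@pytest.fixture
def medium_dataset():
    """25 targets x 20 drugs, dim 8, light noise — for split/training tests."""
    cfg = SynthConfig(n_targets=25, n_drugs=20, d_target=8, d_drug=8, noise_sd=0.05, seed=5)
    return generate(cfg)


@pytest.fixture
def interactions_file(tmp_path, tiny_table):
    path = tmp_path / "interactions.tsv"
    with open(path, "w") as fh:
        fh.write("drug_id\ttarget_id\tlabel\n")
        for r in tiny_table.records:
            fh.write(f"{r.drug_id}\t{r.target_id}\t{r.label}\n")
    return str(path)


def store_from_matrix(ids, M):
    return EmbeddingStore(M.shape[1], {i: M[k] for k, i in enumerate(ids)})
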