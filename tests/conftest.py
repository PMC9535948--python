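import numpy as np
import pytest

from ensplice.data_io import OneHotBatch, SpliceDataset, SpliceRecord
from ensplice.synthetic import SyntheticConfig, default_motif, generate_dataset


def make_dataset(seqs_pos, seqs_neg, site_type="donor", consensus=(3, 4)):
    records = [SpliceRecord(s, 1, site_type) for s in seqs_pos] + [
        SpliceRecord(s, 0, site_type) for s in seqs_neg
    ]
    return SpliceDataset(
        records=records,
        window_length=len(records[0].sequence),
        consensus_positions=consensus,
        site_type=site_type,
    )


class FixedModel:
    """Duck-typed stand-in whose hard predictions are fixed in advance."""

    def __init__(self, preds, name="stub", window_length=8):
        self.name = name
        self.input_shape = (window_length, 4)
        self.preds = np.asarray(preds)

    def predict_proba(self, x, batch_size=512):
        out = np.zeros((len(self.preds), 2))
        out[np.arange(len(self.preds)), self.preds] = 1.0
        return out


@pytest.fixture
def fixed_model_factory():
    return FixedModel


@pytest.fixture
def dummy_batch():
    def _make(n, length=8):
        return OneHotBatch(tensor=np.zeros((n, length, 4), dtype=np.float32))

    return _make


@pytest.fixture(scope="session")
def separable_donor_dataset():
    """Small strongly separable dataset shared by the slower tests."""
    motif = default_motif("donor", 40, (20, 21), sharpness=1.0)
    cfg = SyntheticConfig(
        n_per_class=250, window_length=40, site_type="donor",
        signal_strength=1.0, seed=7,
    )
    return generate_dataset(cfg, motif)
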