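import numpy as np
import pytest

from obqsar.datamodel import CompoundDataset, CompoundRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(cid, ob, scores=None, desc=None):
    return CompoundRecord(
        compound_id=cid,
        ob_percent=ob,
        binding_scores=scores or {"cyp3a4": 5.0},
        descriptors=desc or {"d1": 0.0, "d2": 1.0},
    )


@pytest.fixture
def tiny_dataset():
    """Three compounds, two descriptors."""
    records = [
        make_record("A", 20.0, {"cyp3a4": 6.0, "pgp": 4.0}, {"d1": 1.0, "d2": 0.0}),
        make_record("B", 50.0, {"cyp3a4": 5.0, "pgp": 7.0}, {"d1": 0.0, "d2": 1.0}),
        make_record("C", 80.0, {"cyp3a4": 4.5, "pgp": 4.5}, {"d1": 1.0, "d2": 1.0}),
    ]
    return CompoundDataset(records=records, descriptor_names=["d1", "d2"])
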