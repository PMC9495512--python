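import numpy as np
import pytest

from msres.dataio import record_from_synthetic
from msres.preprocess import segment_records
from msres.synth import af_spec, generate_record, normal_spec


@pytest.fixture(scope="session")
def record_pair_sets():
    """100 normal and 100 AF records at default generator settings (30 s)."""
    normals = [generate_record(normal_spec(), duration=30.0, seed=10_000 + i)
               for i in range(100)]
    afs = [generate_record(af_spec(), duration=30.0, seed=20_000 + i)
           for i in range(100)]
    return normals, afs


@pytest.fixture(scope="session")
def small_segment_set():
    """A labeled ~350-segment population from 100 default-generator records."""
    from msres.synth import generate_dataset

    recs = generate_dataset(20, 80, seed=11)
    records = [record_from_synthetic(r) for r in recs]
    labels = {r.name: r.label for r in recs}
    return segment_records(records, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
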