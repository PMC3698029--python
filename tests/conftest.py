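import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

from seqfarm import SeqRecord, build_db_image, gen_database
from seqfarm.outstore import StoreConfig, open_store


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_db():
    return gen_database(10, ("fixed", 40), seed=11)


@pytest.fixture
def small_image(small_db):
    return build_db_image(small_db)


@pytest.fixture
def store_factory(tmp_path):
    """Open a fresh store under a unique subdirectory of tmp_path."""
    counter = iter(range(10_000))

    def make(**kw):
        root = tmp_path / f"store-{next(counter)}"
        kw.setdefault("shards", 2)
        kw.setdefault("block_capacity", 4096)
        return open_store(StoreConfig.at(root, **kw))

    return make


def random_records(rng, n, min_len=5, max_len=60, prefix="r"):
    from seqfarm.seqio import AA20

    out = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(AA20[k] for k in rng.integers(0, 20, size=length))
        out.append(SeqRecord(f"{prefix}{i:04d}", seq))
    return out
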