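import numpy as np
import pytest

from dsim.datamodel import GroupContrast, OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def balanced_contrast():
    return GroupContrast(labels=np.r_[np.ones(10, int), 2 * np.ones(10, int)])


def make_matrix(values, role="dependent", prefix="p", sprefix="s"):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return OmicsMatrix(
        values=values,
        probe_ids=[f"{prefix}{i}" for i in range(m)],
        sample_ids=[f"{sprefix}{j}" for j in range(n)],
        role=role,
    )


@pytest.fixture
def tiny_tsv(tmp_path):
    """A 3-probe x 4-sample matrix TSV on disk."""
    path = tmp_path / "mat.tsv"
    path.write_text(
        "probe_id\ts1\ts2\ts3\ts4\n"
        "pA\t1.0\t2.0\t3.0\t4.0\n"
        "pB\t0.5\t-1.5\t2.5\t0.0\n"
        "pC\t10\t20\t30\t40\n"
    )
    return path
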