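import numpy as np
import pytest

from specmeta import MetaDataset, PValue, StudyRecord, load_table1


@pytest.fixture(scope="session")
def table1():
    return load_table1()


def make_record(i, r, n, **kw):
    defaults = dict(
        study_id=f"s{i:03d}", author=f"Author {i}", year=2000, n=n, r=r,
        p_value=PValue(0.5), sample_type="college", pct_men=None,
        religiosity_type="beliefs", intelligence_type="iq",
        publication_status="published",
    )
    defaults.update(kw)
    return StudyRecord(**defaults)


@pytest.fixture
def tiny_dataset():
    """Ten heterogeneous studies with hand-picked effects and sizes."""
    rs = [-0.30, -0.10, 0.05, -0.22, -0.45, 0.00, -0.15, -0.08, -0.35, -0.02]
    ns = [50, 120, 80, 400, 35, 1000, 250, 60, 90, 150]
    return MetaDataset([make_record(i, r, n) for i, (r, n) in enumerate(zip(rs, ns))],
                       "tiny")
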