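import random

import pytest

from gobymine.io import HspRecord


def make_hsp(
    query_id="q1",
    subject_id="ctg1",
    pct_identity=90.0,
    q_start=1,
    q_end=100,
    s_start=1001,
    s_end=1300,
    evalue=1e-60,
    bit_score=200.0,
):
    return HspRecord(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=pct_identity,
        aln_len=q_end - q_start + 1,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=evalue,
        bit_score=bit_score,
    )


@pytest.fixture
def rng():
    return random.Random(20260921)
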