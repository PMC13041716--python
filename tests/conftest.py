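import numpy as np
import pytest

from triggerscan.io import MiRNA, ScoringParams, TranscriptRegion

#: let-7a-like guide used throughout as a realistic 22-nt miRNA
LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


@pytest.fixture
def params():
    return ScoringParams()


@pytest.fixture
def mirna():
    return MiRNA("miR-let7", LET7, family_id="let-7")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


def make_region(seq, tid="tx1", **kw):
    return TranscriptRegion(transcript_id=tid, sequence=seq, **kw)
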