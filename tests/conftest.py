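import pytest

from scrkit import build_topology, isoform_sequences
from scrkit.simulate import sim_transcript


@pytest.fixture(scope="session")
def mtch2_like_transcript():
    """Synthetic transcript planted with the MTCH2 stop-codon geometry:
    ISR1 = 30 nt and ISR2 = 72 nt, i.e. downstream in-frame stops at
    offsets 30 and 105 nt after the canonical UGA."""
    return sim_transcript(seed=11, cds_codons=100, isr1_len=30, isr2_len=72, utr_len=300)


@pytest.fixture(scope="session")
def mtch2_like_topology(mtch2_like_transcript):
    return build_topology(mtch2_like_transcript)


@pytest.fixture(scope="session")
def mtch2_like_isoforms(mtch2_like_transcript, mtch2_like_topology):
    return isoform_sequences(mtch2_like_transcript, mtch2_like_topology)
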