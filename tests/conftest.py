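import numpy as np
import pytest

from mintron.annotation import GenomeSequence, TranscriptModel
from mintron.pwm import PwmSet
from mintron.simulate import SimConfig, simulate_genome_annotation, simulate_ppms


@pytest.fixture(scope="session")
def ppms():
    return simulate_ppms(seed=0, information_content=1.8)


@pytest.fixture(scope="session")
def pwms(ppms):
    return PwmSet.from_ppms(ppms)


@pytest.fixture(scope="session")
def sim():
    """One 50-gene simulated genome shared by read-level tests."""
    return simulate_genome_annotation(SimConfig(seed=11))


def make_transcript(
    exons, strand="+", transcript_id="T1", gene_id="G1", chrom="chr1", cds_span=None, tags=()
):
    tx = TranscriptModel(transcript_id, gene_id, chrom, strand)
    tx.exons = list(exons)
    tx.cds_span = cds_span
    tx.tags = set(tags)
    tx.finalize()
    return tx


def make_genome(length=5000, seed=0, chrom="chr1"):
    rng = np.random.default_rng(seed)
    return GenomeSequence({chrom: "".join(rng.choice(list("ACGT"), size=length))})
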