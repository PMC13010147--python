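import pytest

from ncorfkit import GenomicInterval, OrfRecord, PsiteTrack, TranscriptModel
from ncorfkit.simulate import SimulationConfig, simulate_annotation


def make_transcript(exons, strand="+", cds=(), tid="t", gid="g",
                    gene_biotype="protein_coding",
                    transcript_biotype="protein_coding", chrom="chr1", **tags):
    return TranscriptModel(
        transcript_id=tid, gene_id=gid, gene_biotype=gene_biotype,
        transcript_biotype=transcript_biotype,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        cds_blocks=[GenomicInterval(chrom, s, e, strand) for s, e in cds],
        **tags,
    )


def make_orf(blocks, strand="+", orf_id="orf", chrom="chr1", **kwargs):
    return OrfRecord(
        orf_id=orf_id,
        blocks=[GenomicInterval(chrom, s, e, strand) for s, e in blocks],
        strand=strand, **kwargs,
    )


def make_track(counts, dataset_id="ds", chrom="chr1", strand="+"):
    """Track from {position: count} (single chrom/strand) or
    {(chrom, strand, pos): count}."""
    track = PsiteTrack(dataset_id)
    for key, n in counts.items():
        if isinstance(key, tuple):
            c, s, p = key
        else:
            c, s, p = chrom, strand, key
        track.add(c, s, p, n)
    return track


@pytest.fixture
def two_exon_plus():
    """Two-exon plus-strand transcript: exons (0,100) and (200,300)."""
    return make_transcript([(0, 100), (200, 300)])


@pytest.fixture
def two_exon_minus():
    return make_transcript([(0, 100), (200, 300)], strand="-")


@pytest.fixture(scope="session")
def sim_default():
    return simulate_annotation(SimulationConfig(seed=7))
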