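"""Splice-aware genome <-> transcript mapping and codon/frame algebra.

Transcript offsets are 0-based along the spliced transcript, 5'->3'; on the
minus strand offset 0 is the 3'-most genomic base of the first exon in
transcription order.  Reading frame is anchored at an ORF's start codon and
extends in phase beyond the ORF in both directions, which is what allows
in-frame counting inside the stop-codon flanking windows.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation_io import OrfRecord, TranscriptModel

__all__ = [
    "TranscriptPosition",
    "TranscriptInterval",
    "CodonAddress",
    "genome_to_transcript",
    "transcript_to_genome",
    "orf_codons",
    "orf_transcript_span",
    "frame_of",
    "stop_flank_windows",
]


@dataclass(frozen=True)
class TranscriptPosition:
    transcript_id: str
    offset: int


@dataclass(frozen=True)
class TranscriptInterval:
    """Half-open interval in spliced-transcript coordinates."""

    transcript_id: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CodonAddress:
    """One codon of an ORF: its index and 3 genomic positions in translation order."""

    index: int
    genomic_positions: tuple[int, int, int]


def genome_to_transcript(t: TranscriptModel, g: int) -> TranscriptPosition | None:
    """Map a genomic position to its spliced offset, or None if intronic/outside."""
    acc = 0
    for e in t.exons_tx_order():
        if e.start <= g < e.end:
            within = (g - e.start) if t.strand == "+" else (e.end - 1 - g)
            return TranscriptPosition(t.transcript_id, acc + within)
        acc += len(e)
    return None


def transcript_to_genome(t: TranscriptModel, offset: int) -> int:
    """Inverse of :func:`genome_to_transcript` for valid offsets."""
    if not (0 <= offset < t.spliced_length):
        raise ValueError(
            f"{t.transcript_id}: offset {offset} outside spliced length "
            f"{t.spliced_length}"
        )
    acc = 0
    for e in t.exons_tx_order():
        if offset < acc + len(e):
            within = offset - acc
            return (e.start + within) if t.strand == "+" else (e.end - 1 - within)
        acc += len(e)
    raise AssertionError("unreachable")


def orf_codons(orf: OrfRecord) -> list[CodonAddress]:
    """Tile the ORF (stop codon included) into codons of 3 genomic positions.

    A codon may span a splice junction, in which case its positions come
    from two blocks.
    """
    pos = orf.positions()
    return [
        CodonAddress(i // 3, (pos[i], pos[i + 1], pos[i + 2]))
        for i in range(0, len(pos), 3)
    ]


def orf_transcript_span(orf: OrfRecord, t: TranscriptModel) -> TranscriptInterval:
    """The ORF's half-open span in spliced coordinates of its host transcript."""
    pos = orf.positions()
    first = genome_to_transcript(t, pos[0])
    last = genome_to_transcript(t, pos[-1])
    if first is None or last is None:
        raise ValueError(
            f"{orf.orf_id}: not contained in transcript {t.transcript_id}"
        )
    return TranscriptInterval(t.transcript_id, first.offset, last.offset + 1)


def frame_of(orf: OrfRecord, t: TranscriptModel, g: int) -> int | None:
    """Reading frame (0/1/2) of a genomic position relative to the ORF start.

    Defined for any exonic position of the host transcript, including
    positions 5' or 3' of the ORF span (phase extension); returns None for
    positions not on the transcript.
    """
    p = genome_to_transcript(t, g)
    if p is None:
        return None
    start = genome_to_transcript(t, orf.positions()[0])
    if start is None:
        raise ValueError(
            f"{orf.orf_id}: start not on transcript {t.transcript_id}"
        )
    return (p.offset - start.offset) % 3


def stop_flank_windows(
    orf: OrfRecord, t: TranscriptModel, w: int = 15
) -> tuple[TranscriptInterval, TranscriptInterval]:
    """Transcript windows of up to ``w`` nt flanking the stop codon.

    ``before`` ends at the first base of the stop codon; ``after`` begins at
    the base following its last base.  The stop codon belongs to neither.
    Windows are defined on the transcript (the before window may extend 5'
    of a very short ORF's start codon) and truncate at transcript ends.
    """
    pos = orf.positions()
    stop_first = genome_to_transcript(t, pos[-3])
    stop_last = genome_to_transcript(t, pos[-1])
    if stop_first is None or stop_last is None:
        raise ValueError(
            f"{orf.orf_id}: stop codon not on transcript {t.transcript_id}"
        )
    before = TranscriptInterval(
        t.transcript_id, max(0, stop_first.offset - w), stop_first.offset
    )
    after = TranscriptInterval(
        t.transcript_id,
        stop_last.offset + 1,
        min(t.spliced_length, stop_last.offset + 1 + w),
    )
    return before, after
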