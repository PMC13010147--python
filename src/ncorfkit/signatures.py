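"""Per-ORF translation-signature metrics.

Three metrics summarize how closely an ORF's P-site profile resembles
active translation:

* PIF (P-sites in frame): fraction of the ORF body's P-sites on frame 0.
* Uniformity: fraction of codons whose own P-sites are >1/3 on frame 0 —
  rewards periodic signal throughout the ORF, not just one read stack.
* Drop-off: in-frame P-sites in the 15-nt transcript window before the stop
  codon over in-frame P-sites in the windows before plus after it —
  rewards sharp termination.

By default the ORF body for PIF/Uniformity is the sense codons only (stop
codon excluded — terminating-ribosome pileups belong to the Drop-off
windows, not the body); ``include_stop`` switches this.  A metric is
missing (None) exactly when its defining denominator is zero, and missing
scores always fail thresholds downstream.

PPM (P-sites per million) is the length-normalized P-site density of an
ORF scaled so densities over the evaluated ORF universe sum to one
million; it depends on the universe composition, which callers therefore
record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation_io import OrfRecord, TranscriptModel, ValidationError
from .coordinates import (
    TranscriptInterval,
    genome_to_transcript,
    orf_transcript_span,
)
from .psite_tracks import PsiteTrack, PsiteVector, project

__all__ = [
    "SignatureScores",
    "PeriodicityReport",
    "compute_pif",
    "compute_uniformity",
    "compute_dropoff",
    "compute_ppm",
    "score_orf",
    "score_transcript_cds",
    "periodicity_qc",
    "profile_dump",
]


@dataclass
class SignatureScores:
    """Scores of one ORF against one dataset; None marks a missing score."""

    orf_id: str
    dataset_id: str
    pif: float | None = None
    uniformity: float | None = None
    dropoff: float | None = None
    ppm: float | None = None
    n_psites: int = 0


@dataclass
class PeriodicityReport:
    """Per-read-length in-frame fraction over annotated CDS bodies."""

    dataset_id: str
    fractions: dict[int, float | None] = field(default_factory=dict)
    selected: dict[int, bool] = field(default_factory=dict)


def compute_pif(orf_body: PsiteVector) -> float | None:
    """Fraction of body P-sites on frame 0; the body vector is phased so
    that index 0 is the first base of a codon."""
    total = orf_body.total
    if total == 0:
        return None
    return float(orf_body.values[0::3].sum()) / total


def compute_uniformity(orf_body: PsiteVector) -> float | None:
    """Fraction of codons with >1/3 of their own P-sites on frame 0.

    Zero-count codons fail (no evidence); missing only when the whole body
    has zero counts.
    """
    if len(orf_body.values) % 3 != 0:
        raise ValidationError("ORF body length not a multiple of 3")
    if orf_body.total == 0:
        return None
    codons = np.asarray(orf_body.values).reshape(-1, 3)
    totals = codons.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac0 = np.where(totals > 0, codons[:, 0] / np.maximum(totals, 1), 0.0)
    passing = (totals > 0) & (frac0 > 1.0 / 3.0)
    return float(passing.sum()) / len(codons)


def compute_dropoff(
    before: PsiteVector,
    after: PsiteVector,
    before_first_frame: int,
    after_first_frame: int,
) -> float | None:
    """B / (B + A) over frame-0 positions of the stop-flanking windows.

    ``*_first_frame`` give the reading frame (relative to the ORF start)
    of each window's first base, so in-frame positions can be selected
    inside windows that were truncated at transcript ends.
    """
    def inframe(vec: PsiteVector, first_frame: int) -> int:
        if len(vec.values) == 0:
            return 0
        offset = (-first_frame) % 3
        return int(np.asarray(vec.values)[offset::3].sum())

    b = inframe(before, before_first_frame)
    a = inframe(after, after_first_frame)
    if b + a == 0:
        return None
    return b / (b + a)


def compute_ppm(universe: list[tuple[str, int, int]]) -> dict[str, float]:
    """Map orf_id -> PPM for a universe of (orf_id, n_psites, body length nt).

    density_i = n_psites_i / length_i; ppm_i = 1e6 * density_i / sum(density).
    An all-zero universe yields all-zero PPM.
    """
    if not universe:
        raise ValidationError("compute_ppm: empty universe")
    densities = {}
    for orf_id, n, length in universe:
        if length <= 0:
            raise ValidationError(f"compute_ppm: non-positive length for {orf_id}")
        densities[orf_id] = n / length
    total = sum(densities.values())
    if total == 0:
        return {k: 0.0 for k in densities}
    return {k: 1e6 * d / total for k, d in densities.items()}


def _score_region(
    t: TranscriptModel,
    track: PsiteTrack,
    body_start: int,
    body_end: int,
    window: int,
    include_stop: bool,
    orf_id: str,
    dataset_id: str,
) -> SignatureScores:
    """Score a translated region of a transcript.

    The sense codons occupy transcript offsets [body_start, body_end); the
    stop codon occupies the following 3 nt (possibly truncated at the
    transcript 3' end).
    """
    L = t.spliced_length
    pif_end = body_end
    if include_stop:
        pif_end = min(L, body_end + 3)
        if (pif_end - body_start) % 3 != 0:
            pif_end = body_end
    body = project(track, t, TranscriptInterval(t.transcript_id, body_start, pif_end))
    pif = compute_pif(body)
    uniformity = compute_uniformity(body)

    stop_end = min(L, body_end + 3)
    before_iv = TranscriptInterval(
        t.transcript_id, max(0, body_end - window), body_end
    )
    after_iv = TranscriptInterval(
        t.transcript_id, stop_end, min(L, stop_end + window)
    )
    before = project(track, t, before_iv)
    after = project(track, t, after_iv)
    dropoff = compute_dropoff(
        before,
        after,
        (before_iv.start - body_start) % 3,
        (after_iv.start - body_start) % 3,
    )
    n_psites = project(
        track, t, TranscriptInterval(t.transcript_id, body_start, body_end)
    ).total
    return SignatureScores(
        orf_id=orf_id,
        dataset_id=dataset_id,
        pif=pif,
        uniformity=uniformity,
        dropoff=dropoff,
        n_psites=n_psites,
    )


def score_orf(
    orf: OrfRecord,
    host: TranscriptModel,
    track: PsiteTrack,
    window: int = 15,
    include_stop: bool = False,
) -> SignatureScores:
    """Compute PIF, Uniformity, Drop-off and the body P-site count for one ORF.

    PPM is not computed here: it needs the whole ORF universe
    (:func:`compute_ppm`).
    """
    span = orf_transcript_span(orf, host)
    return _score_region(
        host,
        track,
        span.start,
        span.end - 3,
        window,
        include_stop,
        orf.orf_id,
        track.dataset_id,
    )


def score_transcript_cds(
    t: TranscriptModel,
    track: PsiteTrack,
    window: int = 15,
    include_stop: bool = False,
) -> SignatureScores:
    """Score a transcript's annotated CDS the same way an ORF is scored.

    The GTF CDS excludes the stop codon, which occupies the 3 transcript nt
    after the CDS end; used for threshold calibration and the PPM universe.
    """
    if not t.cds_blocks:
        raise ValidationError(f"{t.transcript_id}: no CDS to score")
    first = t.cds_tx_order()[0]
    g_first = first.start if t.strand == "+" else first.end - 1
    start = genome_to_transcript(t, g_first).offset
    return _score_region(
        t,
        track,
        start,
        start + t.cds_length,
        window,
        include_stop,
        t.transcript_id,
        track.dataset_id,
    )


def periodicity_qc(
    tracks: dict[int, PsiteTrack] | list[PsiteTrack],
    cds_transcripts: list[TranscriptModel],
    min_fraction: float = 0.60,
) -> PeriodicityReport:
    """In-frame fraction per read length over annotated CDS bodies.

    A read length is selected when its frame-0 fraction, aggregated over
    all provided CDS bodies in CDS phase, exceeds ``min_fraction``.  Tracks
    may be given as a mapping read length -> track or as a list whose
    dataset_ids end in ``_len{N}``.
    """
    if isinstance(tracks, list):
        parsed = {}
        for tr in tracks:
            head, _, tail = tr.dataset_id.rpartition("_len")
            if not head or not tail.isdigit():
                raise ValidationError(
                    f"track id {tr.dataset_id!r} lacks a _len{{N}} suffix"
                )
            parsed[int(tail)] = tr
        tracks = parsed
    if not tracks:
        raise ValidationError("periodicity_qc: no tracks")
    cds_transcripts = [t for t in cds_transcripts if t.cds_blocks]
    if not cds_transcripts:
        raise ValidationError("periodicity_qc: no transcripts with CDS")

    base_id = next(iter(tracks.values())).dataset_id
    report = PeriodicityReport(dataset_id=base_id.rpartition("_len")[0] or base_id)
    for length, tr in sorted(tracks.items()):
        frame0 = total = 0
        for t in cds_transcripts:
            first = t.cds_tx_order()[0]
            g_first = first.start if t.strand == "+" else first.end - 1
            start = genome_to_transcript(t, g_first).offset
            body = project(
                tr, t, TranscriptInterval(t.transcript_id, start, start + t.cds_length)
            )
            frame0 += int(np.asarray(body.values)[0::3].sum())
            total += body.total
        frac = frame0 / total if total > 0 else None
        report.fractions[length] = frac
        report.selected[length] = frac is not None and frac > min_fraction
    return report


def profile_dump(
    orf: OrfRecord, host: TranscriptModel, track: PsiteTrack, window: int = 15
):
    """Per-base (transcript offset, frame, count) rows over the ORF and its
    stop flanks, for plotting."""
    import pandas as pd

    span = orf_transcript_span(orf, host)
    lo = max(0, span.start - window)
    hi = min(host.spliced_length, span.end + window)
    vec = project(track, host, TranscriptInterval(host.transcript_id, lo, hi))
    rows = [
        {
            "transcript_id": host.transcript_id,
            "offset": off,
            "frame": (off - span.start) % 3,
            "count": int(vec.values[i]),
        }
        for i, off in enumerate(range(lo, hi))
    ]
    return pd.DataFrame(rows)
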