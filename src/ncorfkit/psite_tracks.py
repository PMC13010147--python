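"""Strand-specific per-base P-site count tracks.

P-sites are single-base events, already offset-corrected upstream; tracks
are sparse mappings (chrom, strand, position) -> count, poolable across
samples, and projectable onto spliced transcript intervals.  Reads on the
opposite strand of a transcript are invisible to that transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import ParseError, TranscriptModel, ValidationError
from .coordinates import TranscriptInterval, transcript_to_genome

__all__ = [
    "PsiteTrack",
    "PsiteVector",
    "read_bedgraph_pair",
    "write_bedgraph_pair",
    "pool_tracks",
    "project",
    "library_size",
]


@dataclass
class PsiteTrack:
    """Sparse per-base P-site counts keyed by (chrom, strand) then position."""

    dataset_id: str
    counts: dict[tuple[str, str], dict[int, int]] = field(default_factory=dict)

    def get(self, chrom: str, strand: str, pos: int) -> int:
        return self.counts.get((chrom, strand), {}).get(pos, 0)

    def add(self, chrom: str, strand: str, pos: int, n: int) -> None:
        if n < 0:
            raise ValidationError(f"negative count at {chrom}:{pos}({strand})")
        if n == 0:
            return
        self.counts.setdefault((chrom, strand), {})
        self.counts[(chrom, strand)][pos] = (
            self.counts[(chrom, strand)].get(pos, 0) + n
        )


@dataclass
class PsiteVector:
    """Dense per-nucleotide counts along one transcript interval, 5'->3'."""

    values: np.ndarray
    origin: TranscriptInterval

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if len(self.values) != len(self.origin):
            raise ValidationError("vector length != interval length")

    @property
    def total(self) -> int:
        return int(self.values.sum())


def _read_bedgraph(path, strand: str, track: PsiteTrack) -> None:
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return
    for row in df.itertuples(index=False):
        val = float(row.value)
        if val < 0:
            raise ValidationError(
                f"{path}: negative value at {row.chrom}:{row.start}-{row.end}"
            )
        rounded = round(val)
        if abs(val - rounded) > 1e-6:
            raise ParseError(
                f"{path}: non-integer count {val} at "
                f"{row.chrom}:{row.start}-{row.end}"
            )
        if rounded == 0:
            continue
        per_chrom = track.counts.setdefault((row.chrom, strand), {})
        for pos in range(int(row.start), int(row.end)):
            if pos in per_chrom:
                raise ValidationError(
                    f"{path}: overlapping spans at {row.chrom}:{pos}({strand})"
                )
            per_chrom[pos] = int(rounded)


def read_bedgraph_pair(plus_path, minus_path, dataset_id: str) -> PsiteTrack:
    """Load a strand pair of bedGraph files (0-based half-open spans)."""
    track = PsiteTrack(dataset_id)
    _read_bedgraph(plus_path, "+", track)
    _read_bedgraph(minus_path, "-", track)
    return track


def write_bedgraph_pair(track: PsiteTrack, plus_path, minus_path) -> None:
    """Write a track as one bedGraph per strand, merging adjacent equal counts."""
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path, "w") as fh:
            for (chrom, s), per_pos in sorted(track.counts.items()):
                if s != strand:
                    continue
                run_start = run_end = run_val = None
                for pos in sorted(per_pos):
                    val = per_pos[pos]
                    if run_val == val and pos == run_end:
                        run_end = pos + 1
                        continue
                    if run_val is not None:
                        fh.write(f"{chrom}\t{run_start}\t{run_end}\t{run_val}\n")
                    run_start, run_end, run_val = pos, pos + 1, val
                if run_val is not None:
                    fh.write(f"{chrom}\t{run_start}\t{run_end}\t{run_val}\n")


def pool_tracks(tracks: list[PsiteTrack], dataset_id: str = "pooled") -> PsiteTrack:
    """Positionwise sum of one or more tracks."""
    if not tracks:
        raise ValidationError("pool_tracks requires at least one track")
    pooled = PsiteTrack(dataset_id)
    for tr in tracks:
        for key, per_pos in tr.counts.items():
            dest = pooled.counts.setdefault(key, {})
            for pos, n in per_pos.items():
                dest[pos] = dest.get(pos, 0) + n
    return pooled


def project(
    track: PsiteTrack, t: TranscriptModel, interval: TranscriptInterval
) -> PsiteVector:
    """Dense counts over a transcript interval, strand-matched to the transcript."""
    if interval.start < 0 or interval.end > t.spliced_length:
        raise ValueError(
            f"interval {interval.start}-{interval.end} outside transcript "
            f"{t.transcript_id}"
        )
    per_pos = track.counts.get((t.chrom, t.strand), {})
    values = np.zeros(len(interval), dtype=np.int64)
    for i, off in enumerate(range(interval.start, interval.end)):
        g = transcript_to_genome(t, off)
        n = per_pos.get(g)
        if n:
            values[i] = n
    return PsiteVector(values, interval)


def library_size(track: PsiteTrack) -> int:
    """Total P-site count across the whole track."""
    return sum(sum(d.values()) for d in track.counts.values())
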