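"""Readers and writers for the standard formats the pipeline touches.

GTF (Ensembl attribute dialect), BED12 candidate-ORF files with an optional
metadata TSV, and the final catalog TSV/BED12 pair.  All coordinates are
0-based half-open internally; GTF's 1-based closed convention is converted
at this boundary and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd
from gffutils.feature import feature_from_line

__all__ = [
    "ParseError",
    "ValidationError",
    "GenomicInterval",
    "TranscriptModel",
    "OrfRecord",
    "ORF_TYPES",
    "read_annotation",
    "write_annotation",
    "read_orfs",
    "write_orfs",
    "read_fasta",
    "verify_start_codons",
    "write_catalog",
    "read_catalog",
    "MISSING_TOKEN",
]

MISSING_TOKEN = "NA"

#: the seven ORF classes relative to a host transcript
ORF_TYPES = ("uORF", "uoORF", "intORF", "dORF", "doORF", "lncRNA-ORF", "PT-ORF")

#: Ensembl APPRIS tags as a rank; lower is better, absent ranks worst.
APPRIS_RANKS = {
    "appris_principal_1": 1,
    "appris_principal_2": 2,
    "appris_principal_3": 3,
    "appris_principal_4": 4,
    "appris_principal_5": 5,
    "appris_alternative_1": 6,
    "appris_alternative_2": 7,
}
_APPRIS_TAGS = {v: k for k, v in APPRIS_RANKS.items()}


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def _normalize_gene_biotype(raw: str) -> str:
    if raw == "protein_coding":
        return "protein_coding"
    if raw in ("lncRNA", "lincRNA"):
        return "lncRNA"
    if "pseudogene" in raw:
        return "pseudogene"
    return "other"


@dataclass
class TranscriptModel:
    """A spliced transcript: exons, optional CDS, biotype and priority tags.

    Exons are stored sorted by genomic start; transcription order is the
    reverse of that on the minus strand.  The frame of every CDS base is
    derivable from ``cds_blocks`` (phase 0 at the CDS 5' end).
    """

    transcript_id: str
    gene_id: str
    gene_biotype: str
    transcript_biotype: str
    exons: list[GenomicInterval]
    cds_blocks: list[GenomicInterval] = field(default_factory=list)
    mane_select: bool = False
    appris_rank: int | None = None
    tsl: int | None = None
    readthrough: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        self.cds_blocks = sorted(self.cds_blocks, key=lambda e: e.start)
        chrom, strand = self.exons[0].chrom, self.exons[0].strand
        for blk in list(self.exons) + list(self.cds_blocks):
            if blk.chrom != chrom or blk.strand != strand:
                raise ValidationError(
                    f"{self.transcript_id}: blocks on mixed chrom/strand"
                )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        for c in self.cds_blocks:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValidationError(
                    f"{self.transcript_id}: CDS block {c.start}-{c.end} "
                    f"outside exons"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds_blocks)

    def exons_tx_order(self) -> list[GenomicInterval]:
        """Exons in transcription (5'->3') order."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def cds_tx_order(self) -> list[GenomicInterval]:
        return (
            self.cds_blocks
            if self.strand == "+"
            else list(reversed(self.cds_blocks))
        )


@dataclass
class OrfRecord:
    """A candidate ORF as ordered genomic blocks on one strand.

    Blocks are stored in transcription order and include the stop codon as
    the final 3 nt; total length is a multiple of 3 and at least 6 nt (a
    minimal start-stop ORF has 2 codons).
    """

    orf_id: str
    blocks: list[GenomicInterval]
    strand: str
    start_codon: str = "ATG"
    source_datasets: set[str] = field(default_factory=set)
    legacy_name: str | None = None
    host_transcript: str | None = None
    orf_type: str | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValidationError(f"{self.orf_id}: no blocks")
        chrom = self.blocks[0].chrom
        for b in self.blocks:
            if b.chrom != chrom or b.strand != self.strand:
                raise ValidationError(f"{self.orf_id}: blocks on mixed chrom/strand")
        # keep blocks in transcription order
        key = lambda b: b.start if self.strand == "+" else -b.start
        self.blocks = sorted(self.blocks, key=key)
        length = self.length_nt
        if length % 3 != 0:
            raise ValidationError(
                f"{self.orf_id}: length {length} not divisible by 3"
            )
        if self.n_codons < 2:
            raise ValidationError(f"{self.orf_id}: fewer than 2 codons")
        if self.orf_type is not None and self.orf_type not in ORF_TYPES:
            raise ValidationError(f"{self.orf_id}: unknown type {self.orf_type}")

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def length_nt(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def n_codons(self) -> int:
        return self.length_nt // 3

    @property
    def genomic_start(self) -> int:
        return min(b.start for b in self.blocks)

    @property
    def genomic_end(self) -> int:
        return max(b.end for b in self.blocks)

    def positions(self) -> list[int]:
        """Genomic positions of every ORF base in translation order."""
        out: list[int] = []
        for b in self.blocks:
            rng = range(b.start, b.end)
            out.extend(rng if self.strand == "+" else reversed(rng))
        return out

    def identity_key(self) -> tuple:
        """Genomic identity used for duplicate collapsing."""
        blocks = tuple(sorted((b.start, b.end) for b in self.blocks))
        return (self.chrom, self.strand, blocks)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _attr(feat, key: str) -> str | None:
    vals = feat.attributes.get(key)
    return vals[0] if vals else None


def read_annotation(path) -> list[TranscriptModel]:
    """Parse an Ensembl-dialect GTF into :class:`TranscriptModel` objects.

    Recognized attributes: ``gene_biotype``, ``transcript_biotype``,
    ``transcript_support_level`` and ``tag`` values ``MANE_Select``,
    ``readthrough_transcript`` and the APPRIS principal/alternative tags.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise ParseError(f"{path}: malformed GTF line {lineno}")
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise ParseError(
                    f"{path}: malformed GTF line {lineno}: {exc}"
                ) from exc
            if feat.featuretype not in ("transcript", "exon", "CDS"):
                continue
            tid = _attr(feat, "transcript_id")
            if tid is None:
                raise ParseError(
                    f"{path}: line {lineno}: missing transcript_id"
                )
            if tid not in meta:
                order.append(tid)
                meta[tid] = {}
            if feat.strand not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: missing strand")
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            if feat.featuretype == "exon":
                exons.setdefault(tid, []).append(iv)
            elif feat.featuretype == "CDS":
                cds.setdefault(tid, []).append(iv)
            if feat.featuretype == "transcript" or not meta[tid]:
                tags = feat.attributes.get("tag", [])
                tsl_raw = _attr(feat, "transcript_support_level")
                tsl = None
                if tsl_raw:
                    tsl_tok = tsl_raw.split()[0]
                    if tsl_tok.isdigit():
                        tsl = int(tsl_tok)
                appris = min(
                    (APPRIS_RANKS[t] for t in tags if t in APPRIS_RANKS),
                    default=None,
                )
                meta[tid].update(
                    gene_id=_attr(feat, "gene_id") or "",
                    gene_biotype=_normalize_gene_biotype(
                        _attr(feat, "gene_biotype") or ""
                    ),
                    transcript_biotype=_attr(feat, "transcript_biotype") or "",
                    mane_select="MANE_Select" in tags,
                    readthrough="readthrough_transcript" in tags,
                    appris_rank=appris,
                    tsl=tsl,
                )

    models = []
    for tid in order:
        if tid not in exons:
            raise ValidationError(f"{path}: transcript {tid} has no exons")
        try:
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    exons=exons[tid],
                    cds_blocks=cds.get(tid, []),
                    **meta[tid],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return models


def write_annotation(transcripts: list[TranscriptModel], path) -> None:
    """Write transcripts back out as Ensembl-dialect GTF."""

    def attrs(t: TranscriptModel) -> str:
        parts = [
            f'gene_id "{t.gene_id}"',
            f'transcript_id "{t.transcript_id}"',
            f'gene_biotype "{t.gene_biotype}"',
            f'transcript_biotype "{t.transcript_biotype}"',
        ]
        if t.tsl is not None:
            parts.append(f'transcript_support_level "{t.tsl}"')
        if t.mane_select:
            parts.append('tag "MANE_Select"')
        if t.readthrough:
            parts.append('tag "readthrough_transcript"')
        if t.appris_rank is not None and t.appris_rank in _APPRIS_TAGS:
            parts.append(f'tag "{_APPRIS_TAGS[t.appris_rank]}"')
        return "; ".join(parts) + ";"

    with open(path, "w") as fh:
        for t in transcripts:
            a = attrs(t)
            span = (t.exons[0].start + 1, t.exons[-1].end)
            fh.write(
                f"{t.chrom}\tncorfkit\ttranscript\t{span[0]}\t{span[1]}\t.\t"
                f"{t.strand}\t.\t{a}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\tncorfkit\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{a}\n"
                )
            for c in t.cds_blocks:
                fh.write(
                    f"{t.chrom}\tncorfkit\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{t.strand}\t0\t{a}\n"
                )


# ---------------------------------------------------------------------------
# BED12 ORFs
# ---------------------------------------------------------------------------

_BED12_COLS = [
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
    "blockStarts",
]


def read_orfs(path, meta: object = None) -> list[OrfRecord]:
    """Read candidate ORFs from BED12, optionally joining a metadata TSV.

    Blocks include the stop codon; thickStart/thickEnd are ignored.  The
    metadata TSV is joined on ``name`` and may provide ``source_datasets``
    (comma-separated), ``start_codon`` and ``legacy_name`` columns.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=_BED12_COLS, comment="#",
        dtype={"chrom": str, "name": str},
    )
    meta_df = None
    if meta is not None:
        meta_df = pd.read_csv(meta, sep="\t", dtype=str).set_index("name")

    records, bad = [], []
    for row in df.itertuples(index=False):
        sizes = [int(s) for s in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(s) for s in str(row.blockStarts).rstrip(",").split(",")]
        if len(sizes) != int(row.blockCount) or len(starts) != int(row.blockCount):
            raise ParseError(f"{path}: ORF {row.name}: inconsistent block fields")
        blocks = [
            GenomicInterval(
                row.chrom, row.chromStart + st, row.chromStart + st + sz,
                row.strand,
            )
            for st, sz in zip(starts, sizes)
        ]
        kwargs: dict = {}
        if meta_df is not None and row.name in meta_df.index:
            m = meta_df.loc[row.name]
            if pd.notna(m.get("source_datasets")):
                kwargs["source_datasets"] = set(
                    str(m["source_datasets"]).split(",")
                )
            if pd.notna(m.get("start_codon")):
                kwargs["start_codon"] = str(m["start_codon"])
            if pd.notna(m.get("legacy_name")):
                kwargs["legacy_name"] = str(m["legacy_name"])
        try:
            records.append(
                OrfRecord(
                    orf_id=str(row.name), blocks=blocks, strand=row.strand,
                    **kwargs,
                )
            )
        except ValidationError:
            bad.append(str(row.name))
    if bad:
        raise ValidationError(
            f"{path}: invalid ORF records (length not a positive multiple "
            f"of 3 codons): {', '.join(bad)}"
        )
    return records


def write_orfs(orfs: list[OrfRecord], path) -> None:
    """Write ORFs as BED12 (blocks include the stop codon)."""
    with open(path, "w") as fh:
        for o in orfs:
            blocks = sorted(o.blocks, key=lambda b: b.start)
            start, end = blocks[0].start, blocks[-1].end
            sizes = ",".join(str(len(b)) for b in blocks)
            starts = ",".join(str(b.start - start) for b in blocks)
            fh.write(
                f"{o.chrom}\t{start}\t{end}\t{o.orf_id}\t0\t{o.strand}\t"
                f"{start}\t{end}\t0\t{len(blocks)}\t{sizes}\t{starts}\n"
            )


def write_orf_metadata(orfs: list[OrfRecord], path) -> None:
    """Companion metadata TSV for :func:`read_orfs`."""
    rows = [
        {
            "name": o.orf_id,
            "source_datasets": ",".join(sorted(o.source_datasets)) or MISSING_TOKEN,
            "start_codon": o.start_codon,
            "legacy_name": o.legacy_name or MISSING_TOKEN,
        }
        for o in orfs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA (optional start-codon verification)
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def verify_start_codons(orfs: list[OrfRecord], genome: dict[str, str]) -> list[str]:
    """Return ids of ORFs whose genomic first codon != their declared start codon."""
    mismatched = []
    for o in orfs:
        first = o.positions()[:3]
        bases = "".join(genome[o.chrom][p] for p in first)
        if o.strand == "-":
            bases = bases.translate(_COMPLEMENT)
        if bases.upper() != o.start_codon.upper():
            mismatched.append(o.orf_id)
    return mismatched


# ---------------------------------------------------------------------------
# Catalog TSV + BED12
# ---------------------------------------------------------------------------

_CORE_COLUMNS = [
    "orf_id", "name", "host_transcript", "gene_id", "orf_type", "start_codon",
    "n_codons", "length_nt", "chrom", "strand", "source_datasets",
    "legacy_names_v35", "isoform_cluster", "ppm_gt1", "primary",
]


def write_catalog(records: pd.DataFrame, orfs: dict[str, OrfRecord],
                  tsv_path, bed_path) -> None:
    """Write the catalog as a TSV plus a companion BED12 with catalog names.

    Every record must be classified and carry at least one per-dataset pass
    flag; missing scores are rendered as the designated missing token.
    Floats are written to 6 decimals so the TSV round-trips exactly at that
    precision.
    """
    missing_cols = [c for c in _CORE_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ValidationError(f"catalog records missing columns: {missing_cols}")
    if not any(c.endswith("_pass") for c in records.columns):
        raise ValidationError("catalog records carry no scores/pass flags")
    if records["orf_type"].isna().any():
        bad = records.loc[records["orf_type"].isna(), "orf_id"].tolist()
        raise ValidationError(f"unclassified records: {bad}")

    out = records.copy()
    for col in out.columns:
        if out[col].dtype == float:
            out[col] = out[col].map(
                lambda v: MISSING_TOKEN if v is None or (isinstance(v, float) and math.isnan(v))
                else f"{v:.6f}"
            )
    out = out.fillna(MISSING_TOKEN)
    out.to_csv(tsv_path, sep="\t", index=False)

    named = []
    for row in records.itertuples(index=False):
        o = orfs[row.orf_id]
        named.append(replace(o, orf_id=row.name, blocks=list(o.blocks)))
    write_orfs(named, bed_path)


def read_catalog(tsv_path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t", na_values=[MISSING_TOKEN])
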