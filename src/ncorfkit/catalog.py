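"""Catalog construction: collapse, exclude, assign, classify, cluster, name.

The pipeline turns a pile of candidate ORFs from heterogeneous studies
into a Comprehensive set (deduplicated, mappable, not redundant with
annotated coding sequence) and a Primary set (the subset whose translation
signatures meet CDS-calibrated thresholds in at least one pooled dataset),
with full stage bookkeeping: every compiled ORF is accounted for as
unmapped, duplicate, excluded or comprehensive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import chi2_contingency

from .annotation_io import OrfRecord, TranscriptModel, ValidationError
from .calibration import (
    ThresholdSet,
    derive_thresholds,
    fit_reference,
    passes,
    select_primary,
)
from .coordinates import genome_to_transcript, orf_codons, orf_transcript_span
from .psite_tracks import PsiteTrack
from .signatures import compute_ppm, score_orf, score_transcript_cds

__all__ = [
    "CatalogReport",
    "IsoformCluster",
    "MapResult",
    "CatalogConfig",
    "ClassificationError",
    "collapse_identical",
    "map_and_exclude",
    "assign_host_transcript",
    "classify_orf_type",
    "cluster_isoforms",
    "assign_names",
    "build_catalog",
    "retained_after_removals",
    "pct",
    "length_pass_comparison",
    "length_bin_label",
]

SAME_FRAME_CDS = "same_frame_cds"
PSEUDOGENE_OVERLAP = "pseudogene_overlap"

#: transcript biotypes whose CDS triggers the same-frame exclusion
_CODING_BIOTYPES = ("protein_coding", "nonsense_mediated_decay")

#: gene biotypes acceptable as ORF hosts
_HOST_BIOTYPES = ("protein_coding", "lncRNA")


class ClassificationError(ValidationError):
    """An ORF's layout is not representable in the seven-type schema."""


# ---------------------------------------------------------------------------
# Bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class CatalogReport:
    """Stage accounting for a catalog run.

    Conservation: compiled = unmapped + duplicate + excluded + comprehensive,
    and primary <= comprehensive.
    """

    compiled: int
    duplicate: int
    unmapped: int
    excluded_same_frame: int
    excluded_pseudogene: int
    comprehensive: int
    primary: int = 0
    per_type: dict[str, int] = field(default_factory=dict)
    per_type_pass: dict[str, int] = field(default_factory=dict)
    length_bins: dict[str, int] = field(default_factory=dict)
    length_bins_pass: dict[str, int] = field(default_factory=dict)
    ppm_universe: list[str] = field(default_factory=list)

    @property
    def excluded(self) -> int:
        return self.excluded_same_frame + self.excluded_pseudogene

    @property
    def unique_sequences(self) -> int:
        """Unique genomic sequences surviving collapse and mapping."""
        return self.compiled - self.duplicate - self.unmapped

    def validate(self) -> None:
        if self.compiled != (
            self.unmapped + self.duplicate + self.excluded + self.comprehensive
        ):
            raise ValidationError(
                "stage conservation violated: "
                f"{self.compiled} != {self.unmapped} + {self.duplicate} + "
                f"{self.excluded} + {self.comprehensive}"
            )
        if self.primary > self.comprehensive:
            raise ValidationError("primary exceeds comprehensive")

    @classmethod
    def from_stage_counts(
        cls, compiled: int, duplicate: int, unmapped: int, excluded: int,
        primary: int = 0,
    ) -> "CatalogReport":
        """Accounting from stage counts alone; comprehensive follows by
        conservation."""
        report = cls(
            compiled=compiled,
            duplicate=duplicate,
            unmapped=unmapped,
            excluded_same_frame=excluded,
            excluded_pseudogene=0,
            comprehensive=compiled - duplicate - unmapped - excluded,
            primary=primary,
        )
        report.validate()
        return report

    def to_dict(self) -> dict:
        return {
            "compiled": self.compiled,
            "duplicate": self.duplicate,
            "unmapped": self.unmapped,
            "excluded_same_frame": self.excluded_same_frame,
            "excluded_pseudogene": self.excluded_pseudogene,
            "excluded": self.excluded,
            "unique_sequences": self.unique_sequences,
            "comprehensive": self.comprehensive,
            "primary": self.primary,
            "per_type": dict(self.per_type),
            "per_type_pass": dict(self.per_type_pass),
            "length_bins": dict(self.length_bins),
            "length_bins_pass": dict(self.length_bins_pass),
            "ppm_universe_size": len(self.ppm_universe),
        }

    def render(self) -> str:
        lines = [
            f"compiled            {self.compiled}",
            f"  duplicates        {self.duplicate}",
            f"  unmapped          {self.unmapped}",
            f"unique sequences    {self.unique_sequences}",
            f"  same-frame CDS    {self.excluded_same_frame}",
            f"  pseudogene        {self.excluded_pseudogene}",
            f"comprehensive       {self.comprehensive}",
            f"primary             {self.primary}",
        ]
        if self.per_type:
            lines.append("per type (comprehensive/primary):")
            for k in sorted(self.per_type):
                lines.append(
                    f"  {k:<12}{self.per_type[k]:>8}"
                    f"{self.per_type_pass.get(k, 0):>8}"
                )
        return "\n".join(lines)


def retained_after_removals(prior_total: int, removals: dict[str, int]) -> int:
    """Records of a prior catalog retained after itemized removals."""
    retained = prior_total - sum(removals.values())
    if retained < 0:
        raise ValidationError("removals exceed prior total")
    return retained


def pct(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """A percentage rounded to the reported precision."""
    if denominator <= 0:
        raise ValidationError("pct: non-positive denominator")
    return round(100.0 * numerator / denominator, ndigits)


def length_pass_comparison(
    pass_short: int, total_short: int, pass_long: int, total_long: int
) -> dict:
    """Compare pass rates of short vs long ORFs with a Pearson chi-square.

    Returns the two percentages, the chi-square statistic, the p-value and
    its log10 (the p underflows double precision for strongly separated
    groups; for df=1, log p = log 2 + log Phi(-sqrt(chi2))).
    """
    table = [
        [pass_short, total_short - pass_short],
        [pass_long, total_long - pass_long],
    ]
    stat, p, _, _ = chi2_contingency(table, correction=False)
    log10_p = float((np.log(2) + log_ndtr(-np.sqrt(stat))) / np.log(10))
    return {
        "pct_short": pct(pass_short, total_short, 2),
        "pct_long": pct(pass_long, total_long, 2),
        "chi2": float(stat),
        "p_value": float(p),
        "log10_p": log10_p,
    }


def length_bin_label(length_nt: int) -> str:
    """20-nt length bins up to 500 nt, then open-ended."""
    if length_nt > 500:
        return ">500"
    lo = ((length_nt - 1) // 20) * 20
    return f"{lo + 1}-{lo + 20}"


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def collapse_identical(orfs: list[OrfRecord]) -> tuple[list[OrfRecord], int]:
    """Collapse ORFs with identical chrom, strand and block list.

    Survivors carry the union of source datasets; all legacy names are
    retained (semicolon-joined when duplicates carried different ones).
    """
    by_key: dict[tuple, OrfRecord] = {}
    for o in orfs:
        key = o.identity_key()
        if key not in by_key:
            by_key[key] = o
        else:
            kept = by_key[key]
            kept.source_datasets |= o.source_datasets
            if o.legacy_name:
                if kept.legacy_name and o.legacy_name not in kept.legacy_name:
                    kept.legacy_name = f"{kept.legacy_name};{o.legacy_name}"
                elif not kept.legacy_name:
                    kept.legacy_name = o.legacy_name
    unique = list(by_key.values())
    return unique, len(orfs) - len(unique)


def is_compatible(orf: OrfRecord, t: TranscriptModel) -> bool:
    """True iff the ORF's blocks form a contiguous sub-path of the
    transcript's spliced structure (junction-exact containment)."""
    if orf.chrom != t.chrom or orf.strand != t.strand:
        return False
    prev = None
    for g in orf.positions():
        p = genome_to_transcript(t, g)
        if p is None:
            return False
        if prev is not None and p.offset != prev + 1:
            return False
        prev = p.offset
    return True


@dataclass
class MapResult:
    kept: list[OrfRecord]
    unmapped: list[str]
    excluded: list[tuple[str, str]]  # (orf_id, reason)
    candidates: dict[str, list[TranscriptModel]]


def _cds_phase_index(transcripts: list[TranscriptModel]) -> dict:
    """(chrom, strand) -> {genomic position -> set of codon phases} over the
    CDSs of protein-coding / NMD transcripts."""
    index: dict[tuple[str, str], dict[int, set[int]]] = {}
    for t in transcripts:
        if t.transcript_biotype not in _CODING_BIOTYPES or not t.cds_blocks:
            continue
        per = index.setdefault((t.chrom, t.strand), {})
        i = 0
        for blk in t.cds_tx_order():
            rng = range(blk.start, blk.end)
            for g in (rng if t.strand == "+" else reversed(rng)):
                per.setdefault(g, set()).add(i % 3)
                i += 1
    return index


def _pseudogene_index(transcripts: list[TranscriptModel]) -> dict:
    """(chrom, strand) -> set of exonic positions of pseudogene genes."""
    index: dict[tuple[str, str], set[int]] = {}
    for t in transcripts:
        if t.gene_biotype != "pseudogene":
            continue
        per = index.setdefault((t.chrom, t.strand), set())
        for e in t.exons:
            per.update(range(e.start, e.end))
    return index


def map_and_exclude(
    orfs: list[OrfRecord], transcripts: list[TranscriptModel]
) -> MapResult:
    """Split ORFs into kept / unmapped / excluded with reasons.

    Unmapped: no host-eligible transcript (protein-coding or lncRNA gene)
    contains the ORF's blocks contiguously in spliced space.  Excluded:
    same-strand overlap with an annotated coding CDS in the same codon
    phase, or same-strand exonic overlap with a pseudogene in any frame.
    """
    host_pool = [t for t in transcripts if t.gene_biotype in _HOST_BIOTYPES]
    by_loc: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in host_pool:
        by_loc.setdefault((t.chrom, t.strand), []).append(t)
    cds_phase = _cds_phase_index(transcripts)
    pseudo = _pseudogene_index(transcripts)

    kept, unmapped, excluded = [], [], []
    candidates: dict[str, list[TranscriptModel]] = {}
    for o in orfs:
        compat = [
            t for t in by_loc.get((o.chrom, o.strand), []) if is_compatible(o, t)
        ]
        if not compat:
            unmapped.append(o.orf_id)
            continue
        phase_map = cds_phase.get((o.chrom, o.strand), {})
        same_frame = any(
            (i % 3) in phase_map.get(g, ())
            for i, g in enumerate(o.positions())
        )
        if same_frame:
            excluded.append((o.orf_id, SAME_FRAME_CDS))
            continue
        pseudo_pos = pseudo.get((o.chrom, o.strand), set())
        if any(g in pseudo_pos for g in o.positions()):
            excluded.append((o.orf_id, PSEUDOGENE_OVERLAP))
            continue
        kept.append(o)
        candidates[o.orf_id] = compat
    return MapResult(kept, unmapped, excluded, candidates)


def assign_host_transcript(
    orf: OrfRecord, compatible: list[TranscriptModel]
) -> str:
    """Pick the host transcript among compatible isoforms.

    Priority: non-readthrough first, then MANE Select, best (lowest) APPRIS
    rank, best (lowest) TSL, protein-coding transcript biotype over
    non-coding, and finally lexicographic transcript_id as a deterministic
    tiebreak.
    """
    if not compatible:
        raise ValidationError(f"{orf.orf_id}: no compatible transcripts")
    best = min(
        compatible,
        key=lambda t: (
            1 if t.readthrough else 0,
            0 if t.mane_select else 1,
            t.appris_rank if t.appris_rank is not None else 8,
            t.tsl if t.tsl is not None else 6,
            0 if t.transcript_biotype == "protein_coding" else 1,
            t.transcript_id,
        ),
    )
    return best.transcript_id


def classify_orf_type(orf: OrfRecord, host: TranscriptModel) -> str:
    """One of the seven ORF types, from the host biotype and the ORF's
    position relative to the host CDS in spliced coordinates."""
    if host.gene_biotype == "lncRNA":
        return "lncRNA-ORF"
    if host.gene_biotype != "protein_coding":
        raise ClassificationError(
            f"{orf.orf_id}: host gene biotype {host.gene_biotype!r} cannot "
            f"host an ORF"
        )
    if not host.cds_blocks:
        return "PT-ORF"
    first = host.cds_tx_order()[0]
    g_first = first.start if host.strand == "+" else first.end - 1
    cstart = genome_to_transcript(host, g_first).offset
    cend = cstart + host.cds_length
    span = orf_transcript_span(orf, host)
    ostart, oend = span.start, span.end
    if oend <= cstart:
        return "uORF"
    if ostart >= cend:
        return "dORF"
    if ostart < cstart and oend > cend:
        raise ClassificationError(
            f"{orf.orf_id}: spans 5'UTR, CDS and 3'UTR of "
            f"{host.transcript_id}; not representable"
        )
    if ostart < cstart:
        return "uoORF"
    if oend <= cend:
        return "intORF"
    return "doORF"


@dataclass
class IsoformCluster:
    """Connected component of the shared-genomic-codon relation."""

    cluster_id: int
    members: list[str]
    pairwise: dict[frozenset, dict[str, bool]] = field(default_factory=dict)


def cluster_isoforms(orfs: list[OrfRecord]) -> list[IsoformCluster]:
    """Group ORFs sharing at least one genomic codon (same 3 positions, same
    strand, same order) into connected components.

    Pairwise flags within a cluster: shared_start / shared_stop for
    identical first / last codon positions, and overlap_ge_90 when shared
    codons cover >=90% of the shorter ORF.
    """
    codon_sets = {}
    firsts, lasts = {}, {}
    for o in orfs:
        addrs = orf_codons(o)
        key = lambda c: (o.chrom, o.strand, c.genomic_positions)
        codon_sets[o.orf_id] = {key(c) for c in addrs}
        firsts[o.orf_id] = key(addrs[0])
        lasts[o.orf_id] = key(addrs[-1])

    g = nx.Graph()
    g.add_nodes_from(codon_sets)
    by_codon: dict[tuple, list[str]] = {}
    for oid, codons in codon_sets.items():
        for c in codons:
            by_codon.setdefault(c, []).append(oid)
    for ids in by_codon.values():
        for a, b in zip(ids, ids[1:]):
            g.add_edge(a, b)

    clusters = []
    n_codons = {o.orf_id: o.n_codons for o in orfs}
    for cid, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        members = sorted(comp)
        cluster = IsoformCluster(cid, members)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                shared = codon_sets[a] & codon_sets[b]
                if not shared:
                    continue
                cluster.pairwise[frozenset((a, b))] = {
                    "shared_start": firsts[a] == firsts[b],
                    "shared_stop": lasts[a] == lasts[b],
                    "overlap_ge_90": (
                        len(shared) / min(n_codons[a], n_codons[b]) >= 0.9
                    ),
                }
        clusters.append(cluster)
    return clusters


_NAME_RE = re.compile(r"^c(\w+?)riboseqorf(\d+)$")


def _chrom_prefix(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


def assign_names(
    orfs: list[OrfRecord], legacy: dict[str, str] | None = None
) -> dict[str, str]:
    """Catalog names: legacy holders keep theirs; new ORFs get
    c{chrom}riboseqorf{k} with k continuing above the chromosome's highest
    legacy ordinal, in genomic-start order."""
    legacy = legacy or {}
    seen: dict[str, str] = {}
    for oid, name in legacy.items():
        if name in seen.values():
            raise ValidationError(f"duplicate legacy name {name!r}")
        seen[oid] = name

    max_ordinal: dict[str, int] = {}
    keep: dict[str, str] = {}
    for oid, name in legacy.items():
        m = _NAME_RE.match(name)
        if m:
            keep[oid] = name
            c, k = m.group(1), int(m.group(2))
            max_ordinal[c] = max(max_ordinal.get(c, 0), k)

    names: dict[str, str] = dict(keep)
    new = [o for o in orfs if o.orf_id not in keep]
    for o in sorted(new, key=lambda o: (o.chrom, o.genomic_start, o.orf_id)):
        c = _chrom_prefix(o.chrom)
        k = max_ordinal.get(c, 0) + 1
        max_ordinal[c] = k
        names[o.orf_id] = f"c{c}riboseqorf{k}"
    if len(set(names.values())) != len(names):
        raise ValidationError("catalog names not unique")
    return names


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class CatalogConfig:
    """Tunable options of a catalog run."""

    window: int = 15            # stop-flank window size, nt
    include_stop: bool = False  # count the stop codon in PIF/Uniformity bodies
    tail: float = 0.05          # calibration tail for PIF/Uniformity
    seed: int = 0               # recorded for provenance; the pipeline is deterministic


def build_catalog(
    orfs: list[OrfRecord],
    transcripts: list[TranscriptModel],
    tracks: dict[str, PsiteTrack],
    thresholds: dict[str, ThresholdSet] | None = None,
    config: CatalogConfig | None = None,
) -> tuple[pd.DataFrame, CatalogReport]:
    """Run the whole pipeline and return (catalog records, stage report).

    Stages: collapse -> map/exclude -> host assignment -> classification ->
    per-dataset scoring -> PPM (universe = kept ORFs + annotated CDSs) ->
    threshold passes -> Primary selection -> isoform clustering -> naming.
    When ``thresholds`` is None they are calibrated per dataset from the
    annotated protein-coding CDS score distributions.
    """
    config = config or CatalogConfig()
    compiled = len(orfs)
    unique, dup_count = collapse_identical(orfs)
    mapped = map_and_exclude(unique, transcripts)

    hosts: dict[str, TranscriptModel] = {}
    types: dict[str, str] = {}
    t_by_id = {t.transcript_id: t for t in transcripts}
    for o in mapped.kept:
        tid = assign_host_transcript(o, mapped.candidates[o.orf_id])
        o.host_transcript = tid
        hosts[o.orf_id] = t_by_id[tid]
        types[o.orf_id] = classify_orf_type(o, hosts[o.orf_id])
        o.orf_type = types[o.orf_id]

    cds_transcripts = [
        t for t in transcripts
        if t.transcript_biotype == "protein_coding" and t.cds_blocks
    ]
    if thresholds is None:
        thresholds = {}
        for ds, track in tracks.items():
            ref = [score_transcript_cds(t, track, config.window,
                                        config.include_stop)
                   for t in cds_transcripts]
            fits = {
                m: fit_reference([getattr(s, m) for s in ref
                                  if getattr(s, m) is not None])
                for m in ("pif", "uniformity", "dropoff")
            }
            thresholds[ds] = derive_thresholds(fits, ds, config.tail)
    else:
        # a named default set applied to a dataset adopts its id
        from dataclasses import replace
        thresholds = {
            ds: thr if thr.dataset_id == ds else replace(thr, dataset_id=ds)
            for ds, thr in thresholds.items()
        }

    scores: dict[str, dict] = {}  # dataset -> orf_id -> SignatureScores
    ppm_universe_ids: list[str] = []
    for ds, track in tracks.items():
        per = {}
        universe = []
        for o in mapped.kept:
            s = score_orf(o, hosts[o.orf_id], track, config.window,
                          config.include_stop)
            per[o.orf_id] = s
            universe.append((o.orf_id, s.n_psites, (o.n_codons - 1) * 3))
        for t in cds_transcripts:
            s = score_transcript_cds(t, track, config.window,
                                     config.include_stop)
            universe.append((f"CDS:{t.transcript_id}", s.n_psites, t.cds_length))
        ppm = compute_ppm(universe)
        for oid, s in per.items():
            s.ppm = ppm[oid]
        scores[ds] = per
        ppm_universe_ids = [u[0] for u in universe]

    pass_flags: dict[str, dict[str, bool]] = {
        ds: {oid: passes(s, thresholds[ds]) for oid, s in per.items()}
        for ds, per in scores.items()
    }
    primary = {
        o.orf_id: select_primary([pass_flags[ds][o.orf_id] for ds in tracks])
        for o in mapped.kept
    }

    clusters = cluster_isoforms(mapped.kept) if mapped.kept else []
    cluster_of = {
        oid: c.cluster_id for c in clusters for oid in c.members
    }
    legacy = {
        o.orf_id: o.legacy_name.split(";")[0]
        for o in mapped.kept
        if o.legacy_name and _NAME_RE.match(o.legacy_name.split(";")[0])
    }
    names = assign_names(mapped.kept, legacy)

    rows = []
    for o in mapped.kept:
        row = {
            "orf_id": o.orf_id,
            "name": names[o.orf_id],
            "host_transcript": o.host_transcript,
            "gene_id": hosts[o.orf_id].gene_id,
            "orf_type": types[o.orf_id],
            "start_codon": o.start_codon,
            "n_codons": o.n_codons,
            "length_nt": o.length_nt,
            "chrom": o.chrom,
            "strand": o.strand,
            "source_datasets": ",".join(sorted(o.source_datasets)),
            "legacy_names_v35": o.legacy_name,
            "isoform_cluster": cluster_of.get(o.orf_id, -1),
            "ppm_gt1": any(
                (scores[ds][o.orf_id].ppm or 0) > 1 for ds in tracks
            ),
            "primary": primary[o.orf_id],
        }
        for ds in tracks:
            s = scores[ds][o.orf_id]
            row.update({
                f"{ds}_pif": s.pif,
                f"{ds}_uniformity": s.uniformity,
                f"{ds}_dropoff": s.dropoff,
                f"{ds}_ppm": s.ppm,
                f"{ds}_n_psites": s.n_psites,
                f"{ds}_pass": pass_flags[ds][o.orf_id],
            })
        rows.append(row)
    records = pd.DataFrame(rows)

    report = CatalogReport(
        compiled=compiled,
        duplicate=dup_count,
        unmapped=len(mapped.unmapped),
        excluded_same_frame=sum(
            1 for _, r in mapped.excluded if r == SAME_FRAME_CDS
        ),
        excluded_pseudogene=sum(
            1 for _, r in mapped.excluded if r == PSEUDOGENE_OVERLAP
        ),
        comprehensive=len(mapped.kept),
        primary=sum(primary.values()),
        ppm_universe=ppm_universe_ids,
    )
    for o in mapped.kept:
        typ = types[o.orf_id]
        bin_ = length_bin_label(o.length_nt)
        report.per_type[typ] = report.per_type.get(typ, 0) + 1
        report.length_bins[bin_] = report.length_bins.get(bin_, 0) + 1
        if primary[o.orf_id]:
            report.per_type_pass[typ] = report.per_type_pass.get(typ, 0) + 1
            report.length_bins_pass[bin_] = (
                report.length_bins_pass.get(bin_, 0) + 1
            )
    report.validate()
    return records, report
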