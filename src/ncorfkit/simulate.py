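"""Synthetic annotations, ORF sets and P-site tracks with known ground truth.

The generator plants a fixed, hand-designed locus layout that exercises
every classification and assignment branch (all seven ORF types, MANE /
APPRIS / TSL / readthrough combinations, a pseudogene, a retained-intron
transcript) plus structural decoys (a duplicate, an intronic ORF, a
same-frame CDS clone, a pseudogene-overlapping ORF) and signal decoys
(frame-shifted reads, zero coverage).  P-site counts follow a
gamma-Poisson-multinomial model: per sense codon an intensity is drawn
from a gamma with configurable mean and dispersion, a Poisson read count
is placed multinomially within the codon (frame 0 with probability
``frame_fidelity``), and in-frame reads leak past the stop codon at rate
``post_stop_leakage`` relative to the before-window in-frame count, so the
expected Drop-off is 1/(1+leakage).  Everything is deterministic under the
seed.  This is a test harness for the scoring machinery, not a model of
Ribo-seq biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import (
    GenomicInterval,
    OrfRecord,
    TranscriptModel,
    ValidationError,
    write_annotation,
    write_orf_metadata,
    write_orfs,
)
from .coordinates import genome_to_transcript, transcript_to_genome
from .psite_tracks import PsiteTrack, write_bedgraph_pair

__all__ = [
    "SimulationConfig",
    "SimulatedData",
    "simulate_annotation",
    "simulate_psites",
    "simulate_readlength_tracks",
]

DECOY_NONE = ""
DECOY_DUPLICATE = "duplicate"
DECOY_INTRONIC = "intronic"
DECOY_SAME_FRAME = "same_frame_cds"
DECOY_PSEUDOGENE = "pseudogene_overlap"
DECOY_FRAME_SHIFT = "frame_shifted"
DECOY_ZERO = "zero_coverage"


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults emulate deep pooled Ribo-seq data.

    frame_fidelity mirrors the ~85% overall 3-nt periodicity of pooled
    human data; mean_psites_per_codon reflects deep pooled coverage;
    dispersion is the gamma shape of per-codon intensities (lower = more
    ragged coverage); post_stop_leakage is the expected after/before
    in-frame density ratio at the stop codon.
    """

    seed: int = 0
    frame_fidelity: float = 0.85
    dispersion: float = 2.0
    mean_psites_per_codon: float = 8.0
    post_stop_leakage: float = 0.05
    include_decoys: bool = True
    cds_signal: bool = True
    min_codon_count: int = 0     # coverage floor per sense codon
    n_extra_orfs: int = 0        # standalone single-exon lncRNA ORFs (batch mode)
    extra_orf_codons: int = 30   # sense+stop codons of each extra ORF

    def __post_init__(self) -> None:
        if not (0.0 <= self.frame_fidelity <= 1.0):
            raise ValidationError("frame_fidelity must be in [0, 1]")
        for name in ("dispersion", "mean_psites_per_codon", "post_stop_leakage"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and non-negative")
        if self.extra_orf_codons < 2:
            raise ValidationError("extra ORFs need at least 2 codons")


@dataclass
class SimulatedData:
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    orfs: list[OrfRecord]
    truth: pd.DataFrame  # orf_id, true_type, host, decoy

    def transcript(self, tid: str) -> TranscriptModel:
        return next(t for t in self.transcripts if t.transcript_id == tid)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gtf",
            "orfs": outdir / "orfs.bed",
            "orf_meta": outdir / "orfs_meta.tsv",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["genome"], "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        write_annotation(self.transcripts, paths["annotation"])
        write_orfs(self.orfs, paths["orfs"])
        write_orf_metadata(self.orfs, paths["orf_meta"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _orf_from_offsets(
    t: TranscriptModel, start: int, end: int, orf_id: str, **kwargs
) -> OrfRecord:
    """Build an ORF from a spliced-offset range of a transcript, merging
    consecutive genomic positions into blocks (translation order)."""
    gpos = [transcript_to_genome(t, off) for off in range(start, end)]
    blocks: list[GenomicInterval] = []
    run = [gpos[0]]
    step = 1 if t.strand == "+" else -1
    for g in gpos[1:]:
        if g == run[-1] + step:
            run.append(g)
        else:
            lo, hi = min(run), max(run)
            blocks.append(GenomicInterval(t.chrom, lo, hi + 1, t.strand))
            run = [g]
    lo, hi = min(run), max(run)
    blocks.append(GenomicInterval(t.chrom, lo, hi + 1, t.strand))
    return OrfRecord(orf_id=orf_id, blocks=blocks, strand=t.strand, **kwargs)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_annotation(config: SimulationConfig) -> SimulatedData:
    """Deterministic toy genome, annotation, ORF set and truth table."""
    rng = np.random.default_rng([config.seed, 101])

    def T(tid, gid, gbio, tbio, exons, cds=(), **tags):
        return TranscriptModel(
            transcript_id=tid, gene_id=gid, gene_biotype=gbio,
            transcript_biotype=tbio,
            exons=[GenomicInterval(*e) for e in exons],
            cds_blocks=[GenomicInterval(*c) for c in cds], **tags,
        )

    transcripts = [
        # geneA: 3-exon coding gene; A1 is MANE, A2 a retained-intron transcript
        T("T_A1", "G_A", "protein_coding", "protein_coding",
          [("chr1", 1000, 1300, "+"), ("chr1", 1500, 1800, "+"),
           ("chr1", 2000, 2400, "+")],
          [("chr1", 1200, 1300, "+"), ("chr1", 1500, 1800, "+"),
           ("chr1", 2000, 2200, "+")],
          mane_select=True, appris_rank=1, tsl=1),
        T("T_A2", "G_A", "protein_coding", "retained_intron",
          [("chr1", 1000, 1800, "+")], tsl=3),
        # geneB: 2-exon lncRNA on the minus strand
        T("T_B1", "G_B", "lncRNA", "lncRNA",
          [("chr1", 5000, 5200, "-"), ("chr1", 5400, 5600, "-")], tsl=1),
        # geneC: pseudogene on chr2
        T("T_C1", "G_C", "pseudogene", "processed_pseudogene",
          [("chr2", 500, 700, "+")]),
        # geneD: readthrough coding transcript vs plain non-coding sibling
        T("T_D1", "G_D", "protein_coding", "protein_coding",
          [("chr2", 300, 1100, "+")], [("chr2", 400, 700, "+")],
          readthrough=True, tsl=1),
        T("T_D2", "G_D", "protein_coding", "processed_transcript",
          [("chr2", 300, 1100, "+")], tsl=2),
        # geneE: APPRIS/TSL tie-breaking between two coding isoforms
        T("T_E1", "G_E", "protein_coding", "protein_coding",
          [("chr2", 2000, 2600, "+")], [("chr2", 2200, 2500, "+")],
          appris_rank=1, tsl=2),
        T("T_E2", "G_E", "protein_coding", "protein_coding",
          [("chr2", 2000, 2600, "+")], [("chr2", 2200, 2500, "+")],
          appris_rank=3, tsl=1),
    ]
    by_id = {t.transcript_id: t for t in transcripts}

    orfs: list[OrfRecord] = []
    truth_rows: list[dict] = []

    def plant(tid, start, end, orf_id, true_type, decoy=DECOY_NONE,
              start_codon="ATG", source="studyA", legacy=None):
        t = by_id[tid]
        o = _orf_from_offsets(
            t, start, end, orf_id, start_codon=start_codon,
            source_datasets={source}, legacy_name=legacy,
        )
        orfs.append(o)
        truth_rows.append({
            "orf_id": orf_id, "true_type": true_type or "",
            "host": tid if true_type else "", "decoy": decoy,
        })
        return o

    # offsets on T_A1: 5'UTR [0,200), CDS [200,800), 3'UTR [800,1000)
    plant("T_A1", 50, 74, "orf_uORF_1", "uORF", legacy="c1riboseqorf3")
    plant("T_A1", 100, 106, "orf_uORF_min", "uORF")
    plant("T_A1", 190, 220, "orf_uoORF_1", "uoORF", start_codon="GTG")
    plant("T_A1", 300, 345, "orf_intORF_1", "intORF")
    plant("T_A1", 769, 829, "orf_doORF_1", "doORF")
    plant("T_A1", 850, 880, "orf_dORF_1", "dORF")
    plant("T_A2", 320, 350, "orf_PT_1", "PT-ORF")  # inside retained intron
    plant("T_B1", 180, 240, "orf_lnc_1", "lncRNA-ORF", legacy="c1norep7")
    plant("T_B1", 198, 240, "orf_lnc_iso", "lncRNA-ORF", start_codon="CTG")
    plant("T_D2", 500, 530, "orf_PT_rt", "PT-ORF")  # readthrough demotion
    plant("T_E1", 50, 80, "orf_uORF_E", "uORF")

    if config.include_decoys:
        plant("T_A1", 50, 74, "orf_uORF_dup", "uORF",
              decoy=DECOY_DUPLICATE, source="studyB")
        plant("T_A1", 110, 140, "orf_fs_decoy", "uORF", decoy=DECOY_FRAME_SHIFT)
        plant("T_A1", 900, 930, "orf_zero_decoy", "dORF", decoy=DECOY_ZERO)
        plant("T_A1", 230, 260, "orf_clone_decoy", None, decoy=DECOY_SAME_FRAME)
        # intronic: in A1's second intron, outside every exon
        orfs.append(OrfRecord(
            "orf_intronic_decoy",
            [GenomicInterval("chr1", 1850, 1880, "+")], "+",
            source_datasets={"studyA"},
        ))
        truth_rows.append({"orf_id": "orf_intronic_decoy", "true_type": "",
                           "host": "", "decoy": DECOY_INTRONIC})
        # overlaps the chr2 pseudogene exon (same strand, maps to G_D)
        orfs.append(OrfRecord(
            "orf_pseudo_decoy",
            [GenomicInterval("chr2", 600, 630, "+")], "+",
            source_datasets={"studyA"},
        ))
        truth_rows.append({"orf_id": "orf_pseudo_decoy", "true_type": "",
                           "host": "", "decoy": DECOY_PSEUDOGENE})

    # batch mode: standalone single-exon lncRNA ORFs for parameter recovery
    chr3_len = 100
    if config.n_extra_orfs:
        body = config.extra_orf_codons * 3
        pitch = body + 200
        chr3_len = 100 + config.n_extra_orfs * pitch
        for i in range(config.n_extra_orfs):
            lo = 100 + i * pitch
            t = TranscriptModel(
                transcript_id=f"T_X{i}", gene_id=f"G_X{i}",
                gene_biotype="lncRNA", transcript_biotype="lncRNA",
                exons=[GenomicInterval("chr3", lo, lo + body + 60, "+")],
            )
            transcripts.append(t)
            by_id[t.transcript_id] = t
            plant(f"T_X{i}", 20, 20 + body, f"orf_extra_{i}", "lncRNA-ORF")

    sizes = {"chr1": 6000, "chr2": 3000, "chr3": chr3_len}
    genome = {
        c: "".join(rng.choice(list("ACGT"), size=n))
        for c, n in sizes.items()
    }
    # stamp declared start codons and TAA stops into the sequence
    arrs = {c: list(s) for c, s in genome.items()}
    for o in orfs:
        pos = o.positions()
        for codon, targets in ((o.start_codon, pos[:3]), ("TAA", pos[-3:])):
            for base, g in zip(codon, targets):
                arrs[o.chrom][g] = (
                    base if o.strand == "+" else base.translate(_COMPLEMENT)
                )
    genome = {c: "".join(a) for c, a in arrs.items()}

    return SimulatedData(
        genome=genome, transcripts=transcripts, orfs=orfs,
        truth=pd.DataFrame(truth_rows),
    )


def _codon_probs(f: float, shift: int) -> list[float]:
    probs = [0.0, 0.0, 0.0]
    for frame in range(3):
        probs[(frame + shift) % 3] = f if frame == 0 else (1 - f) / 2
    return probs


def simulate_psites(
    sim: SimulatedData,
    config: SimulationConfig,
    dataset_id: str = "sim",
    seed: int | None = None,
) -> PsiteTrack:
    """Generate a P-site track over the simulated loci.

    Sense codons of every planted ORF (except zero-coverage / duplicate /
    same-frame-clone decoys) receive gamma-Poisson counts split
    multinomially across the codon's 3 positions; frame-shifted decoys
    have the split rotated by one.  Annotated CDSs receive the same signal
    when ``cds_signal`` is on.  In-frame reads leak into the 15-nt window
    after each stop codon at rate ``post_stop_leakage``.
    """
    rng = np.random.default_rng(
        [config.seed if seed is None else seed, 202]
    )
    track = PsiteTrack(dataset_id)
    by_id = {t.transcript_id: t for t in sim.transcripts}
    truth = sim.truth.set_index("orf_id")

    def emit_region(chrom, strand, sense_positions, shift, host, stop_end_off):
        """sense_positions: genomic positions of sense codons in translation
        order; host+stop_end_off locate the after-stop window."""
        n_codons = len(sense_positions) // 3
        probs = _codon_probs(config.frame_fidelity, shift)
        frame0_per_codon = np.zeros(n_codons, dtype=int)
        intensities = rng.gamma(
            shape=config.dispersion,
            scale=config.mean_psites_per_codon / config.dispersion,
            size=n_codons,
        )
        counts = np.maximum(rng.poisson(intensities), config.min_codon_count)
        for ci in range(n_codons):
            if counts[ci] == 0:
                continue
            split = rng.multinomial(counts[ci], probs)
            for k in range(3):
                if split[k]:
                    track.add(chrom, strand, sense_positions[3 * ci + k],
                              int(split[k]))
            frame0_per_codon[ci] = split[(0 + shift) % 3]
        # post-stop leakage, in frame, onto the transcript's after window
        if host is not None and config.post_stop_leakage > 0:
            b = int(frame0_per_codon[-5:].sum())
            n_after = rng.poisson(config.post_stop_leakage * b)
            slots = [
                stop_end_off + 3 * k
                for k in range(5)
                if stop_end_off + 3 * k < host.spliced_length
            ]
            if n_after and slots:
                placed = rng.multinomial(n_after, [1 / len(slots)] * len(slots))
                for off, n in zip(slots, placed):
                    if n:
                        g = transcript_to_genome(host, off)
                        track.add(chrom, strand, g, int(n))

    skip = {DECOY_ZERO, DECOY_DUPLICATE, DECOY_SAME_FRAME}
    for o in sim.orfs:
        row = truth.loc[o.orf_id]
        if row["decoy"] in skip:
            continue
        shift = 1 if row["decoy"] == DECOY_FRAME_SHIFT else 0
        host = by_id.get(row["host"]) if row["host"] else None
        pos = o.positions()
        stop_end_off = None
        if host is not None:
            stop_end_off = genome_to_transcript(host, pos[-1]).offset + 1
        emit_region(o.chrom, o.strand, pos[:-3], shift, host, stop_end_off)

    if config.cds_signal:
        seen_cds = set()
        for t in sim.transcripts:
            if t.transcript_biotype != "protein_coding" or not t.cds_blocks:
                continue
            key = tuple((b.start, b.end) for b in t.cds_blocks)
            if (t.chrom, t.strand, key) in seen_cds:
                continue
            seen_cds.add((t.chrom, t.strand, key))
            pos = []
            for blk in t.cds_tx_order():
                rng_ = range(blk.start, blk.end)
                pos.extend(rng_ if t.strand == "+" else reversed(rng_))
            stop_end_off = genome_to_transcript(t, pos[-1]).offset + 4
            emit_region(t.chrom, t.strand, pos, 0, t, stop_end_off)
    return track


def simulate_readlength_tracks(
    sim: SimulatedData,
    config: SimulationConfig,
    fidelity_by_length: dict[int, float],
    dataset_id: str = "sim",
) -> dict[int, PsiteTrack]:
    """CDS-only tracks per read length with length-specific frame fidelity,
    for the periodicity QC; ids carry the ``_len{N}`` suffix."""
    from dataclasses import replace

    tracks = {}
    for i, (length, f) in enumerate(sorted(fidelity_by_length.items())):
        cfg = replace(config, frame_fidelity=f, cds_signal=True)
        tr = simulate_psites(
            SimulatedData(sim.genome, sim.transcripts, [],
                          sim.truth.iloc[0:0]),
            cfg, dataset_id=f"{dataset_id}_len{length}",
            seed=config.seed + 1000 + i,
        )
        tracks[length] = tr
    return tracks


def write_tracks(track: PsiteTrack, outdir) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plus = outdir / f"{track.dataset_id}.plus.bedgraph"
    minus = outdir / f"{track.dataset_id}.minus.bedgraph"
    write_bedgraph_pair(track, plus, minus)
    return plus, minus
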