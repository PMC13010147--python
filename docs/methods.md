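# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open on the genome; GTF's
1-based closed convention is converted at the parsing boundary and nowhere
else. Transcript offsets run 5'→3' along the spliced transcript; on the
minus strand offset 0 is the 3'-most genomic base of the first exon in
transcription order. ORF BED12 blocks include the stop codon as the final
3 nt, and all codon arithmetic downstream assumes this. Reading frame is
anchored at the ORF start codon and extended in phase beyond the ORF in
both directions; this phase extension is what makes "in-frame" counting
well defined inside the stop-codon flanking windows. Codons may span
splice junctions; no ORF is rejected for junctional codons.

## Scores

PIF, Uniformity and Drop-off are computed per (ORF, dataset) from the
P-site counts projected onto the host transcript. Decisions where the
definitions leave room:

* **Stop codon exclusion.** The ORF body for PIF/Uniformity is the sense
  codons only. Terminating-ribosome pileups on the stop codon would
  otherwise inflate in-frame totals, and the stop region is owned by the
  Drop-off metric. `include_stop=True` switches this, as the body-map
  convention on this point is not documented.
* **Strict codon test.** A codon shows translation when its frame-0 share
  is strictly greater than 1/3, so a perfectly uniform codon (equal
  thirds) fails. Zero-count codons also fail: 0/0 is no evidence, which
  keeps Uniformity sensitive to coverage gaps, matching its intent of
  rewarding signal throughout the length.
* **Drop-off windows are transcript windows**, 15 nt on either side of the
  stop codon, excluding the stop codon itself, truncated at transcript
  ends; the before window may extend 5' of a very short ORF's start.
  Only frame-0 positions (in ORF phase) contribute to either side.
* **Missing scores** (zero denominator) are first-class, never imputed,
  and always fail thresholds.
* **PPM universe.** PPM is relative to the set of regions it is computed
  over; the catalog uses kept ncORFs plus all annotated protein-coding
  CDS bodies, and records the universe in the run report because the
  values are meaningless without it. PPM > 1 is reported as an expression
  flag only; it never gates Primary membership.

## Calibration

Per dataset and metric, a normal distribution is moment-fitted (sample
mean, unbiased sample sd) to the score distribution of annotated
protein-coding CDSs. PIF and Uniformity thresholds are the fitted-normal
point exceeded by 95% of reference CDSs, `μ + z(0.05)·σ ≈ μ − 1.645σ`
(the tail is configurable); the Drop-off threshold is `μ`. Thresholds are
clamped to [0, 1]. The lower-tail reading of "95th percentile" is forced
by the published threshold values themselves (e.g. a PIF threshold of
0.7589 sits well below typical CDS PIF; the upper percentile would reject
nearly everything). Passing is the conjunction of all three metrics
within a dataset, with inclusive boundaries (published thresholds are
reported to limited precision; exclusive equality would be seed-
sensitive), and Primary membership requires passing in at least one
dataset.

## Catalog pipeline

Stages run in a fixed order — collapse identical genomic sequences →
map/exclude → host assignment → classification → scoring → PPM →
selection → isoform clustering → naming — and the report asserts
conservation (compiled = duplicates + unmapped + excluded +
comprehensive) after every build. Choices made where the procedure was
open:

* **Mapping is junction-exact**: an ORF maps to a transcript only when its
  blocks form a contiguous sub-path of the spliced transcript, not merely
  lie within exons; an ORF is a spliced sequence and a junction mismatch
  implies a different transcript.
* **Same-frame exclusion** compares genomic codon phase, same strand,
  against CDSs of protein-coding and nonsense-mediated-decay transcripts;
  partial overlap suffices.
* **Pseudogene exclusion** uses same-strand exonic overlap in any frame.
  Opposite-strand overlap is kept: this is the conservative annotation
  reading, though the multimapping concern motivating the rule is
  strand-agnostic.
* **Host priority**: readthrough transcripts are demoted below all
  others, then MANE Select, lowest APPRIS rank (principal1=1 …
  alternative2=7, absent ranks worst — ranks are the portable reading of
  "highest APPRIS score"), lowest TSL, protein-coding transcript biotype,
  then transcript id as a deterministic tiebreak. Gene biotypes other
  than protein_coding/lncRNA are rejected as hosts; an ORF only
  compatible with such transcripts reports as unmapped.
* **Isoform relation** is shared *genomic* codons (same 3 positions, same
  strand, same order), clustered as connected components; amino-acid
  string sharing would relate unrelated loci. The ≥90% overlap flag uses
  the shorter ORF's codon count as denominator (the stricter symmetric
  choice).
* **Naming** keeps legacy `c{chrom}riboseqorf{k}` names, continues `k`
  above each chromosome's highest legacy ordinal in genomic-start order,
  and carries non-pattern legacy labels (e.g. norep-style) in a
  `legacy_names_v35` column instead of reusing them.

An ORF spanning 5'UTR, CDS and 3'UTR simultaneously is not representable
in the seven-type schema and raises a classification error rather than
receiving an arbitrary label.

## Synthetic data

The simulator is a test harness, not a model of Ribo-seq biology. It
plants a fixed locus layout — a 3-exon coding gene with a retained-intron
sibling, a minus-strand spliced lncRNA, a pseudogene, a readthrough
coding transcript with an ordinary non-coding sibling, and an APPRIS/TSL
tie — hosting at least one ORF of each of the seven types (including a
2-codon minimal ORF and non-AUG starts), plus decoys: a duplicate, an
intronic ORF, a same-frame CDS clone, a pseudogene-overlapping ORF, a
frame-shifted-signal ORF and a zero-coverage ORF.

Counts follow a gamma–Poisson–multinomial model: per sense codon an
intensity is drawn from a gamma (configurable mean and shape), a Poisson
count is drawn and split multinomially across the codon's three positions
with frame-0 probability `f` (rotated by one for frame-shifted decoys),
and in-frame reads leak into the after-stop window as Poisson(λ·B) where
B is the realized in-frame count in the 15-nt before window — so the
expected Drop-off is 1/(1+λ) and expected PIF is `f`, giving the
parameter-recovery tests closed forms. A `min_codon_count` floor makes
the noiseless limit (`f=1, λ=0`) exact for Uniformity. Defaults
(`f=0.85`, mean 8 P-sites/codon, gamma shape 2, `λ=0.05`) mirror deep
pooled human data with ~85% overall periodicity and sharp termination.
Everything derives from a single seed and is byte-reproducible.

What the simulator does **not** emulate: read-length distributions,
sequence-dependent and ligation biases, rRNA contamination, multimapping,
transcript-abundance heterogeneity, or realistic gene structure scale
(the toy genome is tens of kilobases). Passing tests therefore show the
scoring and bookkeeping machinery is correct under the stated generative
model, not that the thresholds transfer to any particular real dataset.
The simulated CDS signal shares the planted ORFs' fidelity, so
calibrating on simulated CDSs yields thresholds coupled to `f`; the
parameter-recovery suites disable CDS signal to score planted ORFs
without overlap contamination.

## Problem sizes and numerics

Test and acceptance runs use 40–100 planted ORFs of ~30 codons at
10–20 P-sites/codon per batch, 50-seed decoy-rejection batches, and
10,000-draw Monte-Carlo calibration checks; these sizes give binomial
standard errors small enough for 3-SE assertions while keeping the whole
suite in seconds. Ratios are computed in double precision with no
smoothing; exactness assertions on closed forms allow only float
round-off (≤1e-12). The pipeline itself contains no randomness; the CLI
records the seed purely for provenance.

## Known limitations

Overlapping reading frames (uoORF/doORF/intORF) mix periodic signals, so
the metrics systematically under-score them — visible directly in the
simulator once CDS signal is enabled. PPM depends on the chosen universe
and is not comparable across runs with different universes. The catalog
TSV schema is a faithful superset of the published catalog fields, not
byte-identical to it. GFF3 input, BigWig output, BAM ingestion, P-site
offset inference and assembly liftover are out of scope.
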