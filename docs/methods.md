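# Methods

## Evidence model

A fusion junction is a pair of genomic coordinates (the breakpoint) joined
in a transcript. Two read-level observations support it:

- **SPLIT read** — a read covering the junction. It cannot align
  end-to-end; its local alignments A_i = (c_i, p_i, q_i, l_i) are tested
  pairwise in read-coordinate order (q_i < q_j). The pair is fusion
  evidence when it is *not* splice-explainable — different chromosome,
  discordant strands, genomic order contradicting read order, or a
  same-strand separation above the maximum intron size I_max — and the
  read-coordinate gap g = q_j − (q_i + l_i) lies in [−T_inner, +T_outer].
  T_inner bounds junction microhomology (the same read bases align on both
  sides), T_outer bounds unaligned junction bases; both bounds are closed.
  The implied breakpoint is exact: the donor end is the genomic position of
  read base q_i + l_i − 1 (strand-aware), the acceptor that of read base
  q_j. With microhomology the junction is anchored at the donor end — a
  deterministic tie-break among the |g| equally consistent placements.
- **BRIDGE pair** — mates flanking the junction inside the unsequenced
  insert. A pair is concordant when both mates land on one chromosome
  within I_max (transcriptomic alignments are projected to genomic
  coordinates first); everything else is a BRIDGE candidate. Pairs where
  either mate is multimapped are not used as BRIDGE evidence, which keeps
  false discordance from ambiguous placements out of the candidate set.

## Alignment layer

Alignment is delegated through a backend interface. The default backend is
an internal seed-and-extend aligner: a sorted 20-mer index over the target
sequences; end-to-end placement verifies the full read with mismatches
only (up to 5); local mode extends every seed diagonal to the
maximum-scoring gapless run (match +2, mismatch −2) and keeps alignments
scoring above Score_max/3, where Score_max = 2 × read length. Gapless
extension means a read with an indel inside one segment is split at the
indel; the two co-linear pieces are splice-compatible and correctly
rejected as fusion evidence, costing a small fraction of junction reads at
Illumina indel rates. Reads are mapped to the transcriptome first (so
spliced reads place correctly), optionally to the genome (for intronic and
intergenic transcription), and only then locally. Mitochondrial
alignments are discarded by default. Any external SAM-emitting aligner can
replace the internal one via a command template, or pre-made SAM/BAM can
be ingested directly (bypass mode).

The insert-size model is the sample mean and standard deviation of
outer-distance insert sizes of concordant pairs, measured in the spliced
transcript frame when both mates map to one transcript (genomic outer
distance would count intron bases); pairs mapped in mixed frames are
excluded from the model.

## Clustering and rescue

Breakpoint-candidate alignments are clustered per chromosome by iterative
insertion: no overlap → new cluster; one overlap → join; several → merge
then join. The result is order-independent (verified exhaustively in the
tests). Clusters are then separated by direction to the breakpoint — the
side on which the junction lies, a function of alignment strand and the
member's role (SPLIT read order / BRIDGE orientation), written out as an
explicit table in `clusters.py` — and by breakpoint position:
single-linkage with chain-breaking at a 10 bp tolerance after sorting,
with the consensus breakpoint the most supported position (ties to the
smaller coordinate). One-pass separation after sorting is used; groups are
not re-merged if their means re-converge.

Unused local alignments (score > 50% of maximum, edit distance < 2) are
rescued: a candidate must intersect a host cluster consistently with its
direction and breakpoint, and its remaining read part (≥ 10 bases) must
realign — edit distance < 2, same score criterion on the part — against a
partner cluster's junction region at the partner breakpoint. For
BRIDGE-only hosts the search window extends by the insert reach
(mean + 3σ) on the junction side, and the resulting breakpoint is voted by
the amount of rescued evidence; breakpoints already fixed by SPLIT reads
are never moved.

Fusions are keyed by the unordered cluster pair holding a BPC's two
alignments. The 5'/3' order comes from read orientations when the library
is strand-specific; otherwise from the annotated gene strands at the two
breakpoints, with a genomic left-to-right tie-break (leftmost '+' gene
first). The transcribed strand at each partner follows from the cluster
side and the assigned role.

## Features and filtering

- *Mate consistency*: SPLIT support is removed when the mate has an
  alignment and it lies farther than I_max from both partners. Mates with
  no alignment do not disqualify a SPLIT (they may themselves span the
  junction); such SPLITs only lose the "mated" score bonus. This is the
  lenient of the two possible readings of the rule and costs nothing on
  the simulated data, where mates almost always place.
- *BRIDGE-only merging*: a fusion supported only by BRIDGEs is absorbed
  into a SPLIT-backed fusion whose partners lie within I_max on matching
  sides, so one event is not reported twice.
- *Multimap resolution*: reads supporting several fusions are iteratively
  assigned to the highest-scoring one (fixed point, ≤ 50 iterations, ties
  to the smallest cluster-id key). The fusion score weights unique mated
  SPLITs 3, unique SPLITs 2, multimapped SPLITs 1, BRIDGEs 1.
- *Metacluster homogeneity*: clusters of different fusions intersecting or
  within 1 kb form a metacluster; a fusion's weight is its supporting
  alignments over the metacluster total, minimum over its two sides. True
  fusions dominate their region; homology artifacts share it.
- *Coverage statistics*: fraction of distinct SPLIT footprints, deviation
  of the mean in-read breakpoint offset from mid-read (|mean − L/2|/L),
  and the requirement of at least one uniquely-mapping SPLIT when no
  BRIDGE support exists. Flanking proper-pair depth (200 bp windows) is
  reported as advisory only.
- *Homology*: the junction sequence is reconstructed following annotated
  splicing (intronic/intergenic/antisense sides fall back to genomic
  continuation) and locally aligned to genome and transcriptome; the best
  single contiguous score, normalised by the sequence's Score_max over a
  window symmetric about the junction, approaches 1 only when the "fusion"
  exists contiguously in the reference. Genuine chimeras sit near 0.5.
- *Insert validity*: each BRIDGE pair is placed on the reconstructed
  junction sequence (spliced frame) and its outer distance checked against
  the 3σ interval of the insert model; the valid fraction is the feature
  (1.0 when not applicable).
- *Strand concordance*: with a strand-specific protocol, the fraction of
  supporting alignments agreeing with the majority transcribed strand per
  partner; the antisense flag compares that majority with the annotated
  gene strand. Antisense fusions therefore keep high concordance and are
  flagged, not filtered.
- *Biotypes*: partners annotated only as pseudogene / processed transcript
  are discarded by default; intergenic partners are reported by default.
  Both are switches.

Default thresholds (all in `FilterThresholds`, persisted as a key=value
file): min_support 2, min_homogeneity 0.25, min_unique_split_fraction
0.05, max_breakpoint_offset_dev 0.25, max_homology_score 0.8,
min_valid_insert_ratio 0.5, min_strand_concordance 0.8 (stranded runs
only). They aim at a recall/precision compromise: support ≥ 2 suppresses
singleton artifacts, homogeneity 0.25 tolerates up to three co-located
isoforms before the weight rule bites, homology 0.8 leaves headroom over
the ≈0.5 score of genuine chimeras, and insert validity 0.5 tolerates a
minority of mismeasured bridges. Filtering is monotone in every threshold,
and all features are checkpointed so re-filtering needs no realignment.

Reports use 1-based inclusive coordinates; breakpoints are classified as
exon edge (exact by default; a slack parameter widens the match, since how
close "at the boundary" must be is a reporting choice), inside exon,
inside intron, or intergenic. Read-through calls require same chromosome,
shared annotated strand, transcriptional order and ≤ 200 kb separation
(configurable; the concept fixes no distance). Junction sequences default
to 500 bp flanks.

## Simulator

The simulator emulates a benchmark experiment on a synthetic reference:
the toy-reference generator writes a repeat-free multi-chromosome genome
(uniform random bases) with multi-exon genes — 3–8 exons of 100–300 bp,
introns 200–1800 bp (all below I_max), intergenic gaps 3–8 kb, random
strands, a small pseudogene fraction. Five fusion classes are drawn from
multi-exon protein-coding genes, 20 events per class per dataset, each
isoform assigned an integer coverage uniform on [1, 60]. Partner pairs are
drawn so the junction is not splice-explainable (different chromosome or
separation > I_max): a splice-compatible "fusion" is by construction
invisible to condition 1, and on a genome-scale reference such draws
essentially never occur by chance. Class-5 events carry two isoforms
sharing the donor junction; each isoform is a separate truth entry.

Reads are 75 bp pairs with fragment length Normal(300, 80) truncated to
[read length, transcript length], orientation fixed by the strandedness
mode, and an Illumina-like error model: substitution rate rising linearly
0.1% → 1% along the read, insertion/deletion rates 0.01%/0.02% (a declared
stand-in where exact error-model parameters are a free choice). Background
reads are drawn from the normal transcriptome with a synthetic log-normal
(μ=1, σ=1) expression profile, 25,000 pairs per dataset — the same order
as the fusion reads, a desk-scale choice that keeps a dataset near 50,000
pairs. All draws come from one seeded generator; identical seeds give
byte-identical outputs.

What the simulation does *not* emulate: repeats and homologous gene
families (so the homology and homogeneity filters are exercised but not
stressed), PCR/coverage bias, quality-score structure, template-switching
chimeras, and real splice-isoform complexity. Passing benchmarks here
show the detection and filtering machinery is correct and well calibrated
on clean data, not that real-genome precision would match.

## Evaluation

A prediction is a true positive when each partner's breakpoint lies within
20 bp of a planted junction; truth entries are matched at most once, and
the 5'/3' assignment may be swapped (partner-wise positional agreement is
what is scored; with unstranded data the order of an intergenic partner is
not identifiable). Recall = TP/(TP+FN), precision = TP/(TP+FP), reported
as NA when there are no predictions. The benchmark in
`scripts/acceptance.py` uses a ~5 Mb genome, 250 genes and three datasets
— problem sizes chosen so the whole study runs in about a minute while
keeping ≥ 100 events per dataset.

## Numerical and degenerate-input choices

- Local extension maximises the gapless score (Kadane on ±2); chance
  matches can over-extend past a junction by a few bases, so implied
  breakpoints scatter within ~8 bp of the truth and the 10 bp cluster
  tolerance plus consensus voting recovers the exact position.
- SPLIT candidate ranking for the 20-configuration cap: summed score, then
  fewer mismatches, then lexicographic locus order.
- Fewer than two concordant pairs → no insert model; BRIDGE-related
  features become inert rather than failing.
- Single-end input skips pair analysis entirely: no BRIDGEs, mate
  consistency is the identity.
- An empty prediction set gives recall 0 and undefined (NA) precision.

## Known limitations

- SPLITs from more than two local segments are out of scope; very short
  junction overhangs (< ~13 bp) fall below the local score threshold and
  are recoverable only through rescue.
- The internal aligner is mismatch-only end-to-end and gapless locally; it
  is built for clean short reads against modest references, not a
  replacement for a production aligner on a full mammalian genome.
- Fusion expression quantification is not attempted; reported junction
  sequences can feed external quantifiers.
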