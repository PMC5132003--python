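"""Annotation, classification and serialization of fusion calls.

One row per fusion, 1-based inclusive breakpoint coordinates, deterministic
sort order; the TSV round-trips losslessly through :func:`read_report`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .clusters import PutativeFusion
from .filters import FusionFeatures, Verdict
from .refdb import RegionAnnotation, TranscriptDB, revcomp

REPORT_COLUMNS = [
    "fusion_id",
    "gene_5p",
    "gene_3p",
    "chrom_5p",
    "pos_5p",
    "break_5p",
    "strand_5p",
    "chrom_3p",
    "pos_3p",
    "break_3p",
    "strand_3p",
    "n_split",
    "n_bridge",
    "score",
    "fusion_type",
    "homogeneity",
    "unique_split_fraction",
    "breakpoint_offset_dev",
    "has_unique_split",
    "flank_cov_5p",
    "flank_cov_3p",
    "homology_score",
    "valid_insert_ratio",
    "strand_concordance",
    "antisense_5p",
    "antisense_3p",
    "approximate_5p",
    "approximate_3p",
    "filter_status",
    "filter_reasons",
    "junction_seq",
]

_BOOL_COLS = [
    "has_unique_split",
    "antisense_5p",
    "antisense_3p",
    "approximate_5p",
    "approximate_3p",
]


@dataclass
class FusionRecord:
    fusion_id: str
    gene_5p: str
    gene_3p: str
    chrom_5p: str
    pos_5p: int  # 1-based inclusive
    break_5p: str
    strand_5p: str
    chrom_3p: str
    pos_3p: int
    break_3p: str
    strand_3p: str
    n_split: int
    n_bridge: int
    score: float
    fusion_type: str
    homogeneity: float
    unique_split_fraction: float
    breakpoint_offset_dev: float
    has_unique_split: bool
    flank_cov_5p: float
    flank_cov_3p: float
    homology_score: float
    valid_insert_ratio: float
    strand_concordance: float
    antisense_5p: bool
    antisense_3p: bool
    approximate_5p: bool
    approximate_3p: bool
    filter_status: str
    filter_reasons: str
    junction_seq: str = "."


def classify_fusion_type(
    chrom_5p: str,
    pos_5p: int,
    ann_5p: RegionAnnotation,
    chrom_3p: str,
    pos_3p: int,
    ann_3p: RegionAnnotation,
    read_through_distance: int = 200_000,
) -> str:
    """Primary chromosomal relation plus orthogonal region flags.

    Read-through: same chromosome, shared annotated strand, 5' partner
    preceding the 3' partner in transcriptional order within the distance
    limit (default 200 kb).
    """
    labels: List[str] = []
    if chrom_5p != chrom_3p:
        labels.append("inter-chromosomal")
    else:
        strands5 = set(ann_5p.strands)
        strands3 = set(ann_3p.strands)
        shared = strands5 & strands3
        rt = False
        for s in shared:
            before = pos_5p <= pos_3p if s == "+" else pos_5p >= pos_3p
            if before and abs(pos_3p - pos_5p) <= read_through_distance:
                rt = True
        labels.append("read-through" if rt else "intra-chromosomal-other")
    if "intergenic" in (ann_5p.category, ann_3p.category):
        labels.append("involving-intergenic")
    if "inside_intron" in (ann_5p.category, ann_3p.category):
        labels.append("involving-intron")
    return ";".join(labels)


def _portion_seq(fetch, chrom: str, blocks, strand: str) -> str:
    parts = []
    for a, b in blocks:
        s = fetch(chrom, a, b)
        parts.append(revcomp(s) if strand == "-" else s)
    return "".join(parts)


def _blocks_to(t, bp: int, upstream: bool):
    """Transcription-order genomic blocks of transcript ``t`` ending at
    (upstream=True) or starting at (False) position ``bp``; intronic
    breakpoints include the transcribed intron piece.  None if ``bp`` is
    outside the transcript body."""
    order = t.exons_in_transcription_order()
    plus = t.strand == "+"
    for i, (a, b) in enumerate(order):
        if a <= bp < b:
            if upstream:
                blocks = [tuple(e) for e in order[:i]]
                blocks.append((a, bp + 1) if plus else (bp, b))
            else:
                blocks = [(bp, b) if plus else (a, bp + 1)]
                blocks += [tuple(e) for e in order[i + 1 :]]
            return blocks
        if i + 1 < len(order):
            na, nb = order[i + 1]
            ia, ib = (b, na) if plus else (nb, a)
            if ia <= bp < ib:
                if upstream:
                    blocks = [tuple(e) for e in order[: i + 1]]
                    blocks.append((ia, bp + 1) if plus else (bp, ib))
                else:
                    blocks = [(bp, ib) if plus else (ia, bp + 1)]
                    blocks += [tuple(e) for e in order[i + 1 :]]
                return blocks
    return None


def transcribed_flank(
    db,
    fetch,
    contig_length,
    chrom: str,
    bp: int,
    strand: str,
    flank: int,
    five_prime: bool,
) -> Tuple[str, bool]:
    """Transcribed sequence context on one side of a junction.

    When an annotated transcript on the inferred transcribed strand covers
    the breakpoint, the flank follows its splicing (introns removed,
    intronic breakpoints keep the transcribed intron piece); otherwise the
    genomic continuation is used.  Returns (sequence, truncated)."""
    t = None
    if db is not None:
        cands = sorted(
            (c for c in db.transcripts_overlapping(chrom, bp, bp + 1) if c.strand == strand),
            key=lambda c: c.transcript_id,
        )
        t = cands[0] if cands else None
    if t is not None:
        blocks = _blocks_to(t, bp, upstream=five_prime)
        if blocks is not None:
            seq = _portion_seq(fetch, chrom, blocks, t.strand)
            if five_prime:
                return seq[-flank:], len(seq) < flank
            return seq[:flank], len(seq) < flank
    clen = contig_length(chrom)
    plus = strand == "+"
    if five_prime == plus:
        a, b = bp - flank + 1, bp + 1
        seq = fetch(chrom, max(0, a), b)
        return (seq if plus else revcomp(seq)), a < 0
    a, b = bp, bp + flank
    seq = fetch(chrom, a, min(clen, b))
    return (seq if plus else revcomp(seq)), b > clen


def reconstruct_junction_sequence(
    fusion: PutativeFusion, fetch, contig_length, flank: int = 500, db=None
) -> Tuple[str, bool]:
    """Strand-aware junction sequence: ``flank`` transcribed bases ending at
    the 5' breakpoint followed by ``flank`` transcribed bases starting at
    the 3' breakpoint; the junction sits at offset ``len(5' part)``.
    Splicing follows the annotation when available (see
    :func:`transcribed_flank`).  Returns (sequence, junction offset,
    truncation flag)."""
    if fusion.cluster_5p.breakpoint_pos is None or fusion.cluster_3p.breakpoint_pos is None:
        return "", 0, True
    s5, t5 = transcribed_flank(
        db, fetch, contig_length, fusion.cluster_5p.chrom,
        fusion.cluster_5p.breakpoint_pos, fusion.strand_5p, flank, True,
    )
    s3, t3 = transcribed_flank(
        db, fetch, contig_length, fusion.cluster_3p.chrom,
        fusion.cluster_3p.breakpoint_pos, fusion.strand_3p, flank, False,
    )
    return s5 + s3, len(s5), t5 or t3


def build_record(
    fusion: PutativeFusion,
    features: FusionFeatures,
    verdict: Verdict,
    score: float,
    db: Optional[TranscriptDB],
    edge_slack: int = 0,
    junction_seq: str = ".",
) -> FusionRecord:
    """Assemble the reportable record for one putative fusion."""
    c5, c3 = fusion.cluster_5p, fusion.cluster_3p
    if db is not None and c5.breakpoint_pos is not None:
        ann5 = db.annotate_position(c5.chrom, c5.breakpoint_pos, edge_slack)
    else:
        ann5 = RegionAnnotation("intergenic")
    if db is not None and c3.breakpoint_pos is not None:
        ann3 = db.annotate_position(c3.chrom, c3.breakpoint_pos, edge_slack)
    else:
        ann3 = RegionAnnotation("intergenic")
    ftype = classify_fusion_type(
        c5.chrom, c5.breakpoint_pos or 0, ann5, c3.chrom, c3.breakpoint_pos or 0, ann3
    )
    return FusionRecord(
        fusion_id=f"F{fusion.id}",
        gene_5p=",".join(ann5.gene_names) or "INTERGENIC",
        gene_3p=",".join(ann3.gene_names) or "INTERGENIC",
        chrom_5p=c5.chrom,
        pos_5p=(c5.breakpoint_pos or 0) + 1,
        break_5p=ann5.category,
        strand_5p=fusion.strand_5p,
        chrom_3p=c3.chrom,
        pos_3p=(c3.breakpoint_pos or 0) + 1,
        break_3p=ann3.category,
        strand_3p=fusion.strand_3p,
        n_split=fusion.n_split,
        n_bridge=fusion.n_bridge,
        score=score,
        fusion_type=ftype,
        homogeneity=round(features.homogeneity_weight, 6),
        unique_split_fraction=round(features.unique_split_fraction, 6),
        breakpoint_offset_dev=round(features.mean_breakpoint_offset_dev, 6),
        has_unique_split=features.has_unique_split,
        flank_cov_5p=round(features.flank_coverage_5p, 4),
        flank_cov_3p=round(features.flank_coverage_3p, 4),
        homology_score=round(features.homology_score, 6),
        valid_insert_ratio=round(features.valid_insert_ratio, 6),
        strand_concordance=round(features.strand_concordance, 6),
        antisense_5p=features.antisense_5p,
        antisense_3p=features.antisense_3p,
        approximate_5p=c5.approximate,
        approximate_3p=c3.approximate,
        filter_status="PASS" if verdict.passed else "FAIL",
        filter_reasons=";".join(verdict.reasons) or ".",
        junction_seq=junction_seq,
    )


def write_report(records: Sequence[FusionRecord], out_path: str) -> None:
    """Write the fusion report TSV (header always present, stable column
    order, rows sorted by 5' then 3' coordinate)."""
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["chrom_5p", "pos_5p", "chrom_3p", "pos_3p", "fusion_id"]
        ).reset_index(drop=True)
    df.to_csv(out_path, sep="\t", index=False)


def read_report(path: str) -> pd.DataFrame:
    """Parse a report written by :func:`write_report` losslessly."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom_5p": str, "chrom_3p": str},
                     keep_default_na=False, na_values=[])
    for col in _BOOL_COLS:
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
        else:
            df[col] = df[col].astype(bool)
    return df


def records_from_dataframe(df: pd.DataFrame) -> List[FusionRecord]:
    return [FusionRecord(**{k: row[k] for k in REPORT_COLUMNS}) for _, row in df.iterrows()]


def write_support_alignments(
    fusions: Sequence[PutativeFusion],
    contig_lengths: Dict[str, int],
    out_path: str,
) -> int:
    """Write the alignments of supporting reads, tagged by fusion id.

    One record per breakpoint candidate (its leading alignment; a SPLIT's
    second segment is encoded as the soft-clipped remainder).  Output is
    SAM or BAM by file extension; returns the number of records written.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(l)} for n, l in sorted(contig_lengths.items())],
    }
    mode = "wb" if str(out_path).endswith(".bam") else "w"
    n = 0
    with pysam.AlignmentFile(out_path, mode, header=dict(header)) as fh:
        tid = {n_: i for i, (n_, _l) in enumerate(sorted(contig_lengths.items()))}
        for f in fusions:
            for b in f.bpcs:
                rec = pysam.AlignedSegment()
                if b.kind == "split" and b.split is not None:
                    a = b.split.first
                    rec.query_name = a.read_id
                    rec.reference_id = tid[a.chrom]
                    rec.reference_start = a.p
                    rec.flag = 16 if a.strand == "-" else 0
                    cigar = []
                    if a.q:
                        cigar.append((4, a.q))
                    cigar.append((0, a.length))
                    tail = a.read_length - a.q_end
                    if tail:
                        cigar.append((4, tail))
                    rec.cigartuples = cigar if a.strand == "+" else cigar[::-1]
                else:
                    a1 = b.bridge[0]
                    rec.query_name = a1.read_id
                    rec.reference_id = tid[a1.chrom]
                    rec.reference_start = a1.start
                    rec.flag = (16 if a1.strand == "-" else 0) | 0x1 | 0x40
                    rec.cigartuples = [(0, a1.end - a1.start)]
                rec.mapping_quality = 60
                rec.set_tag("fz", f"F{f.id}")
                fh.write(rec)
                n += 1
    return n
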