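"""Fusion-transcript simulation and evaluation.

Implements a reproducible simulation design for benchmarking fusion
callers: five classes of fusion events (1 - both breakpoints at exon
boundaries; 2 - breakpoint inside an exon; 3 - breakpoint inside an
intron; 4 - one partner from an intergenic region; 5 - several
alternatively spliced isoforms with exon-boundary breakpoints), chimeric
transcript construction, strand-aware paired-end read simulation with an
Illumina-like error model (substitution rate rising along the read plus
rare indels), background reads from the normal transcriptome, and a
recall/precision evaluator with a per-partner breakpoint tolerance.

A companion toy-reference generator synthesises a repeat-free
multi-chromosome genome with multi-exon gene annotations so that the whole
study runs without any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .refdb import TranscriptDB, TranscriptModel, revcomp

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# toy reference generator


def make_toy_reference(
    out_fasta: str,
    out_gtf: str,
    n_chroms: int = 5,
    chrom_len: int = 1_000_000,
    genes_per_chrom: int = 50,
    seed: int = 0,
    include_mito: bool = False,
    pseudogene_fraction: float = 0.04,
) -> None:
    """Write a random repeat-free genome FASTA plus a multi-exon GTF.

    Genes are laid out left to right with intergenic gaps of 3-8 kb,
    3-8 exons of 100-300 bp separated by introns of 200-1800 bp (all well
    below the default maximum intron size), random strand, and mostly
    protein_coding biotypes with a small pseudogene fraction.
    """
    rng = np.random.default_rng(seed)
    gtf_lines: List[str] = []
    with open(out_fasta, "w") as fa:
        for ci in range(n_chroms):
            chrom = f"chr{ci + 1}"
            seq = "".join(BASES[rng.integers(0, 4, chrom_len)])
            fa.write(f">{chrom}\n")
            for i in range(0, chrom_len, 80):
                fa.write(seq[i : i + 80] + "\n")
            cursor = int(rng.integers(2_000, 5_000))
            gi = 0
            while gi < genes_per_chrom:
                n_exons = int(rng.integers(3, 9))
                exon_lens = rng.integers(100, 301, n_exons)
                intron_lens = rng.integers(200, 1801, max(0, n_exons - 1))
                span = int(exon_lens.sum() + intron_lens.sum())
                if cursor + span + 3_000 > chrom_len:
                    break
                strand = "+" if rng.random() < 0.5 else "-"
                biotype = (
                    "processed_pseudogene"
                    if rng.random() < pseudogene_fraction
                    else "protein_coding"
                )
                gid = f"G{ci + 1}_{gi + 1}"
                tid = f"T{ci + 1}_{gi + 1}"
                pos = cursor
                for ei in range(n_exons):
                    a, b = pos, pos + int(exon_lens[ei])
                    gtf_lines.append(
                        "\t".join(
                            [
                                chrom,
                                "toy",
                                "exon",
                                str(a + 1),
                                str(b),
                                ".",
                                strand,
                                ".",
                                f'gene_id "{gid}"; transcript_id "{tid}"; '
                                f'gene_name "{gid}"; gene_biotype "{biotype}"; '
                                f'exon_number "{ei + 1}";',
                            ]
                        )
                    )
                    pos = b + (int(intron_lens[ei]) if ei < n_exons - 1 else 0)
                cursor += span + int(rng.integers(3_000, 8_000))
                gi += 1
        if include_mito:
            fa.write(">chrM\n")
            mseq = "".join(BASES[rng.integers(0, 4, 16_000)])
            for i in range(0, len(mseq), 80):
                fa.write(mseq[i : i + 80] + "\n")
    with open(out_gtf, "w") as gf:
        gf.write("\n".join(gtf_lines) + "\n")


# ---------------------------------------------------------------------------
# fusion specs


@dataclass
class FusionSpec:
    """Truth record for one simulated fusion junction (one isoform)."""

    fusion_id: str
    fusion_class: int  # 1-5
    gene_5p: str
    gene_3p: str
    chrom_5p: str
    pos_5p: int  # 0-based coordinate of the last transcribed 5' base
    chrom_3p: str
    pos_3p: int  # 0-based coordinate of the first transcribed 3' base
    strand_5p: str
    strand_3p: str
    blocks_5p: List[Tuple[int, int]] = field(default_factory=list)  # transcription order
    blocks_3p: List[Tuple[int, int]] = field(default_factory=list)
    coverage: int = 10
    isoform: int = 1


def _portion_sequence(db: TranscriptDB, chrom: str, blocks: Sequence[Tuple[int, int]], strand: str) -> str:
    parts = []
    for a, b in blocks:
        s = db.fetch(chrom, a, b)
        parts.append(revcomp(s) if strand == "-" else s)
    return "".join(parts)


def _donor_cut(blocks_tx_order: List[Tuple[int, int]], strand: str) -> int:
    """Genomic coordinate of the last transcribed base of a 5' portion."""
    a, b = blocks_tx_order[-1]
    return b - 1 if strand == "+" else a


def _acceptor_cut(blocks_tx_order: List[Tuple[int, int]], strand: str) -> int:
    """Genomic coordinate of the first transcribed base of a 3' portion."""
    a, b = blocks_tx_order[0]
    return a if strand == "+" else b - 1


def _exon_prefix(t: TranscriptModel, n: int, cut_last: Optional[int] = None) -> List[Tuple[int, int]]:
    """First ``n`` exons in transcription order; optionally the last one is
    cut after ``cut_last`` transcribed bases."""
    blocks = [tuple(e) for e in t.exons_in_transcription_order()[:n]]
    if cut_last is not None:
        a, b = blocks[-1]
        if t.strand == "+":
            blocks[-1] = (a, a + cut_last)
        else:
            blocks[-1] = (b - cut_last, b)
    return blocks


def _exon_suffix(t: TranscriptModel, start: int, cut_first: Optional[int] = None) -> List[Tuple[int, int]]:
    """Exons from index ``start`` (transcription order) onward; optionally
    the first one starts ``cut_first`` bases into the exon."""
    blocks = [tuple(e) for e in t.exons_in_transcription_order()[start:]]
    if cut_first is not None:
        a, b = blocks[0]
        if t.strand == "+":
            blocks[0] = (a + cut_first, b)
        else:
            blocks[0] = (a, b - cut_first)
    return blocks


def _intron_after(t: TranscriptModel, exon_idx: int) -> Tuple[int, int]:
    """Intron following exon ``exon_idx`` in transcription order."""
    order = t.exons_in_transcription_order()
    a, b = order[exon_idx]
    c, d = order[exon_idx + 1]
    return (b, c) if t.strand == "+" else (d, a)


def _splice_distant(t1: TranscriptModel, t2: TranscriptModel, I_max: int) -> bool:
    """Partner pairs whose junction could pass for a normal splice (same
    chromosome within the maximum intron size) are not drawn."""
    if t1.chrom != t2.chrom:
        return True
    gap = max(0, max(t1.start, t2.start) - min(t1.end, t2.end))
    return gap > I_max


def generate_fusion_annotations(
    db: TranscriptDB,
    n_per_class: int = 20,
    seed: int = 0,
    min_intergenic_gap: int = 2_000,
    coverage_range: Tuple[int, int] = (1, 60),
    I_max: int = 20_000,
) -> List[FusionSpec]:
    """Draw random fusion specs, ``n_per_class`` for each of the 5 classes.

    Gene pairs are sampled without replacement from multi-exon genes;
    class-4 intergenic partners come from annotated gaps of at least
    ``min_intergenic_gap``; class-5 specs carry two spliced isoforms that
    are scored as separate truth entries.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    genes = {
        g: txs[0]
        for g, txs in sorted(db.genes().items())
        if len(txs[0].exons) >= 3 and txs[0].biotype == "protein_coding"
    }
    pool = sorted(genes)
    need = 2 * 4 * n_per_class + n_per_class  # class 4 uses one gene only
    if len(pool) < need:
        raise ValueError(
            f"annotation too small: need {need} multi-exon genes, have {len(pool)}"
        )
    order = list(rng.permutation(pool))

    # intergenic gaps per chromosome, from gene spans
    gaps: List[Tuple[str, int, int]] = []
    by_chrom: Dict[str, List[TranscriptModel]] = {}
    for t in db:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom in sorted(by_chrom):
        txs = sorted(by_chrom[chrom], key=lambda t: t.start)
        for t1, t2 in zip(txs, txs[1:]):
            if t2.start - t1.end >= min_intergenic_gap:
                gaps.append((chrom, t1.end + 200, t2.start - 200))
    if not gaps:
        raise ValueError("no intergenic gaps wide enough for class-4 fusions")

    def next_pair() -> Tuple[TranscriptModel, TranscriptModel]:
        while True:
            if len(order) < 2:
                raise ValueError("gene pool exhausted while drawing fusion pairs")
            g1 = order.pop()
            # find a partner that is not splice-compatible with g1
            for k in range(len(order) - 1, -1, -1):
                if _splice_distant(genes[g1], genes[order[k]], I_max):
                    g2 = order.pop(k)
                    return genes[g1], genes[g2]
            # no valid partner left for g1; drop it and retry
            continue

    def cov() -> int:
        return int(rng.integers(coverage_range[0], coverage_range[1] + 1))

    specs: List[FusionSpec] = []
    counter = 0
    for cls in (1, 2, 3, 4, 5):
        for _ in range(n_per_class):
            counter += 1
            fid = f"FUS{counter:03d}"
            if cls == 4:
                t5 = genes[order.pop()]
                for _attempt in range(100):
                    chrom, lo, hi = gaps[int(rng.integers(0, len(gaps)))]
                    if chrom != t5.chrom or min(
                        abs(lo - t5.end), abs(t5.start - hi)
                    ) > I_max:
                        break
                seg_len = int(rng.integers(300, 801))
                if hi - lo <= seg_len:
                    seg_start = lo
                    seg_len = max(200, hi - lo)
                else:
                    seg_start = int(rng.integers(lo, hi - seg_len))
                seg_strand = "+" if rng.random() < 0.5 else "-"
                i = int(rng.integers(1, len(t5.exons)))
                b5 = _exon_prefix(t5, i)
                b3 = [(seg_start, seg_start + seg_len)]
                specs.append(
                    FusionSpec(
                        fusion_id=fid,
                        fusion_class=4,
                        gene_5p=t5.gene_id,
                        gene_3p=f"intergenic:{chrom}:{seg_start}-{seg_start + seg_len}",
                        chrom_5p=t5.chrom,
                        pos_5p=_donor_cut(b5, t5.strand),
                        chrom_3p=chrom,
                        pos_3p=_acceptor_cut(b3, seg_strand),
                        strand_5p=t5.strand,
                        strand_3p=seg_strand,
                        blocks_5p=b5,
                        blocks_3p=b3,
                        coverage=cov(),
                    )
                )
                continue
            t5, t3 = next_pair()
            n5, n3 = len(t5.exons), len(t3.exons)
            i = int(rng.integers(1, n5))  # donor keeps exons [0, i)
            j = int(rng.integers(1, n3))  # acceptor starts at exon j
            if cls == 1:
                b5 = _exon_prefix(t5, i)
                b3 = _exon_suffix(t3, j)
            elif cls == 2:
                # one or both breakpoints strictly inside an exon
                which = int(rng.integers(0, 3))  # 0: donor, 1: acceptor, 2: both
                e5 = t5.exons_in_transcription_order()[i - 1]
                e3 = t3.exons_in_transcription_order()[j]
                cut5 = int(rng.integers(20, (e5[1] - e5[0]) - 19)) if which in (0, 2) else None
                cut3 = int(rng.integers(20, (e3[1] - e3[0]) - 19)) if which in (1, 2) else None
                b5 = _exon_prefix(t5, i, cut_last=cut5)
                b3 = _exon_suffix(t3, j, cut_first=cut3)
            elif cls == 3:
                # intronic breakpoint on the donor or the acceptor side
                if rng.random() < 0.5:
                    ia, ib = _intron_after(t5, i - 1)
                    ilen = ib - ia
                    u = int(rng.integers(30, max(31, ilen - 29)))
                    # transcribed intron prefix: enters from the exon-i side
                    b5 = _exon_prefix(t5, i) + (
                        [(ia, ia + u)] if t5.strand == "+" else [(ib - u, ib)]
                    )
                    b3 = _exon_suffix(t3, j)
                else:
                    ia, ib = _intron_after(t3, j - 1)
                    ilen = ib - ia
                    u = int(rng.integers(30, max(31, ilen - 29)))
                    b5 = _exon_prefix(t5, i)
                    # transcribed intron suffix: runs into exon j
                    b3 = (
                        [(ib - u, ib)] if t3.strand == "+" else [(ia, ia + u)]
                    ) + _exon_suffix(t3, j)
            else:  # class 5: two isoforms sharing the donor junction
                b5 = _exon_prefix(t5, i)
                j2 = j + 1 if j + 1 < n3 else j - 1
                if j2 < 1:
                    j2 = j + 1
                for iso, jj in enumerate(sorted({j, j2}), start=1):
                    b3 = _exon_suffix(t3, jj)
                    specs.append(
                        FusionSpec(
                            fusion_id=fid,
                            fusion_class=5,
                            gene_5p=t5.gene_id,
                            gene_3p=t3.gene_id,
                            chrom_5p=t5.chrom,
                            pos_5p=_donor_cut(b5, t5.strand),
                            chrom_3p=t3.chrom,
                            pos_3p=_acceptor_cut(b3, t3.strand),
                            strand_5p=t5.strand,
                            strand_3p=t3.strand,
                            blocks_5p=b5,
                            blocks_3p=b3,
                            coverage=cov(),
                            isoform=iso,
                        )
                    )
                continue
            specs.append(
                FusionSpec(
                    fusion_id=fid,
                    fusion_class=cls,
                    gene_5p=t5.gene_id,
                    gene_3p=t3.gene_id,
                    chrom_5p=t5.chrom,
                    pos_5p=_donor_cut(b5, t5.strand),
                    chrom_3p=t3.chrom,
                    pos_3p=_acceptor_cut(b3, t3.strand),
                    strand_5p=t5.strand,
                    strand_3p=t3.strand,
                    blocks_5p=b5,
                    blocks_3p=b3,
                    coverage=cov(),
                )
            )
    return specs


def build_fusion_transcripts(specs: Sequence[FusionSpec], db: TranscriptDB) -> Dict[str, str]:
    """Chimeric transcript per spec (one per isoform): spliced 5' portion
    joined to the spliced 3' portion at the junction.  Keys encode the
    truth: ``fusionid|isoform|junction_offset``."""
    out: Dict[str, str] = {}
    for s in specs:
        s5 = _portion_sequence(db, s.chrom_5p, s.blocks_5p, s.strand_5p)
        s3 = _portion_sequence(db, s.chrom_3p, s.blocks_3p, s.strand_3p)
        out[f"{s.fusion_id}|{s.isoform}|{len(s5)}"] = s5 + s3
    return out


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimReadParams:
    read_len: int = 75
    frag_mean: float = 300.0
    frag_sd: float = 80.0
    sub_rate_start: float = 0.001  # substitution rate at the 5' end of a read
    sub_rate_end: float = 0.01  # ... rising linearly to the 3' end
    ins_rate: float = 0.0001
    del_rate: float = 0.0002
    strandedness: str = "none"  # none | forward | reverse
    seed: int = 0


@dataclass
class SimulatedPairs:
    names: List[str]
    reads1: List[str]
    reads2: List[str]


def _apply_errors(reads: List[str], params: SimReadParams, rng: np.random.Generator) -> List[str]:
    if not reads:
        return reads
    L = params.read_len
    arr = np.vstack([np.frombuffer(r.encode(), dtype=np.uint8) for r in reads])
    rates = np.linspace(params.sub_rate_start, params.sub_rate_end, L)
    sub_mask = rng.random(arr.shape) < rates
    if sub_mask.any():
        # substitute with a uniformly drawn different base
        lut = {65: "CGT", 67: "AGT", 71: "ACT", 84: "ACG"}
        idx = np.nonzero(sub_mask)
        repl = rng.integers(0, 3, len(idx[0]))
        vals = arr[idx]
        arr[idx] = [ord(lut.get(v, "ACG")[r]) for v, r in zip(vals, repl)]
    out = [bytes(row).decode() for row in arr]
    # rare indels: shift the read, refill the tail with random bases
    indel_p = L * (params.ins_rate + params.del_rate)
    hit = np.nonzero(rng.random(len(out)) < indel_p)[0]
    for i in hit:
        pos = int(rng.integers(1, L - 1))
        s = out[i]
        if rng.random() < params.ins_rate / (params.ins_rate + params.del_rate):
            s = s[:pos] + str(BASES[rng.integers(0, 4)]) + s[pos : L - 1]
        else:
            s = s[:pos] + s[pos + 1 :] + str(BASES[rng.integers(0, 4)])
        out[i] = s
    return out


def simulate_reads(
    transcripts: Dict[str, str],
    coverages: Dict[str, float],
    params: SimReadParams,
    rng: Optional[np.random.Generator] = None,
    name_prefix: str = "sim",
) -> SimulatedPairs:
    """Paired-end reads from transcript sequences at the assigned coverage.

    Pairs per transcript: round(coverage * length / (2 * read_len)).
    Fragment lengths are Normal(frag_mean, frag_sd) truncated to
    [read_len, transcript length]; errors follow the Illumina-like model.
    ``strandedness`` fixes which mate carries the transcript sense.
    Transcripts shorter than one read are skipped with a warning.
    """
    import logging

    rng = rng if rng is not None else np.random.default_rng(params.seed)
    L = params.read_len
    names: List[str] = []
    r1: List[str] = []
    r2: List[str] = []
    for tx in sorted(transcripts):
        seq = transcripts[tx]
        tlen = len(seq)
        if tlen < L:
            logging.getLogger(__name__).warning("transcript %s shorter than a read; skipped", tx)
            continue
        n_pairs = int(round(coverages.get(tx, 0.0) * tlen / (2 * L)))
        if n_pairs <= 0:
            continue
        frags = np.clip(
            np.rint(rng.normal(params.frag_mean, params.frag_sd, n_pairs)), L, tlen
        ).astype(int)
        starts = (rng.random(n_pairs) * (tlen - frags + 1)).astype(int)
        for i in range(n_pairs):
            a, fl_ = int(starts[i]), int(frags[i])
            frag = seq[a : a + fl_]
            sense = frag[:L]
            anti = revcomp(frag[-L:])
            if params.strandedness == "forward":
                m1, m2 = sense, anti
            elif params.strandedness == "reverse":
                m1, m2 = anti, sense
            else:
                m1, m2 = (sense, anti) if rng.random() < 0.5 else (anti, sense)
            names.append(f"{name_prefix}:{tx.split('|')[0]}:{len(names)}")
            r1.append(m1)
            r2.append(m2)
    r1 = _apply_errors(r1, params, rng)
    r2 = _apply_errors(r2, params, rng)
    return SimulatedPairs(names=names, reads1=r1, reads2=r2)


def add_background_reads(
    db: TranscriptDB,
    params: SimReadParams,
    total_pairs: int,
    rng: Optional[np.random.Generator] = None,
    profile: Optional[Dict[str, float]] = None,
) -> SimulatedPairs:
    """Background reads from the normal (non-fusion) transcriptome.

    Genes are weighted by ``profile`` (default: a synthetic log-normal
    expression profile, mu=1 sigma=1) and ``total_pairs`` read pairs are
    apportioned by multinomial draw.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    genes = sorted(db.genes())
    txs = {g: db.genes()[g][0].transcript_id for g in genes}
    if profile is None:
        w = rng.lognormal(mean=1.0, sigma=1.0, size=len(genes))
        profile = dict(zip(genes, w))
    weights = np.array([max(0.0, profile.get(g, 0.0)) for g in genes], dtype=float)
    if weights.sum() <= 0 or total_pairs <= 0:
        return SimulatedPairs([], [], [])
    counts = rng.multinomial(total_pairs, weights / weights.sum())
    seqs = {}
    covs = {}
    L = params.read_len
    for g, n in zip(genes, counts):
        if n == 0:
            continue
        seq = db.transcript_sequence(txs[g])
        if len(seq) < L:
            continue
        seqs[txs[g]] = seq
        # invert the pair-count formula so simulate_reads emits exactly n
        covs[txs[g]] = n * 2 * L / len(seq)
    return simulate_reads(seqs, covs, params, rng=rng, name_prefix="bg")


def write_fastq_pair(sim: SimulatedPairs, path1: str, path2: str) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, a, b in zip(sim.names, sim.reads1, sim.reads2):
            f1.write(f"@{name}/1\n{a}\n+\n{'I' * len(a)}\n")
            f2.write(f"@{name}/2\n{b}\n+\n{'I' * len(b)}\n")


def merge_pairs(*sims: SimulatedPairs) -> SimulatedPairs:
    out = SimulatedPairs([], [], [])
    for s in sims:
        out.names.extend(s.names)
        out.reads1.extend(s.reads1)
        out.reads2.extend(s.reads2)
    return out


# ---------------------------------------------------------------------------
# truth I/O and evaluation


TRUTH_COLUMNS = [
    "fusion_id",
    "isoform",
    "fusion_class",
    "gene_5p",
    "gene_3p",
    "chrom_5p",
    "pos_5p",
    "chrom_3p",
    "pos_3p",
    "strand_5p",
    "strand_3p",
    "coverage",
]


def write_truth(specs: Sequence[FusionSpec], path: str) -> None:
    """Truth table TSV; breakpoint coordinates 1-based inclusive, matching
    the report convention."""
    rows = []
    for s in specs:
        d = dataclasses.asdict(s)
        d["pos_5p"] = s.pos_5p + 1
        d["pos_3p"] = s.pos_3p + 1
        rows.append({k: d[k] for k in TRUTH_COLUMNS})
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom_5p": str, "chrom_3p": str})


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    recall: float
    precision: Optional[float]  # None when there are no predictions
    per_class_recall: Dict[int, float]


def evaluate_predictions(
    truth: pd.DataFrame, predictions: pd.DataFrame, tol: int = 20
) -> EvalResult:
    """Score predictions against the truth table.

    A prediction is a true positive when, for each fusion partner, its
    breakpoint lies within ``tol`` bases of the exact junction point (the
    5'/3' assignment may be swapped).  Each truth entry (isoforms count
    separately) is matched at most once; unmatched predictions are false
    positives, unmatched truths false negatives.
    """
    t_entries = [
        (str(r.chrom_5p), int(r.pos_5p), str(r.chrom_3p), int(r.pos_3p), int(r.fusion_class))
        for r in truth.itertuples()
    ]
    matched = [False] * len(t_entries)
    tp = fp = 0
    cls_total: Dict[int, int] = {}
    cls_hit: Dict[int, int] = {}
    for _c5, _p5, _c3, _p3, cls in t_entries:
        cls_total[cls] = cls_total.get(cls, 0) + 1

    def near(c1, p1, c2, p2):
        return c1 == c2 and abs(p1 - p2) <= tol

    preds = [
        (str(r.chrom_5p), int(r.pos_5p), str(r.chrom_3p), int(r.pos_3p))
        for r in predictions.itertuples()
    ]
    for c5, p5, c3, p3 in preds:
        hit = None
        for i, (tc5, tp5, tc3, tp3, _cls) in enumerate(t_entries):
            if matched[i]:
                continue
            if (near(c5, p5, tc5, tp5) and near(c3, p3, tc3, tp3)) or (
                near(c5, p5, tc3, tp3) and near(c3, p3, tc5, tp5)
            ):
                hit = i
                break
        if hit is None:
            fp += 1
        else:
            matched[hit] = True
            tp += 1
            cls = t_entries[hit][4]
            cls_hit[cls] = cls_hit.get(cls, 0) + 1
    fn = matched.count(False)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else None
    per_class = {
        c: (cls_hit.get(c, 0) / n if n else 0.0) for c, n in sorted(cls_total.items())
    }
    return EvalResult(tp=tp, fp=fp, fn=fn, recall=recall, precision=precision,
                      per_class_recall=per_class)
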