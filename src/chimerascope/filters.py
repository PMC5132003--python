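"""Refinement and filtering of putative fusions.

After clustering, each putative fusion is refined (mate-pair consistency,
merging of BRIDGE-only neighbours, multimapped-read resolution) and scored
on a feature vector: metacluster homogeneity, SPLIT coverage statistics,
junction-sequence homology against the reference, BRIDGE insert validity
under the 3-sigma rule, strand concordance, and partner biotypes.  The
final verdict applies configurable thresholds; every violated threshold is
enumerated so that re-filtering from saved features needs no realignment.

Strand concordance here is the internal consistency of the supporting
reads with the library protocol: the fraction of supporting alignments
that agree with the majority transcribed strand at each partner.  The
antisense flag compares that majority strand with the annotated gene
strand, so genuinely antisense fusions keep a high concordance and are
flagged rather than filtered.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, fields
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .alignment import AlignScoring, InsertSizeModel
from .clusters import (
    BreakpointCandidate,
    Cluster,
    PutativeFusion,
    _flip,
    read_is_sense,
)


@dataclass
class FilterThresholds:
    """Filtering limits; defaults compromise between recall and precision."""

    min_support: int = 2
    min_homogeneity: float = 0.25
    min_unique_split_fraction: float = 0.05
    max_breakpoint_offset_dev: float = 0.25
    max_homology_score: float = 0.8
    min_valid_insert_ratio: float = 0.5
    min_strand_concordance: float = 0.8
    allow_intergenic: bool = True
    allow_discarded_biotypes: bool = False

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def load(cls, path: str) -> "FilterThresholds":
        kwargs = {}
        casts = {f.name: f.type for f in fields(cls)}
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, val = line.split("=", 1)
            key = key.strip()
            if key not in casts:
                raise ValueError(f"unknown threshold {key!r}")
            if casts[key] in ("bool", bool):
                kwargs[key] = val.strip().lower() in ("1", "true", "yes")
            elif casts[key] in ("int", int):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)


@dataclass
class ScoreWeights:
    """Fusion-score weights by supporting-read class."""

    unique_split_mated: float = 3.0
    unique_split: float = 2.0
    multimapped_split: float = 1.0
    bridge: float = 1.0


@dataclass
class FusionFeatures:
    homogeneity_weight: float = 1.0
    unique_split_fraction: float = 1.0
    mean_breakpoint_offset_dev: float = 0.0
    has_unique_split: bool = False
    flank_coverage_5p: float = 0.0
    flank_coverage_3p: float = 0.0
    homology_score: float = 0.0
    valid_insert_ratio: float = 1.0
    strand_concordance: float = 1.0
    antisense_5p: bool = False
    antisense_3p: bool = False
    biotypes_5p: Tuple[str, ...] = ()
    biotypes_3p: Tuple[str, ...] = ()
    intergenic_5p: bool = False
    intergenic_3p: bool = False


# ---------------------------------------------------------------------------
# refinement


def _near(chrom_a: str, span_a: Tuple[int, int], chrom_b: str, span_b: Tuple[int, int], d: int) -> bool:
    if chrom_a != chrom_b:
        return False
    gap = max(0, max(span_a[0], span_b[0]) - min(span_a[1], span_b[1]))
    return gap <= d


def enforce_split_mate_consistency(
    fusion: PutativeFusion,
    mate_locations: Dict[Tuple[str, int], List[Tuple[str, int, int]]],
    I_max: int = 20_000,
    paired: bool = True,
) -> PutativeFusion:
    """Drop SPLIT support whose mate demonstrably maps away from both
    partner loci (farther than I_max); mates with no known location are
    kept but the SPLIT loses its 'mated' score bonus.  No-op for
    single-end data."""
    if not paired:
        for b in fusion.splits:
            b.mate_consistent = None
        return fusion
    spans = [
        (fusion.cluster_5p.chrom, fusion.cluster_5p.span),
        (fusion.cluster_3p.chrom, fusion.cluster_3p.span),
    ]
    kept: List[BreakpointCandidate] = []
    for b in fusion.bpcs:
        if b.kind != "split":
            kept.append(b)
            continue
        mate = b.members[0].mate
        if mate == 0:
            b.mate_consistent = None
            kept.append(b)
            continue
        other = 1 if mate == 2 else 2
        locs = mate_locations.get((b.members[0].read_id, other))
        if not locs:
            b.mate_consistent = None
            kept.append(b)
            continue
        ok = any(
            _near(chrom, (s, e), c, sp, I_max) for chrom, s, e in locs for c, sp in spans
        )
        if ok:
            b.mate_consistent = True
            kept.append(b)
        # contradicted SPLITs are removed from support entirely
    fusion.bpcs = kept
    return fusion


def merge_bridge_only_fusions(
    fusions: List[PutativeFusion], I_max: int = 20_000
) -> List[PutativeFusion]:
    """Absorb BRIDGE-only fusions into a SPLIT-supported fusion whose
    partners lie within I_max on matching sides; support counts add."""
    split_backed = [f for f in fusions if f.n_split > 0]
    out: List[PutativeFusion] = []
    for f in fusions:
        if f.n_split > 0:
            out.append(f)
            continue
        target = None
        for t in split_backed:
            for fa, fb in ((f.cluster_5p, f.cluster_3p), (f.cluster_3p, f.cluster_5p)):
                if (
                    fa.side == t.cluster_5p.side
                    and fb.side == t.cluster_3p.side
                    and _near(fa.chrom, fa.span, t.cluster_5p.chrom, t.cluster_5p.span, I_max)
                    and _near(fb.chrom, fb.span, t.cluster_3p.chrom, t.cluster_3p.span, I_max)
                ):
                    target = t
                    break
            if target:
                break
        if target is None:
            out.append(f)
        else:
            target.bpcs.extend(f.bpcs)
            target.member_cluster.update(f.member_cluster)
    return out


def fusion_score(fusion: PutativeFusion, weights: ScoreWeights = ScoreWeights()) -> float:
    """Weighted support count by alignment type, multimapping and mate status."""
    score = 0.0
    for b in fusion.bpcs:
        if b.kind == "bridge":
            score += weights.bridge
        elif b.multimap_count > 1:
            score += weights.multimapped_split
        elif b.mate_consistent:
            score += weights.unique_split_mated
        else:
            score += weights.unique_split
    return score


def resolve_multimapped(
    fusions: List[PutativeFusion],
    weights: ScoreWeights = ScoreWeights(),
    max_iter: int = 50,
) -> List[PutativeFusion]:
    """Assign each read supporting several fusions to the highest-scoring
    one, iterating to a fixed point (ties break to the smallest fusion key).
    Afterwards every read supports exactly one fusion."""
    holders: Dict[Tuple[str, int], List[PutativeFusion]] = {}
    for f in fusions:
        for b in f.bpcs:
            holders.setdefault((b.members[0].read_id, b.members[0].mate), []).append(f)
    shared = {k: v for k, v in holders.items() if len(v) > 1}
    if not shared:
        return fusions
    original = {id(f): list(f.bpcs) for f in fusions}
    assignment = {k: v[0] for k, v in shared.items()}

    def rebuild() -> None:
        for f in fusions:
            f.bpcs = [
                b
                for b in original[id(f)]
                if (key := (b.members[0].read_id, b.members[0].mate)) not in shared
                or assignment[key] is f
            ]

    for _ in range(max_iter):
        rebuild()
        scores = {id(f): fusion_score(f, weights) for f in fusions}
        changed = False
        for key, cands in shared.items():
            best = min(cands, key=lambda f: (-scores[id(f)], f.key))
            if best is not assignment[key]:
                assignment[key] = best
                changed = True
        if not changed:
            break
    rebuild()
    return fusions


# ---------------------------------------------------------------------------
# features


def compute_homogeneity(
    fusions: Sequence[PutativeFusion], proximity: int = 1000
) -> Dict[int, float]:
    """Metacluster homogeneity per fusion.

    Clusters of different fusions that intersect or lie within ``proximity``
    form a metacluster; a fusion's weight on one side is its supporting
    alignments divided by all supporting alignments in that side's
    metacluster, and the reported weight is the minimum over both sides.
    """
    entries = []  # (chrom, start, end, fusion_id, support)
    for f in fusions:
        for c in (f.cluster_5p, f.cluster_3p):
            entries.append((c.chrom, c.start, c.end, f.id, len(f.bpcs)))
    parent = list(range(len(entries)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    by_chrom: Dict[str, List[int]] = {}
    for i, e in enumerate(entries):
        by_chrom.setdefault(e[0], []).append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: entries[i][1])
        for a, b in zip(idxs, idxs[1:]):
            if entries[b][1] - entries[a][2] <= proximity:
                union(a, b)
    meta_total: Dict[int, int] = {}
    for i, e in enumerate(entries):
        meta_total[find(i)] = meta_total.get(find(i), 0) + e[4]
    weight: Dict[int, float] = {}
    for i, e in enumerate(entries):
        w = e[4] / meta_total[find(i)] if meta_total[find(i)] else 1.0
        weight[e[3]] = min(weight.get(e[3], 1.0), w)
    return weight


class DepthIndex:
    """Mean proper-pair depth over arbitrary windows, from aligned blocks."""

    def __init__(self, blocks_by_chrom: Dict[str, List[Tuple[int, int]]]):
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        for chrom, blocks in blocks_by_chrom.items():
            arr = np.array(blocks, dtype=np.int64).reshape(-1, 2)
            order = np.argsort(arr[:, 0])
            self._starts[chrom] = arr[order, 0]
            self._ends[chrom] = arr[order, 1]

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        if end <= start or chrom not in self._starts:
            return 0.0
        s, e = self._starts[chrom], self._ends[chrom]
        ov = np.clip(np.minimum(e, end) - np.maximum(s, start), 0, None)
        return float(ov.sum()) / (end - start)


def compute_coverage_features(
    fusion: PutativeFusion,
    depth: Optional[DepthIndex] = None,
    flank: int = 200,
) -> Tuple[float, float, bool, float, float]:
    """SPLIT-coverage statistics and flanking proper-read depth.

    Returns (unique_split_fraction, mean_breakpoint_offset_dev,
    has_unique_split, flank_coverage_5p, flank_coverage_3p).
    """
    splits = fusion.splits
    if splits:
        footprints = {
            (
                b.split.first.chrom,
                b.split.first.p,
                b.split.first.length,
                b.split.second.chrom,
                b.split.second.p,
                b.split.second.length,
            )
            for b in splits
        }
        usf = len(footprints) / len(splits)
        offs = [b.split.first.q_end for b in splits]
        L = max(b.split.first.read_length for b in splits) or 1
        dev = abs(float(np.mean(offs)) - L / 2.0) / L
        has_unique = any(b.multimap_count == 1 for b in splits)
    else:
        usf, dev, has_unique = 1.0, 0.0, False
    f5 = f3 = 0.0
    if depth is not None:
        for c, out in ((fusion.cluster_5p, "5"), (fusion.cluster_3p, "3")):
            bp = c.breakpoint_pos
            if bp is None:
                continue
            window = (bp - flank, bp) if c.side == "right" else (bp + 1, bp + 1 + flank)
            d = depth.mean_depth(c.chrom, *window)
            if out == "5":
                f5 = d
            else:
                f3 = d
    return usf, dev, has_unique, f5, f3


def compute_homology_score(
    junction_seq: str,
    aligners: Sequence,
    scoring: AlignScoring = AlignScoring(),
) -> float:
    """Best contiguous local-alignment score of the reconstructed junction
    sequence against the reference sets, normalised by its Score_max.
    A value near 1 means the 'fusion' sequence exists contiguously in the
    reference - an artifact of homologous genes."""
    if not junction_seq:
        return 0.0
    best = 0
    for al in aligners:
        if al is None:
            continue
        best = max(best, al.best_local_score(junction_seq))
    return best / scoring.score_max(len(junction_seq))


def pair_outer_distance(
    seq1: str, seq2: str, target: str, max_edits: int = 6
) -> Optional[float]:
    """Outer distance of a read pair placed on a target sequence (both
    orientations tried per mate); None when either mate does not place."""
    import edlib

    from .refdb import revcomp

    spans = []
    for seq in (seq1, seq2):
        best = None
        for q in (seq, revcomp(seq)):
            res = edlib.align(q, target, mode="HW", task="locations", k=max_edits)
            if res["editDistance"] >= 0 and res["locations"]:
                s, e = res["locations"][0]
                if best is None or res["editDistance"] < best[0]:
                    best = (res["editDistance"], s, e + 1)
        if best is None:
            return None
        spans.append((best[1], best[2]))
    return float(max(s[1] for s in spans) - min(s[0] for s in spans))


def bridge_inserts_via_junction(
    fusion: PutativeFusion,
    junction_seq: str,
    read_seqs: Dict[Tuple[str, int], str],
    max_edits: int = 6,
) -> List[float]:
    """Insert size of each supporting BRIDGE pair measured on the
    reconstructed fusion sequence (spliced frame): both mates are placed on
    the junction sequence and the outer distance is taken."""
    inserts: List[float] = []
    for b in fusion.bridges:
        rid = b.members[0].read_id
        s1 = read_seqs.get((rid, 1))
        s2 = read_seqs.get((rid, 2))
        if s1 is None or s2 is None:
            continue
        d = pair_outer_distance(s1, s2, junction_seq, max_edits)
        if d is not None:
            inserts.append(d)
    return inserts


def compute_insert_validity(
    inserts: Sequence[float], model: Optional[InsertSizeModel], n_bridge: int
) -> float:
    """Fraction of BRIDGE inserts inside the 3-sigma interval of the insert
    model; 1.0 when the feature is not applicable (no bridges, no model, or
    no measurable inserts)."""
    if n_bridge == 0 or model is None or not inserts:
        return 1.0
    return sum(model.valid(v) for v in inserts) / len(inserts)


def compute_strand_concordance(
    fusion: PutativeFusion,
    protocol: str,
    annotated_5p: Optional[str],
    annotated_3p: Optional[str],
) -> Tuple[float, bool, bool]:
    """(min concordance over partners, antisense_5p, antisense_3p).

    Concordance is the fraction of supporting alignments agreeing with the
    majority transcribed strand at the partner; the antisense flag is set
    when that majority strand opposes the annotated gene strand.  Inert
    (1.0, False, False) for unstranded protocols.
    """
    if protocol not in ("forward", "reverse"):
        return 1.0, False, False
    out_conc = []
    flags = []
    for cluster, annotated in (
        (fusion.cluster_5p, annotated_5p),
        (fusion.cluster_3p, annotated_3p),
    ):
        votes = Counter()
        for b in fusion.bpcs:
            for m in b.members:
                if fusion.member_cluster.get((m.bpc_id, m.slot)) != cluster.id:
                    continue
                s = m.strand if read_is_sense(m.mate, protocol) else _flip(m.strand)
                votes[s] += 1
        total = sum(votes.values())
        if total == 0:
            out_conc.append(1.0)
            flags.append(False)
            continue
        major = max(sorted(votes), key=lambda s: votes[s])
        out_conc.append(votes[major] / total)
        flags.append(annotated is not None and major != annotated)
    return min(out_conc), flags[0], flags[1]


# ---------------------------------------------------------------------------
# final verdict


@dataclass
class Verdict:
    passed: bool
    reasons: List[str] = field(default_factory=list)


def apply_filters(
    fusion: PutativeFusion,
    features: FusionFeatures,
    thresholds: FilterThresholds,
    stranded: bool = False,
) -> Verdict:
    """Enumerate every violated threshold; empty reasons means pass.

    Filtering is monotone: relaxing any single threshold can only grow the
    set of passing fusions.  Flank coverage is advisory (reported, never
    filtered on).
    """
    reasons: List[str] = []
    support = fusion.n_split + fusion.n_bridge
    if support < thresholds.min_support:
        reasons.append("min_support")
    if features.homogeneity_weight < thresholds.min_homogeneity:
        reasons.append("min_homogeneity")
    if fusion.n_split > 0:
        if features.unique_split_fraction < thresholds.min_unique_split_fraction:
            reasons.append("min_unique_split_fraction")
        if features.mean_breakpoint_offset_dev > thresholds.max_breakpoint_offset_dev:
            reasons.append("max_breakpoint_offset_dev")
        if fusion.n_bridge == 0 and not features.has_unique_split:
            reasons.append("has_unique_split")
    if features.homology_score > thresholds.max_homology_score:
        reasons.append("max_homology_score")
    if features.valid_insert_ratio < thresholds.min_valid_insert_ratio:
        reasons.append("min_valid_insert_ratio")
    if stranded and features.strand_concordance < thresholds.min_strand_concordance:
        reasons.append("min_strand_concordance")
    if not thresholds.allow_discarded_biotypes:
        from .refdb import is_discarded_biotype

        for side, biotypes in (("5p", features.biotypes_5p), ("3p", features.biotypes_3p)):
            if biotypes and all(is_discarded_biotype(b) for b in biotypes):
                reasons.append(f"biotype_{side}")
    if not thresholds.allow_intergenic and (
        features.intergenic_5p or features.intergenic_3p
    ):
        reasons.append("intergenic")
    return Verdict(passed=not reasons, reasons=reasons)
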