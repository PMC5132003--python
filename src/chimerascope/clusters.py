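"""Clustering of breakpoint candidates and assembly of putative fusions.

SPLIT reads and BRIDGE pairs are treated uniformly as breakpoint candidates
(BPCs), each contributing two alignments.  Alignments are clustered by
genomic overlap (iterative insertion with merge), clusters are then
separated by direction-to-breakpoint and by implied breakpoint position,
unused local alignments are rescued into compatible clusters, and finally
every BPC is mapped to the pair of clusters holding its two alignments,
which keys the putative fusion.

Direction table (side = where the junction lies relative to the member):

  SPLIT first segment   '+' -> right     SPLIT second segment '+' -> left
  SPLIT first segment   '-' -> left      SPLIT second segment '-' -> right
  BRIDGE mate           '+' -> right     BRIDGE mate          '-' -> left
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import edlib
from intervaltree import IntervalTree

from .alignment import AlignScoring, EndToEndAlignment, InsertSizeModel
from .splits import LocalAlignment, SplitCandidate, segment_breakend

logger = logging.getLogger(__name__)


@dataclass
class BPCMember:
    bpc_id: int
    slot: int  # 0 or 1
    kind: str  # 'split' | 'bridge'
    chrom: str
    start: int
    end: int
    side: str  # 'left' | 'right'
    strand: str
    breakpoint: Optional[int]  # exact for SPLIT members, None for BRIDGE
    read_id: str
    mate: int


@dataclass
class BreakpointCandidate:
    bpc_id: int
    kind: str  # 'split' | 'bridge'
    members: Tuple[BPCMember, BPCMember]
    split: Optional[SplitCandidate] = None
    bridge: Optional[Tuple[EndToEndAlignment, EndToEndAlignment]] = None
    multimap_count: int = 1  # SPLIT configurations of this read / mate multimaps
    rescued: bool = False
    mate_consistent: Optional[bool] = None


def split_bpc(bpc_id: int, sc: SplitCandidate, multimap_count: int = 1) -> BreakpointCandidate:
    m = []
    for slot, (aln, is_first) in enumerate(((sc.first, True), (sc.second, False))):
        be = segment_breakend(aln, is_first)
        m.append(
            BPCMember(
                bpc_id=bpc_id,
                slot=slot,
                kind="split",
                chrom=aln.chrom,
                start=aln.p,
                end=aln.ref_end,
                side=be.side,
                strand=aln.strand,
                breakpoint=be.pos,
                read_id=aln.read_id,
                mate=aln.mate,
            )
        )
    return BreakpointCandidate(
        bpc_id=bpc_id, kind="split", members=(m[0], m[1]), split=sc,
        multimap_count=multimap_count,
    )


def bridge_bpc(
    bpc_id: int, a1: EndToEndAlignment, a2: EndToEndAlignment
) -> BreakpointCandidate:
    m = []
    for slot, aln in enumerate((a1, a2)):
        m.append(
            BPCMember(
                bpc_id=bpc_id,
                slot=slot,
                kind="bridge",
                chrom=aln.chrom,
                start=aln.start,
                end=aln.end,
                side="right" if aln.strand == "+" else "left",
                strand=aln.strand,
                breakpoint=None,
                read_id=aln.read_id,
                mate=aln.mate,
            )
        )
    return BreakpointCandidate(
        bpc_id=bpc_id,
        kind="bridge",
        members=(m[0], m[1]),
        bridge=(a1, a2),
        multimap_count=max(a1.multimap_count, a2.multimap_count),
    )


@dataclass
class Cluster:
    id: int
    chrom: str
    start: int
    end: int
    members: List[BPCMember] = field(default_factory=list)
    side: Optional[str] = None
    breakpoint_pos: Optional[int] = None
    approximate: bool = True

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def recompute_span(self) -> None:
        self.start = min(m.start for m in self.members)
        self.end = max(m.end for m in self.members)


class _IdGen:
    def __init__(self) -> None:
        self.n = 0

    def __call__(self) -> int:
        self.n += 1
        return self.n


def build_clusters(members: Sequence[BPCMember], idgen: Optional[_IdGen] = None) -> List[Cluster]:
    """Iterative insertion: no overlap -> new cluster; one -> join; several ->
    merge then join.  Final spans are pairwise disjoint per chromosome."""
    idgen = idgen or _IdGen()
    clusters: Dict[int, Cluster] = {}
    trees: Dict[str, IntervalTree] = {}
    for m in members:
        tree = trees.setdefault(m.chrom, IntervalTree())
        hit_ids = sorted({iv.data for iv in tree.overlap(m.start, m.end)})
        if not hit_ids:
            c = Cluster(idgen(), m.chrom, m.start, m.end, [m])
            clusters[c.id] = c
            tree.addi(c.start, c.end, c.id)
            continue
        host = clusters[hit_ids[0]]
        tree.removei(host.start, host.end, host.id)
        for cid in hit_ids[1:]:
            other = clusters.pop(cid)
            tree.removei(other.start, other.end, other.id)
            host.members.extend(other.members)
        host.members.append(m)
        host.recompute_span()
        tree.addi(host.start, host.end, host.id)
    return sorted(clusters.values(), key=lambda c: (c.chrom, c.start, c.id))


def split_by_directionality(cluster: Cluster, idgen: Optional[_IdGen] = None) -> List[Cluster]:
    """Partition members by the side on which their breakpoint lies."""
    idgen = idgen or _IdGen()
    sides = sorted({m.side for m in cluster.members})
    if len(sides) == 1:
        cluster.side = sides[0]
        return [cluster]
    out = []
    for side in sides:
        mem = [m for m in cluster.members if m.side == side]
        c = Cluster(idgen(), cluster.chrom, 0, 0, mem, side=side)
        c.recompute_span()
        out.append(c)
    return out


def split_by_breakpoint(
    cluster: Cluster,
    tol: int = 10,
    idgen: Optional[_IdGen] = None,
    bridge_reach: float = 600.0,
) -> List[Cluster]:
    """Separate a direction-homogeneous cluster so that SPLIT-implied
    breakpoints within each output cluster agree within ``tol``.

    Grouping is single-linkage with chain-breaking: breakpoints are sorted
    and a new group starts whenever the gap to the previous position exceeds
    ``tol``.  BRIDGE-only members attach to the nearest compatible group
    (within ``bridge_reach``, derived from the insert-size model); if no
    SPLIT member exists the cluster stays BRIDGE-only with an approximate
    breakpoint at the span edge facing the junction.
    """
    idgen = idgen or _IdGen()
    exact = sorted(
        (m for m in cluster.members if m.breakpoint is not None),
        key=lambda m: m.breakpoint,
    )
    bridges = [m for m in cluster.members if m.breakpoint is None]
    if not exact:
        cluster.approximate = True
        cluster.breakpoint_pos = (
            cluster.end - 1 if cluster.side == "right" else cluster.start
        )
        return [cluster]
    groups: List[List[BPCMember]] = [[exact[0]]]
    for m in exact[1:]:
        if m.breakpoint - groups[-1][-1].breakpoint > tol:
            groups.append([m])
        else:
            groups[-1].append(m)
    # consensus breakpoint per group: most supported position, ties -> smallest
    consensus = []
    for g in groups:
        cnt = Counter(m.breakpoint for m in g)
        top = max(cnt.values())
        consensus.append(min(p for p, c in cnt.items() if c == top))
    # attach bridge members to the nearest group whose breakpoint they can reach
    attach: List[List[BPCMember]] = [[] for _ in groups]
    for m in bridges:
        anchor = m.end - 1 if m.side == "right" else m.start
        best, best_d = None, None
        for gi, bp in enumerate(consensus):
            d = abs(bp - anchor)
            reachable = (
                bp >= anchor - tol if m.side == "right" else bp <= anchor + tol
            )
            if d <= bridge_reach and reachable and (best_d is None or d < best_d):
                best, best_d = gi, d
        if best is None:  # fall back to nearest group
            best = min(range(len(groups)), key=lambda gi: abs(consensus[gi] - anchor))
        attach[best].append(m)
    if len(groups) == 1:
        cluster.breakpoint_pos = consensus[0]
        cluster.approximate = False
        return [cluster]
    out = []
    for g, extra, bp in zip(groups, attach, consensus):
        c = Cluster(
            idgen(), cluster.chrom, 0, 0, g + extra, side=cluster.side,
            breakpoint_pos=bp, approximate=False,
        )
        c.recompute_span()
        out.append(c)
    return out


def cluster_bpcs(
    bpcs: Sequence[BreakpointCandidate],
    tol: int = 10,
    bridge_reach: float = 600.0,
) -> List[Cluster]:
    """Full clustering: build, separate by direction, separate by breakpoint."""
    idgen = _IdGen()
    members = sorted(
        (m for b in bpcs for m in b.members),
        key=lambda m: (m.chrom, m.start, m.end, m.bpc_id, m.slot),
    )
    out: List[Cluster] = []
    for c in build_clusters(members, idgen):
        for d in split_by_directionality(c, idgen):
            out.extend(split_by_breakpoint(d, tol=tol, idgen=idgen, bridge_reach=bridge_reach))
    return out


def member_cluster_map(clusters: Sequence[Cluster]) -> Dict[Tuple[int, int], int]:
    return {(m.bpc_id, m.slot): c.id for c in clusters for m in c.members}


def partner_links(
    bpcs: Sequence[BreakpointCandidate], assign: Dict[Tuple[int, int], int]
) -> Dict[int, Set[int]]:
    links: Dict[int, Set[int]] = {}
    for b in bpcs:
        c0 = assign.get((b.bpc_id, 0))
        c1 = assign.get((b.bpc_id, 1))
        if c0 is None or c1 is None or c0 == c1:
            continue
        links.setdefault(c0, set()).add(c1)
        links.setdefault(c1, set()).add(c0)
    return links


# ---------------------------------------------------------------------------
# rescue of unused local alignments


def _junction_part(seq: str, la: LocalAlignment, side: str) -> str:
    """Read bases beyond the junction side of a local alignment, in original
    read orientation."""
    if (side == "right") == (la.strand == "+"):
        return seq[la.q_end :]
    return seq[: la.q]


def rescue_alignments(
    clusters: List[Cluster],
    unused: Sequence[LocalAlignment],
    read_seqs: Dict[Tuple[str, int], str],
    fetch,  # callable(chrom, start, end) -> str
    links: Dict[int, Set[int]],
    scoring: AlignScoring = AlignScoring(),
    insert_model: Optional[InsertSizeModel] = None,
    next_bpc_id: int = 0,
    min_part_len: int = 10,
    host_slack: int = 3,
    max_per_cluster: int = 200,
) -> List[BreakpointCandidate]:
    """Assign compatible unused local alignments to clusters as rescued
    SPLIT candidates.

    A candidate must score above 50% of the maximum alignment score with an
    edit distance below 2, intersect a host cluster concordantly with its
    direction and breakpoint, and its remaining read part must realign to a
    partner cluster's junction region (same thresholds on the rescued part).
    For BRIDGE-only host clusters the positional tolerance is widened by the
    insert model and the final breakpoint is voted by evidence count.
    Breakpoints already fixed by SPLIT reads are never moved.
    """
    from .refdb import revcomp

    by_id = {c.id: c for c in clusters}
    reach = insert_model.upper if insert_model is not None else 600.0
    trees: Dict[str, IntervalTree] = {}
    for c in clusters:
        lo, hi = c.start, max(c.end, c.start + 1)
        if c.approximate:
            # BRIDGE-only hosts: the junction lies up to an insert length
            # beyond the span on the junction side
            if c.side == "right":
                hi += int(reach)
            elif c.side == "left":
                lo -= int(reach)
        trees.setdefault(c.chrom, IntervalTree()).addi(lo, hi, c.id)
    votes: Dict[int, Counter] = {}
    per_cluster = Counter()
    new_bpcs: List[BreakpointCandidate] = []
    bpc_id = next_bpc_id

    for la in sorted(unused, key=lambda a: (a.read_id, a.mate, a.chrom, a.p)):
        smax = scoring.score_max(la.read_length)
        if la.score <= 0.5 * smax or la.edit_distance >= 2:
            continue
        seq = read_seqs.get((la.read_id, la.mate))
        if seq is None:
            continue
        tree = trees.get(la.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(la.p, la.ref_end), key=lambda iv: iv.data):
            host = by_id[iv.data]
            if host.side is None or per_cluster[host.id] >= max_per_cluster:
                continue
            part = _junction_part(seq, la, host.side)
            if len(part) < min_part_len:
                continue
            # concordance with the host breakpoint
            edge = la.ref_end - 1 if host.side == "right" else la.p
            if host.approximate:
                lo = host.start - (reach if host.side == "left" else 0) - host_slack
                hi = host.end + (reach if host.side == "right" else 0) + host_slack
                if not (lo <= edge <= hi):
                    continue
                host_bp = edge
            else:
                if abs(edge - host.breakpoint_pos) > host_slack:
                    continue
                host_bp = host.breakpoint_pos
            is_suffix = (host.side == "right") == (la.strand == "+")
            hit = None
            for pid in sorted(links.get(host.id, ())):
                partner = by_id.get(pid)
                if partner is None:
                    continue
                hit = _realign_part(
                    part, partner, fetch, reach, host_slack, la, scoring, is_suffix
                )
                if hit is not None:
                    break
            if hit is None:
                continue
            part_la, partner, partner_bp = hit
            first, second = (la, part_la) if la.q <= part_la.q else (part_la, la)
            sc = SplitCandidate(first=first, second=second, gap=second.q - first.q_end)
            bpc_id += 1
            b = split_bpc(bpc_id, sc, multimap_count=1)
            b.rescued = True
            # membership follows the rescue, not re-clustering
            hm = b.members[0] if first is la else b.members[1]
            pm = b.members[1] if first is la else b.members[0]
            host.members.append(hm)
            partner.members.append(pm)
            per_cluster[host.id] += 1
            if host.approximate:
                votes.setdefault(host.id, Counter())[host_bp] += 1
            if partner.approximate:
                votes.setdefault(partner.id, Counter())[partner_bp] += 1
            new_bpcs.append(b)
            break

    # most probable breakpoint by amount of evidence (BRIDGE-only hosts)
    for cid, cnt in votes.items():
        c = by_id[cid]
        if c.approximate and cnt:
            top = max(cnt.values())
            c.breakpoint_pos = min(p for p, v in cnt.items() if v == top)
            c.approximate = False
    for c in clusters:
        if c.members:
            c.recompute_span()
    return new_bpcs


def _realign_part(
    part: str,
    partner: Cluster,
    fetch,
    reach: float,
    slack: int,
    host_la: LocalAlignment,
    scoring: AlignScoring,
    part_is_suffix: bool,
):
    """Realign a remaining read part against a partner cluster's junction
    region; returns (LocalAlignment, partner, junction_pos) or None."""
    from .refdb import revcomp

    plen = len(part)
    if partner.approximate:
        lo = int(partner.start - (reach if partner.side == "left" else 0)) - plen
        hi = int(partner.end + (reach if partner.side == "right" else 0)) + plen
    else:
        bp = partner.breakpoint_pos
        if partner.side == "left":
            lo, hi = bp - slack, bp + plen + slack
        else:
            lo, hi = bp - plen - slack, bp + 1 + slack
    lo = max(0, lo)
    region = fetch(partner.chrom, lo, hi)
    if len(region) < plen:
        return None
    best = None
    for strand, q in (("+", part), ("-", None)):
        qseq = q if q is not None else revcomp(part)
        res = edlib.align(qseq, region, mode="HW", task="locations", k=1)
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        ed = res["editDistance"]
        s, e = res["locations"][0]
        p = lo + s
        end = lo + e + 1
        junction = end - 1 if partner.side == "right" else p
        if not partner.approximate and abs(junction - partner.breakpoint_pos) > slack:
            continue
        score = scoring.match * (plen - ed) + scoring.mismatch * ed
        if score <= 0.5 * scoring.match * plen:
            continue
        if best is None or ed < best[0]:
            best = (ed, strand, p, end, junction, score)
    if best is None:
        return None
    ed, strand, p, end, junction, score = best
    seq_len = host_la.read_length
    q = seq_len - plen if part_is_suffix else 0
    la = LocalAlignment(
        read_id=host_la.read_id,
        mate=host_la.mate,
        chrom=partner.chrom,
        p=p,
        q=q,
        length=plen,
        strand=strand,
        score=score,
        edit_distance=ed,
        read_length=seq_len,
    )
    return la, partner, junction


# ---------------------------------------------------------------------------
# putative fusion assembly


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def read_is_sense(mate: int, strandedness: str) -> bool:
    """Whether a read's sequence equals the transcript sense, given the
    library protocol (mate 0 = unpaired, treated like mate 1)."""
    return (strandedness == "forward") == (mate != 2)


@dataclass
class PutativeFusion:
    id: int
    cluster_5p: Cluster
    cluster_3p: Cluster
    bpcs: List[BreakpointCandidate]
    member_cluster: Dict[Tuple[int, int], int]
    strand_5p: str  # inferred transcribed strand at each partner locus
    strand_3p: str
    order_confident: bool = True

    @property
    def key(self) -> Tuple[int, int]:
        return tuple(sorted((self.cluster_5p.id, self.cluster_3p.id)))

    @property
    def breakpoint_5p(self) -> Tuple[str, int]:
        return (self.cluster_5p.chrom, self.cluster_5p.breakpoint_pos)

    @property
    def breakpoint_3p(self) -> Tuple[str, int]:
        return (self.cluster_3p.chrom, self.cluster_3p.breakpoint_pos)

    @property
    def splits(self) -> List[BreakpointCandidate]:
        return [b for b in self.bpcs if b.kind == "split"]

    @property
    def bridges(self) -> List[BreakpointCandidate]:
        return [b for b in self.bpcs if b.kind == "bridge"]

    @property
    def n_split(self) -> int:
        return len(self.splits)

    @property
    def n_bridge(self) -> int:
        return len(self.bridges)

    @property
    def approximate(self) -> bool:
        return self.cluster_5p.approximate or self.cluster_3p.approximate


def _geometric_strand(cluster: Cluster, is_donor: bool) -> str:
    """Transcribed strand implied by the cluster side and the partner role:
    a donor is transcribed toward its junction, an acceptor away from it."""
    if is_donor:
        return "+" if cluster.side == "right" else "-"
    return "+" if cluster.side == "left" else "-"


def _annotated_strand(cluster: Cluster, db) -> Optional[str]:
    if db is None or cluster.breakpoint_pos is None:
        return None
    ann = db.annotate_position(cluster.chrom, cluster.breakpoint_pos)
    if ann.category == "intergenic" or not ann.strands:
        return None
    return ann.strands[0]


def form_putative_fusions(
    clusters: Sequence[Cluster],
    bpcs: Sequence[BreakpointCandidate],
    strandedness: str = "none",
    db=None,
) -> List[PutativeFusion]:
    """Group BPCs by the unordered pair of clusters holding their alignments
    and fix the 5'/3' order.

    With a strand-specific protocol the order comes from the read
    orientations themselves; otherwise the annotated strands of the genes at
    the two breakpoints are used, with a deterministic genomic left-to-right
    tie-break.  BPCs whose two alignments fall in the same cluster are
    degenerate and dropped with a log message.
    """
    assign = member_cluster_map(clusters)
    by_id = {c.id: c for c in clusters}
    groups: Dict[Tuple[int, int], List[BreakpointCandidate]] = {}
    dropped = 0
    for b in bpcs:
        c0 = assign.get((b.bpc_id, 0))
        c1 = assign.get((b.bpc_id, 1))
        if c0 is None or c1 is None or c0 == c1:
            dropped += 1
            continue
        groups.setdefault(tuple(sorted((c0, c1))), []).append(b)
    if dropped:
        logger.info("dropped %d degenerate breakpoint candidates", dropped)

    fusions: List[PutativeFusion] = []
    fid = 0
    for key in sorted(groups):
        blist = groups[key]
        A, B = by_id[key[0]], by_id[key[1]]
        confident = True
        if strandedness in ("forward", "reverse"):
            votes = {A.id: Counter(), B.id: Counter()}
            for b in blist:
                for m in b.members:
                    cid = assign[(m.bpc_id, m.slot)]
                    s = m.strand if read_is_sense(m.mate, strandedness) else _flip(m.strand)
                    votes[cid][s] += 1
            s_a = max(sorted(votes[A.id]), key=lambda s: votes[A.id][s], default="+")
            s_b = max(sorted(votes[B.id]), key=lambda s: votes[B.id][s], default="+")
            a_donor = (A.side == "right") == (s_a == "+")
            b_donor = (B.side == "right") == (s_b == "+")
            if a_donor and not b_donor:
                donor, acceptor = A, B
            elif b_donor and not a_donor:
                donor, acceptor = B, A
            else:
                confident = False
                donor, acceptor = (A, B) if (A.chrom, A.start) <= (B.chrom, B.start) else (B, A)
            s5, s3 = (s_a, s_b) if donor is A else (s_b, s_a)
        else:
            ann_a, ann_b = _annotated_strand(A, db), _annotated_strand(B, db)

            def consistency(donor: Cluster, acceptor: Cluster, sd, sa) -> int:
                score = 0
                if sd is not None:
                    score += int(_geometric_strand(donor, True) == sd)
                if sa is not None:
                    score += int(_geometric_strand(acceptor, False) == sa)
                return score

            sc_ab = consistency(A, B, ann_a, ann_b)
            sc_ba = consistency(B, A, ann_b, ann_a)
            if sc_ab > sc_ba:
                donor, acceptor = A, B
            elif sc_ba > sc_ab:
                donor, acceptor = B, A
            else:
                confident = False
                # genomic left partner transcribed '+' reads through first
                left, right = (A, B) if (A.chrom, A.start) <= (B.chrom, B.start) else (B, A)
                donor, acceptor = (left, right) if _geometric_strand(left, True) == "+" else (right, left)
            s5 = _geometric_strand(donor, True)
            s3 = _geometric_strand(acceptor, False)
        fid += 1
        fusions.append(
            PutativeFusion(
                id=fid,
                cluster_5p=donor,
                cluster_3p=acceptor,
                bpcs=sorted(blist, key=lambda b: b.bpc_id),
                member_cluster={
                    (m.bpc_id, m.slot): assign[(m.bpc_id, m.slot)]
                    for b in blist
                    for m in b.members
                },
                strand_5p=s5,
                strand_3p=s3,
                order_confident=confident,
            )
        )
    return fusions
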