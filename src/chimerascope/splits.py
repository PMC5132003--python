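"""SPLIT breakpoint-candidate formation from local alignments.

A SPLIT read carries two local alignments of one read that flank a fusion
junction.  Two local alignments A_i = (c_i, p_i, q_i, l_i) qualify when

1. they cannot be explained by a normal spliced end-to-end alignment:
   different chromosome, or genomic separation beyond the maximum intron
   size I_max, or discordant strands (inversion), or genomic order that
   contradicts read order; and
2. they are contiguous in read coordinates: with the pair ordered so that
   q_i < q_j, the signed gap g = q_j - (q_i + l_i) lies in
   [-T_inner, +T_outer] - overlap (junction microhomology) up to T_inner
   bases, unaligned gap up to T_outer bases.

Both bounds are closed.  At most ``max_configs`` candidates are kept per
read, ranked by summed alignment score, then fewest mismatches, then
lexicographic locus order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Tuple


@dataclass(frozen=True)
class LocalAlignment:
    """One local (gapless or gapped) mapping of a read segment.

    ``q`` is the segment start in the coordinates of the read as sequenced;
    ``p`` the 0-based reference start; minus-strand alignments map read
    position q to reference position p + length - 1.
    """

    read_id: str
    mate: int  # 1, 2, or 0 for unpaired
    chrom: str
    p: int
    q: int
    length: int
    strand: str
    score: int
    edit_distance: int
    read_length: int
    multimap_count: int = 1

    @property
    def ref_end(self) -> int:
        return self.p + self.length

    @property
    def q_end(self) -> int:
        return self.q + self.length


@dataclass(frozen=True)
class SplitParams:
    I_max: int = 20_000
    T_inner: int = 10
    T_outer: int = 2
    max_configs: int = 20

    def __post_init__(self) -> None:
        if min(self.I_max, self.T_inner, self.T_outer, self.max_configs) < 0:
            raise ValueError("split parameters must be non-negative")


@dataclass(frozen=True)
class Breakend:
    """One side of a junction: the last aligned base and the side on which
    the partner continues ('right' = partner lies at higher coordinates)."""

    chrom: str
    pos: int
    side: str  # 'left' | 'right'
    role: str  # 'upstream' (5', toward junction) | 'downstream' (3', away)


@dataclass(frozen=True)
class SplitCandidate:
    first: LocalAlignment  # lower read coordinate
    second: LocalAlignment
    gap: int  # q_second - (q_first + l_first); negative = microhomology

    @property
    def read_id(self) -> str:
        return self.first.read_id

    @property
    def mate(self) -> int:
        return self.first.mate

    @property
    def total_score(self) -> int:
        return self.first.score + self.second.score


def _splice_compatible(a: LocalAlignment, b: LocalAlignment, params: SplitParams) -> bool:
    """True when the ordered pair (a first in the read) looks like a normal
    spliced alignment, which disqualifies it as fusion evidence."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if a.strand == "+":
        separation = b.p - a.ref_end  # intron length for a forward splice
    else:
        separation = a.p - b.ref_end  # read order runs right-to-left in genome
    return -params.T_inner <= separation <= params.I_max


def condition_one(a: LocalAlignment, b: LocalAlignment, params: SplitParams) -> bool:
    """Fusion-compatibility of the genomic placement (pair ordered by q)."""
    return not _splice_compatible(a, b, params)


def condition_two(a: LocalAlignment, b: LocalAlignment, params: SplitParams) -> bool:
    """Read-coordinate contiguity of the ordered pair."""
    g = b.q - a.q_end
    return -params.T_inner <= g <= params.T_outer


def form_split_candidates(
    alns: List[LocalAlignment], params: SplitParams = SplitParams()
) -> List[SplitCandidate]:
    """All SPLIT configurations formed by the local alignments of one read."""
    if len(alns) < 2:
        return []
    read_ids = {(a.read_id, a.mate) for a in alns}
    if len(read_ids) > 1:
        raise ValueError("alignments from different reads passed together")
    out: List[SplitCandidate] = []
    for x, y in combinations(alns, 2):
        a, b = (x, y) if x.q <= y.q else (y, x)
        if a.q == b.q:  # identical read start cannot flank a junction
            continue
        if condition_two(a, b, params) and condition_one(a, b, params):
            out.append(SplitCandidate(first=a, second=b, gap=b.q - a.q_end))
    out.sort(
        key=lambda sc: (
            -sc.total_score,
            sc.first.edit_distance + sc.second.edit_distance,
            sc.first.chrom,
            sc.first.p,
            sc.second.chrom,
            sc.second.p,
        )
    )
    return out[: params.max_configs]


def implied_breakpoint(sc: SplitCandidate) -> Tuple[Breakend, Breakend]:
    """Exact junction implied by a SPLIT candidate.

    The donor end is the genomic coordinate of the read base at
    q_first + l_first - 1 (strand-aware); the acceptor is the coordinate of
    the read base at q_second.  With microhomology (gap < 0) the junction is
    placed at the end of the first segment, shifting both ends by the same
    amount - a deterministic donor-side tie-break.
    """
    a, b = sc.first, sc.second
    if a.strand == "+":
        donor = Breakend(a.chrom, a.ref_end - 1, "right", "upstream")
    else:
        donor = Breakend(a.chrom, a.p, "left", "upstream")
    # with overlap, the second segment's first |gap| bases belong to the donor
    trim = max(0, -sc.gap)
    if b.strand == "+":
        acceptor = Breakend(b.chrom, b.p + trim, "left", "downstream")
    else:
        acceptor = Breakend(b.chrom, b.ref_end - 1 - trim, "right", "downstream")
    return donor, acceptor


def segment_breakend(aln: LocalAlignment, is_first: bool) -> Breakend:
    """Breakend of one SPLIT segment (direction table written out in full)."""
    if is_first:
        if aln.strand == "+":
            return Breakend(aln.chrom, aln.ref_end - 1, "right", "upstream")
        return Breakend(aln.chrom, aln.p, "left", "upstream")
    if aln.strand == "+":
        return Breakend(aln.chrom, aln.p, "left", "downstream")
    return Breakend(aln.chrom, aln.ref_end - 1, "right", "downstream")
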