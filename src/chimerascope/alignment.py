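"""Alignment layer: end-to-end and local read alignment plus pair statistics.

Alignment is delegated to a pluggable backend.  Two backends ship with the
package:

* :class:`InternalAligner` - a self-contained seed-and-extend short-read
  aligner (numpy k-mer index, gapless extension) with the standard local
  scoring scheme (match +2, mismatch -2, gap open -6, gap extend -3).  It is
  the default backend and what the test-suite and simulation studies use.
* :class:`ExternalAligner` - a thin command-template wrapper so that any
  SAM-emitting short-read aligner can be plugged in; its output is ingested
  with pysam (bypass mode accepts a pre-made SAM/BAM directly).

This module also classifies read pairs (proper vs. BRIDGE candidate),
estimates the insert-size model from concordant pairs and per-gene mean
exonic coverage.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .splits import LocalAlignment

# ---------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class AlignScoring:
    """Local-alignment scoring scheme; Score_max = read_length * match."""

    match: int = 2
    mismatch: int = -2
    gap_open: int = -6
    gap_extend: int = -3

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("match must be positive, penalties non-positive")

    def score_max(self, read_length: int) -> int:
        return read_length * self.match

    def min_local_score(self, read_length: int) -> float:
        """Local mappings are accepted only with score strictly above
        Score_max / 3."""
        return self.score_max(read_length) / 3.0


# ---------------------------------------------------------------------------
# sequence encoding

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_rc(seq: str) -> np.ndarray:
    arr = encode(seq)[::-1].copy()
    return np.where(arr < 4, 3 - arr, 4).astype(np.uint8)


# ---------------------------------------------------------------------------
# end-to-end alignment record


@dataclass
class EndToEndAlignment:
    """A full-length alignment of one read, in genomic coordinates.

    Transcriptome hits retain the source transcript and transcript-frame
    interval so that insert sizes can be measured in the spliced frame.
    """

    read_id: str
    mate: int  # 1, 2, or 0 for unpaired
    chrom: str
    blocks: Tuple[Tuple[int, int], ...]
    strand: str
    mapped_to: str  # 'transcriptome' | 'genome'
    multimap_count: int = 1
    mismatches: int = 0
    transcript_id: Optional[str] = None
    t_start: Optional[int] = None
    t_end: Optional[int] = None
    read_length: int = 0

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass(frozen=True)
class InsertSizeModel:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0 or self.n < 1:
            raise ValueError("invalid insert model")

    def valid(self, insert: float) -> bool:
        """3-sigma rule: an insert is valid inside [mean - 3 sd, mean + 3 sd]."""
        return abs(insert - self.mean) <= 3.0 * self.sd

    @property
    def upper(self) -> float:
        return self.mean + 3.0 * self.sd


# ---------------------------------------------------------------------------
# k-mer seed index


class SeedIndex:
    """Sorted k-mer hash index over a set of named sequences."""

    def __init__(self, seqs: Dict[str, str], k: int = 20):
        self.k = k
        self.names: List[str] = list(seqs)
        arrs = [encode(seqs[n]) for n in self.names]
        lens = np.array([len(a) for a in arrs], dtype=np.int64)
        self.starts = np.concatenate([[0], np.cumsum(lens)])[:-1]
        self.ends = self.starts + lens
        self.arr = (
            np.concatenate(arrs) if arrs else np.zeros(0, dtype=np.uint8)
        )
        self.total = int(self.ends[-1]) if len(lens) else 0
        n = self.total - k + 1
        if n > 0:
            h = np.zeros(n, dtype=np.int64)
            bad = np.zeros(n, dtype=bool)
            for j in range(k):
                v = self.arr[j : j + n].astype(np.int64)
                bad |= v >= 4
                h = h * 4 + np.where(v >= 4, 0, v)
            # windows must not straddle a sequence boundary
            sid = np.searchsorted(self.ends, np.arange(n), side="right")
            sid_end = np.searchsorted(self.ends, np.arange(n) + k - 1, side="right")
            bad |= sid != sid_end
            pos = np.nonzero(~bad)[0]
            hv = h[pos]
            order = np.argsort(hv, kind="stable")
            self.sorted_hashes = hv[order]
            self.sorted_pos = pos[order]
        else:
            self.sorted_hashes = np.zeros(0, dtype=np.int64)
            self.sorted_pos = np.zeros(0, dtype=np.int64)

    def seq_id_of(self, pos: int) -> int:
        return int(np.searchsorted(self.ends, pos, side="right"))

    def locate(self, pos: int) -> Tuple[str, int]:
        sid = self.seq_id_of(pos)
        return self.names[sid], int(pos - self.starts[sid])

    def bounds(self, pos: int) -> Tuple[int, int]:
        sid = self.seq_id_of(pos)
        return int(self.starts[sid]), int(self.ends[sid])

    def hash_kmers(self, arr: np.ndarray, offsets: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Hashes of arr[o:o+k] for each offset; second array flags validity."""
        k = self.k
        h = np.zeros(len(offsets), dtype=np.int64)
        ok = np.ones(len(offsets), dtype=bool)
        for j in range(k):
            v = arr[offsets + j].astype(np.int64)
            ok &= v < 4
            h = h * 4 + np.where(v < 4, v, 0)
        return h, ok

    def lookup(self, hashes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.sorted_hashes, hashes, side="left")
        hi = np.searchsorted(self.sorted_hashes, hashes, side="right")
        return lo, hi


# ---------------------------------------------------------------------------
# internal aligner


@dataclass
class EndHit:
    seq_name: str
    pos: int  # 0-based start within seq_name
    strand: str
    mismatches: int
    multimap_count: int


class InternalAligner:
    """Seed-and-extend aligner over a fixed target sequence set.

    End-to-end mode places the whole read (mismatches only, up to
    ``max_mismatches``); reads it cannot place fall through to local mode,
    which reports every gapless local alignment whose score exceeds
    Score_max / 3, possibly several per read.
    """

    def __init__(
        self,
        seqs: Dict[str, str],
        k: int = 20,
        scoring: AlignScoring = AlignScoring(),
        max_mismatches: int = 5,
        max_hits_per_seed: int = 16,
        local_seed_stride: int = 5,
    ):
        self.index = SeedIndex(seqs, k=k)
        self.scoring = scoring
        self.max_mismatches = max_mismatches
        self.max_hits_per_seed = max_hits_per_seed
        self.local_seed_stride = local_seed_stride

    # -- end-to-end ----------------------------------------------------

    def map_end_to_end_batch(self, seqs: Sequence[str]) -> List[Optional[EndHit]]:
        if not seqs:
            return []
        lengths = {len(s) for s in seqs}
        if len(lengths) == 1 and len(seqs) > 1:
            return self._map_batch_uniform(seqs)
        return [self.map_end_to_end(s) for s in seqs]

    def map_end_to_end(self, seq: str) -> Optional[EndHit]:
        return self._map_batch_uniform([seq])[0]

    def _map_batch_uniform(self, seqs: Sequence[str]) -> List[Optional[EndHit]]:
        idx = self.index
        k = idx.k
        n = len(seqs)
        L = len(seqs[0])
        if L < k or idx.total < L:
            return [None] * n
        fwd = np.vstack([encode(s) for s in seqs])
        rev = np.vstack([encode_rc(s) for s in seqs])
        offsets = sorted({0, (L - k) // 2, L - k})
        cand: List[np.ndarray] = []
        for si, mat in ((0, fwd), (1, rev)):
            for off in offsets:
                h = np.zeros(n, dtype=np.int64)
                ok = np.ones(n, dtype=bool)
                for j in range(k):
                    v = mat[:, off + j].astype(np.int64)
                    ok &= v < 4
                    h = h * 4 + np.where(v < 4, v, 0)
                lo, hi = idx.lookup(h)
                hi = np.minimum(hi, lo + self.max_hits_per_seed)
                rows = np.nonzero(ok & (hi > lo))[0]
                for r in rows:
                    pos = idx.sorted_pos[lo[r] : hi[r]] - off
                    cand.append(
                        np.stack(
                            [np.full(len(pos), r), np.full(len(pos), si), pos], axis=1
                        )
                    )
        if not cand:
            return [None] * n
        c = np.unique(np.concatenate(cand), axis=0)
        rid, sidx, tstart = c[:, 0], c[:, 1], c[:, 2]
        keep = (tstart >= 0) & (tstart + L <= idx.total)
        # alignment must stay within one target sequence
        sid_a = np.searchsorted(idx.ends, tstart, side="right")
        sid_b = np.searchsorted(idx.ends, tstart + L - 1, side="right")
        keep &= sid_a == sid_b
        rid, sidx, tstart, sid_a = rid[keep], sidx[keep], tstart[keep], sid_a[keep]
        if len(rid) == 0:
            return [None] * n
        T = idx.arr[tstart[:, None] + np.arange(L)]
        mism = np.zeros(len(rid), dtype=np.int64)
        for si, mat in ((0, fwd), (1, rev)):
            rowsel = sidx == si
            if rowsel.any():
                Q = mat[rid[rowsel]]
                mism[rowsel] = ((T[rowsel] != Q) | (Q >= 4)).sum(axis=1)
        ok = mism <= self.max_mismatches
        rid, sidx, tstart, sid_a, mism = (
            rid[ok],
            sidx[ok],
            tstart[ok],
            sid_a[ok],
            mism[ok],
        )
        out: List[Optional[EndHit]] = [None] * n
        counts = np.bincount(rid, minlength=n) if len(rid) else np.zeros(n, dtype=int)
        order = np.lexsort((mism, rid))
        seen = set()
        for i in order:
            r = int(rid[i])
            if r in seen:
                continue
            seen.add(r)
            sid = int(sid_a[i])
            out[r] = EndHit(
                seq_name=idx.names[sid],
                pos=int(tstart[i] - idx.starts[sid]),
                strand="+" if sidx[i] == 0 else "-",
                mismatches=int(mism[i]),
                multimap_count=int(counts[r]),
            )
        return out

    # -- local ---------------------------------------------------------

    def local_alignments(
        self, seq: str, read_id: str = "", mate: int = 0, apply_threshold: bool = True
    ) -> List[LocalAlignment]:
        """All gapless local alignments of one read above the score threshold."""
        idx = self.index
        k = idx.k
        L = len(seq)
        if L < k or idx.total == 0:
            return []
        stride = max(1, min(self.local_seed_stride, L - k))
        offs = list(range(0, L - k + 1, stride))
        if offs[-1] != L - k:
            offs.append(L - k)
        offs_arr = np.array(offs, dtype=np.int64)
        min_score = self.scoring.min_local_score(L) if apply_threshold else 0.0
        results: List[LocalAlignment] = []
        seen_diag = set()
        found = {}
        for strand, arr in (("+", encode(seq)), ("-", encode_rc(seq))):
            h, ok = idx.hash_kmers(arr, offs_arr)
            lo, hi = idx.lookup(h)
            hi = np.minimum(hi, lo + self.max_hits_per_seed)
            for oi in np.nonzero(ok & (hi > lo))[0]:
                for tpos in idx.sorted_pos[lo[oi] : hi[oi]]:
                    diag = int(tpos) - int(offs_arr[oi])
                    key = (strand, diag)
                    if key in seen_diag:
                        continue
                    seen_diag.add(key)
                    hit = self._extend_diagonal(arr, diag)
                    if hit is None:
                        continue
                    qoff, length, score, edits, gpos = hit
                    if score <= min_score:
                        continue
                    name, local = idx.locate(gpos)
                    q = qoff if strand == "+" else L - (qoff + length)
                    dkey = (name, local, strand, q)
                    prev = found.get(dkey)
                    if prev is None or score > prev.score:
                        found[dkey] = LocalAlignment(
                            read_id=read_id,
                            mate=mate,
                            chrom=name,
                            p=local,
                            q=q,
                            length=length,
                            strand=strand,
                            score=score,
                            edit_distance=edits,
                            read_length=L,
                        )
        results = sorted(
            found.values(), key=lambda a: (-a.score, a.chrom, a.p, a.strand)
        )
        return results

    def _extend_diagonal(
        self, qarr: np.ndarray, diag: int
    ) -> Optional[Tuple[int, int, int, int, int]]:
        """Best-scoring gapless run on one diagonal (Kadane on +2/-2)."""
        idx = self.index
        L = len(qarr)
        anchor = diag if diag >= 0 else 0
        if anchor >= idx.total:
            return None
        s0, s1 = idx.bounds(min(max(diag, 0), idx.total - 1))
        i0 = max(0, s0 - diag)
        i1 = min(L, s1 - diag)
        if i1 - i0 < 1:
            return None
        t = idx.arr[diag + i0 : diag + i1]
        q = qarr[i0:i1]
        m = (t == q) & (q < 4) & (t < 4)
        sc = np.where(m, self.scoring.match, self.scoring.mismatch).astype(np.int64)
        prefix = np.concatenate([[0], np.cumsum(sc)])
        minpre = np.minimum.accumulate(prefix[:-1])
        gains = prefix[1:] - minpre
        jend = int(np.argmax(gains))
        best = int(gains[jend])
        if best <= 0:
            return None
        jstart = int(np.argmin(prefix[: jend + 1]))
        length = jend + 1 - jstart
        edits = int((~m[jstart : jend + 1]).sum())
        return i0 + jstart, length, best, edits, diag + i0 + jstart

    def best_local_score(self, seq: str) -> int:
        """Score of the single best contiguous local alignment of ``seq``."""
        alns = self.local_alignments(seq, apply_threshold=False)
        return max((a.score for a in alns), default=0)

    def fetch(self, name: str, start: int, end: int) -> str:
        """Slice of an indexed target sequence (clipped to bounds)."""
        i = self.index.names.index(name)
        s0, s1 = int(self.index.starts[i]), int(self.index.ends[i])
        a = max(s0, s0 + start)
        b = min(s1, s0 + end)
        if b <= a:
            return ""
        return "".join("ACGTN"[v] for v in self.index.arr[a:b])


# ---------------------------------------------------------------------------
# external aligner + SAM ingest


@dataclass
class ExternalAligner:
    """Command-template delegation to any SAM-emitting aligner.

    The template is formatted with {reads1}, {reads2} (optional), {index} and
    {out_sam}; a non-zero exit aborts with the captured stderr.
    """

    command_template: str
    index_path: str = ""

    def run(self, reads1: str, out_sam: str, reads2: Optional[str] = None) -> str:
        cmd = self.command_template.format(
            reads1=reads1, reads2=reads2 or "", index=self.index_path, out_sam=out_sam
        )
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"aligner failed (exit {proc.returncode}): {cmd}\n{proc.stderr}"
            )
        return out_sam


def _mate_of(rec: pysam.AlignedSegment) -> int:
    if not rec.is_paired:
        return 0
    return 1 if rec.is_read1 else 2


def read_end_to_end_sam(
    path: str, mapped_to: str = "genome"
) -> Tuple[List[EndToEndAlignment], set]:
    """Ingest end-to-end alignments from SAM/BAM (bypass mode)."""
    alns: List[EndToEndAlignment] = []
    unmapped = set()
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            rid = rec.query_name
            mate = _mate_of(rec)
            if rec.is_unmapped:
                unmapped.add((rid, mate))
                continue
            blocks = tuple(rec.get_blocks())
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            alns.append(
                EndToEndAlignment(
                    read_id=rid,
                    mate=mate,
                    chrom=rec.reference_name,
                    blocks=blocks,
                    strand="-" if rec.is_reverse else "+",
                    mapped_to=mapped_to,
                    mismatches=int(nm),
                    read_length=rec.query_length or rec.infer_query_length() or 0,
                )
            )
    return alns, unmapped


def read_local_sam(path: str, scoring: AlignScoring = AlignScoring()) -> List[LocalAlignment]:
    """Ingest local alignments (soft-clipped SAM records) as LocalAlignments."""
    out: List[LocalAlignment] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            cig = rec.cigartuples or []
            lead = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
            alen = rec.query_alignment_length
            read_len = rec.infer_read_length() or (lead + alen)
            q = lead if not rec.is_reverse else read_len - (lead + alen)
            nm = int(rec.get_tag("NM")) if rec.has_tag("NM") else 0
            score = (
                int(rec.get_tag("AS"))
                if rec.has_tag("AS")
                else scoring.match * (alen - nm) + scoring.mismatch * nm
            )
            out.append(
                LocalAlignment(
                    read_id=rec.query_name,
                    mate=_mate_of(rec),
                    chrom=rec.reference_name,
                    p=rec.reference_start,
                    q=q,
                    length=alen,
                    strand="-" if rec.is_reverse else "+",
                    score=score,
                    edit_distance=nm,
                    read_length=read_len,
                )
            )
    return out


# ---------------------------------------------------------------------------
# pair classification / insert model / expression


def genomic_gap(a1: EndToEndAlignment, a2: EndToEndAlignment) -> Optional[int]:
    """Gap between the two alignments' genomic footprints (0 if overlapping);
    None when on different chromosomes."""
    if a1.chrom != a2.chrom:
        return None
    return max(0, max(a1.start, a2.start) - min(a1.end, a2.end))


def classify_pair(
    a1: EndToEndAlignment, a2: EndToEndAlignment, I_max: int = 20_000
) -> str:
    """'proper' iff same chromosome and genomic distance <= I_max (symmetric)."""
    gap = genomic_gap(a1, a2)
    return "proper" if gap is not None and gap <= I_max else "bridge_candidate"


def pair_insert_size(a1: EndToEndAlignment, a2: EndToEndAlignment) -> Optional[float]:
    """Outer distance of a concordant pair, measured in the spliced
    (transcript) frame when both mates map to the same transcript, else in
    the genomic frame."""
    if (
        a1.transcript_id is not None
        and a1.transcript_id == a2.transcript_id
        and a1.t_start is not None
        and a2.t_start is not None
    ):
        return float(max(a1.t_end, a2.t_end) - min(a1.t_start, a2.t_start))
    if a1.mapped_to != a2.mapped_to or a1.transcript_id != a2.transcript_id:
        # mixed frames would count intron bases into the insert
        return None
    if a1.chrom != a2.chrom:
        return None
    return float(max(a1.end, a2.end) - min(a1.start, a2.start))


def estimate_insert_model(inserts: Sequence[float]) -> InsertSizeModel:
    """Sample mean / sample sd of outer-distance insert sizes."""
    arr = np.asarray(list(inserts), dtype=float)
    if len(arr) < 2:
        raise ValueError("insert-size model needs at least 2 concordant pairs")
    return InsertSizeModel(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=len(arr))


def estimate_expression(alignments: Iterable[EndToEndAlignment], db) -> Dict[str, float]:
    """Per-gene mean read depth over exonic positions, from proper alignments.

    Depth is total aligned bases falling in the gene's exonic union divided
    by the union's length (exons shared between isoforms count once).
    """
    from intervaltree import IntervalTree

    exon_len: Dict[str, int] = {}
    trees: Dict[str, IntervalTree] = {}
    for gene_id, txs in db.genes().items():
        ivs = sorted((a, b) for t in txs for a, b in t.exons)
        merged: List[List[int]] = []
        for a, b in ivs:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        exon_len[gene_id] = sum(b - a for a, b in merged)
        chrom = txs[0].chrom
        tree = trees.setdefault(chrom, IntervalTree())
        for a, b in merged:
            tree.addi(a, b, gene_id)
    covered: Dict[str, int] = {g: 0 for g in exon_len}
    for aln in alignments:
        tree = trees.get(aln.chrom)
        if tree is None:
            continue
        for a, b in aln.blocks:
            for iv in tree.overlap(a, b):
                ov = min(b, iv.end) - max(a, iv.begin)
                if ov > 0:
                    covered[iv.data] += ov
    return {
        g: (covered.get(g, 0) / exon_len[g] if exon_len[g] else 0.0) for g in exon_len
    }
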