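"""Cluster engine: insertion/merge rules, directional and breakpoint
separation, order-independence, rescue, and fusion assembly."""

from itertools import permutations

import pytest

from chimerascope.alignment import AlignScoring, EndToEndAlignment, InsertSizeModel
from chimerascope.clusters import (
    BPCMember,
    bridge_bpc,
    build_clusters,
    cluster_bpcs,
    form_putative_fusions,
    member_cluster_map,
    partner_links,
    rescue_alignments,
    split_bpc,
    split_by_breakpoint,
    split_by_directionality,
)
from chimerascope.refdb import TranscriptDB, TranscriptModel
from chimerascope.splits import LocalAlignment, SplitCandidate, form_split_candidates


def member(bpc_id, start, end, side="right", chrom="chr1", bp=None, kind="split",
           strand="+", slot=0, rid="r", mate=1):
    return BPCMember(
        bpc_id=bpc_id, slot=slot, kind=kind, chrom=chrom, start=start, end=end,
        side=side, strand=strand, breakpoint=bp, read_id=rid, mate=mate,
    )


def la(chrom, p, q, length, strand="+", rid="r", mate=1, score=None, ed=0, read_len=100):
    return LocalAlignment(
        read_id=rid, mate=mate, chrom=chrom, p=p, q=q, length=length, strand=strand,
        score=score if score is not None else 2 * length, edit_distance=ed,
        read_length=read_len,
    )


def make_split(bpc_id, c1, p1, c2, p2, seg=50, rid=None, strand1="+", strand2="+"):
    rid = rid or f"r{bpc_id}"
    first = la(c1, p1, 0, seg, strand1, rid=rid)
    second = la(c2, p2, seg, seg, strand2, rid=rid)
    return split_bpc(bpc_id, SplitCandidate(first=first, second=second, gap=0))


class TestBuildClusters:
    def test_disjoint_members_make_separate_clusters(self):
        ms = [member(1, 100, 200), member(2, 1000, 1100), member(3, 5000, 5100)]
        assert len(build_clusters(ms)) == 3

    def test_chained_overlap_merges_to_one(self):
        """[100,200) + [150,250) + [240,300) inserted in order: one cluster
        spanning [100,300)."""
        ms = [member(1, 100, 200), member(2, 150, 250), member(3, 240, 300)]
        out = build_clusters(ms)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (100, 300)

    def test_bridging_member_merges_two_clusters(self):
        ms = [member(1, 100, 200), member(2, 300, 400), member(3, 150, 350)]
        out = build_clusters(ms)
        assert len(out) == 1 and len(out[0].members) == 3

    def test_insertion_order_invariance(self):
        """All insertion orders of a member set give the same clustering."""
        base = [member(i, s, e) for i, (s, e) in enumerate(
            [(100, 200), (150, 250), (400, 500), (480, 520), (900, 950)]
        )]
        ref = None
        for perm in permutations(base):
            out = build_clusters(list(perm))
            sig = sorted(
                (c.chrom, c.start, c.end, tuple(sorted(m.bpc_id for m in c.members)))
                for c in out
            )
            if ref is None:
                ref = sig
            assert sig == ref

    def test_conservation(self):
        ms = [member(i, 10 * i, 10 * i + 25) for i in range(12)]
        out = build_clusters(ms)
        placed = [m.bpc_id for c in out for m in c.members]
        assert sorted(placed) == list(range(12))


class TestDirectionality:
    def test_mixed_sides_separate(self):
        c = build_clusters(
            [member(1, 100, 200, side="right"), member(2, 120, 220, side="left")]
        )[0]
        parts = split_by_directionality(c)
        assert len(parts) == 2
        assert {p.side for p in parts} == {"left", "right"}

    def test_homogeneous_unchanged(self):
        c = build_clusters([member(1, 100, 200), member(2, 120, 220)])[0]
        assert split_by_directionality(c) == [c]

    def test_split_first_segment_and_bridge_mate_cocluster(self):
        """A plus-strand SPLIT first segment and a plus-strand BRIDGE mate
        both point right and stay in one cluster."""
        s = make_split(1, "chr1", 100, "chr9", 5000)
        b = bridge_bpc(
            2,
            EndToEndAlignment("rb", 1, "chr1", ((120, 195),), "+", "genome", read_length=75),
            EndToEndAlignment("rb", 2, "chr9", ((5100, 5175),), "-", "genome", read_length=75),
        )
        assert s.members[0].side == "right" and b.members[0].side == "right"
        clusters = cluster_bpcs([s, b])
        chr1 = [c for c in clusters if c.chrom == "chr1"]
        assert len(chr1) == 1 and len(chr1[0].members) == 2


class TestBreakpointSeparation:
    def test_tolerance_grouping(self):
        """Breakpoints {1000, 1004, 1050} at tol 10 give groups
        {1000,1004} and {1050}."""
        c = build_clusters(
            [
                member(1, 950, 1001, bp=1000),
                member(2, 955, 1005, bp=1004),
                member(3, 1000, 1051, bp=1050),
            ]
        )[0]
        c.side = "right"
        parts = split_by_breakpoint(c, tol=10)
        bps = sorted(p.breakpoint_pos for p in parts)
        assert bps == [1000, 1050]
        sizes = sorted(len(p.members) for p in parts)
        assert sizes == [1, 2]

    def test_identical_breakpoints_unchanged(self):
        c = build_clusters([member(i, 900, 1001, bp=1000) for i in range(3)])[0]
        c.side = "right"
        parts = split_by_breakpoint(c, tol=10)
        assert len(parts) == 1 and parts[0].breakpoint_pos == 1000
        assert not parts[0].approximate

    def test_chain_linkage_is_single_linkage(self):
        """{1000, 1008, 1016}: consecutive gaps of 8 chain into one group."""
        c = build_clusters(
            [member(i, 950, 1020, bp=1000 + 8 * i) for i in range(3)]
        )[0]
        c.side = "right"
        parts = split_by_breakpoint(c, tol=10)
        assert len(parts) == 1

    def test_consensus_is_majority_position(self):
        c = build_clusters(
            [member(i, 950, 1010, bp=p) for i, p in enumerate([1000, 1000, 1003])]
        )[0]
        c.side = "right"
        (out,) = split_by_breakpoint(c, tol=10)
        assert out.breakpoint_pos == 1000

    def test_bridge_only_cluster_stays_approximate(self):
        c = build_clusters([member(1, 100, 200, kind="bridge")])[0]
        c.side = "right"
        (out,) = split_by_breakpoint(c, tol=10)
        assert out.approximate and out.breakpoint_pos == 199


class TestIdempotence:
    def test_reclustering_final_output_changes_nothing(self):
        bpcs = [
            make_split(1, "chr1", 100, "chr2", 5000),
            make_split(2, "chr1", 120, "chr2", 4980),
            make_split(3, "chr1", 400, "chr3", 9000),
        ]
        first = cluster_bpcs(bpcs)
        for c in first:
            again = cluster_bpcs_members(c)
            assert len(again) == 1
            assert (again[0].start, again[0].end) == (c.start, c.end)
            assert again[0].breakpoint_pos == c.breakpoint_pos


def cluster_bpcs_members(cluster):
    out = build_clusters(cluster.members)
    res = []
    for c in out:
        for d in split_by_directionality(c):
            res.extend(split_by_breakpoint(d))
    return res


class TestRescue:
    def _setup(self):
        """Two SPLIT reads defining a chr1[...1049] | chr2[5000...] fusion,
        plus an artificial genome fetcher."""
        import numpy as np

        rng = np.random.default_rng(3)
        genome = {
            "chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, 8000)),
            "chr2": "".join("ACGT"[i] for i in rng.integers(0, 4, 8000)),
        }

        def fetch(chrom, a, b):
            return genome[chrom][max(0, a) : b]

        bpcs = [
            make_split(1, "chr1", 1000, "chr2", 5000, rid="s1"),
            make_split(2, "chr1", 1000, "chr2", 5000, rid="s2"),
        ]
        clusters = cluster_bpcs(bpcs)
        assign = member_cluster_map(clusters)
        links = partner_links(bpcs, assign)
        return genome, fetch, bpcs, clusters, links

    def test_compatible_half_read_is_rescued(self):
        genome, fetch, bpcs, clusters, links = self._setup()
        # read: 60 bases ending at the chr1 breakpoint + 15 partner bases
        read = genome["chr1"][990:1050] + genome["chr2"][5000:5015]
        host_la = la("chr1", 990, 0, 60, rid="u1", read_len=75, score=120)
        new = rescue_alignments(
            clusters, [host_la], {("u1", 1): read}, fetch, links,
            scoring=AlignScoring(), next_bpc_id=10,
        )
        assert len(new) == 1
        assert new[0].rescued
        sc = new[0].split
        assert sc.second.chrom == "chr2" and sc.second.p == 5000

    def test_high_edit_distance_never_rescued(self):
        genome, fetch, bpcs, clusters, links = self._setup()
        read = genome["chr1"][990:1050] + genome["chr2"][5000:5015]
        host_la = la("chr1", 990, 0, 60, rid="u1", read_len=75, score=120, ed=2)
        new = rescue_alignments(
            clusters, [host_la], {("u1", 1): read}, fetch, links,
            scoring=AlignScoring(), next_bpc_id=10,
        )
        assert new == []

    def test_low_score_never_rescued(self):
        genome, fetch, bpcs, clusters, links = self._setup()
        read = genome["chr1"][1020:1050] + genome["chr2"][5000:5045]
        host_la = la("chr1", 1020, 0, 30, rid="u1", read_len=75, score=60)
        new = rescue_alignments(
            clusters, [host_la], {("u1", 1): read}, fetch, links,
            scoring=AlignScoring(), next_bpc_id=10,
        )
        assert new == []  # 60 <= 0.5 * 150

    def test_rescue_never_moves_exact_breakpoints(self):
        genome, fetch, bpcs, clusters, links = self._setup()
        before = {c.id: c.breakpoint_pos for c in clusters if not c.approximate}
        read = genome["chr1"][990:1050] + genome["chr2"][5000:5015]
        host_la = la("chr1", 990, 0, 60, rid="u1", read_len=75, score=120)
        rescue_alignments(
            clusters, [host_la], {("u1", 1): read}, fetch, links,
            scoring=AlignScoring(), next_bpc_id=10,
        )
        after = {c.id: c.breakpoint_pos for c in clusters if c.id in before}
        assert after == before

    def test_bridge_only_breakpoint_voted_by_evidence(self):
        """Rescued reads fix a BRIDGE-only breakpoint at the majority
        position."""
        import numpy as np

        rng = np.random.default_rng(4)
        genome = {
            "chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, 8000)),
            "chr2": "".join("ACGT"[i] for i in rng.integers(0, 4, 8000)),
        }

        def fetch(chrom, a, b):
            return genome[chrom][max(0, a) : b]

        bpcs = [
            bridge_bpc(
                1,
                EndToEndAlignment("b1", 1, "chr1", ((1300, 1375),), "+", "genome", read_length=75),
                EndToEndAlignment("b1", 2, "chr2", ((5100, 5175),), "-", "genome", read_length=75),
            ),
            bridge_bpc(
                2,
                EndToEndAlignment("b2", 1, "chr1", ((1320, 1395),), "+", "genome", read_length=75),
                EndToEndAlignment("b2", 2, "chr2", ((5080, 5155),), "-", "genome", read_length=75),
            ),
        ]
        clusters = cluster_bpcs(bpcs)
        assign = member_cluster_map(bpcs and clusters)
        links = partner_links(bpcs, assign)
        model = InsertSizeModel(mean=300, sd=80, n=100)
        unused = []
        seqs = {}
        for i, (cut, rid) in enumerate([(1500, "u1"), (1500, "u2"), (1490, "u3")]):
            read = genome["chr1"][cut - 60 : cut] + genome["chr2"][5000 : 5015]
            unused.append(la("chr1", cut - 60, 0, 60, rid=rid, read_len=75, score=120))
            seqs[(rid, 1)] = read
        new = rescue_alignments(
            clusters, unused, seqs, fetch, links, scoring=AlignScoring(),
            insert_model=model, next_bpc_id=10,
        )
        assert len(new) == 3
        host = next(c for c in clusters if c.chrom == "chr1")
        assert host.breakpoint_pos == 1499  # two reads end at 1500, one at 1490
        assert not host.approximate


class TestFormPutativeFusions:
    def test_support_aggregation(self):
        bpcs = [make_split(i, "chr1", 100 + i, "chr2", 5000) for i in range(1, 6)]
        for j in (6, 7):
            bpcs.append(
                bridge_bpc(
                    j,
                    EndToEndAlignment(f"b{j}", 1, "chr1", ((80, 155),), "+", "genome", read_length=75),
                    EndToEndAlignment(f"b{j}", 2, "chr2", ((5005, 5080),), "-", "genome", read_length=75),
                )
            )
        clusters = cluster_bpcs(bpcs)
        fusions = form_putative_fusions(clusters, bpcs, "none", None)
        assert len(fusions) == 1
        assert (fusions[0].n_split, fusions[0].n_bridge) == (5, 2)

    def test_unstranded_order_follows_annotation(self):
        """Two plus-strand genes in genomic left-right order: the left gene
        is the 5' partner."""
        db = TranscriptDB(
            [
                TranscriptModel("tL", "gL", "gL", "chr1", "+", [(0, 2000)]),
                TranscriptModel("tR", "gR", "gR", "chr1", "+", [(50_000, 52_000)]),
            ]
        )
        bpcs = [make_split(1, "chr1", 950, "chr1", 51_000, rid="r1"),
                make_split(2, "chr1", 950, "chr1", 51_000, rid="r2")]
        clusters = cluster_bpcs(bpcs)
        fusions = form_putative_fusions(clusters, bpcs, "none", db)
        f = fusions[0]
        assert f.cluster_5p.chrom == "chr1" and f.cluster_5p.breakpoint_pos == 999
        assert f.strand_5p == "+" and f.strand_3p == "+"

    def test_degenerate_same_cluster_bpc_dropped(self):
        b = make_split(1, "chr1", 100, "chr1", 120)  # both segments co-cluster
        clusters = cluster_bpcs([b])
        # both members share one span -> one cluster after direction split?
        fusions = form_putative_fusions(clusters, [b], "none", None)
        for f in fusions:
            assert f.cluster_5p.id != f.cluster_3p.id

    def test_stranded_order_from_read_orientation(self):
        """Forward protocol: mate-1 SPLIT first segment marks the 5' side."""
        bpcs = [make_split(i, "chr2", 7000, "chr1", 100, rid=f"r{i}") for i in (1, 2)]
        clusters = cluster_bpcs(bpcs)
        fusions = form_putative_fusions(clusters, bpcs, "forward", None)
        f = fusions[0]
        assert f.cluster_5p.chrom == "chr2"
        assert f.order_confident
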