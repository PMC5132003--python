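"""Fusion refinement and filtering: score, multimap resolution, features
and the threshold verdicts with their monotonicity property."""

import numpy as np
import pytest

from chimerascope.alignment import AlignScoring, EndToEndAlignment, InsertSizeModel, InternalAligner
from chimerascope.clusters import (
    bridge_bpc,
    cluster_bpcs,
    form_putative_fusions,
    split_bpc,
)
from chimerascope.filters import (
    FilterThresholds,
    FusionFeatures,
    apply_filters,
    compute_coverage_features,
    compute_homogeneity,
    compute_homology_score,
    compute_insert_validity,
    compute_strand_concordance,
    enforce_split_mate_consistency,
    fusion_score,
    merge_bridge_only_fusions,
    pair_outer_distance,
    resolve_multimapped,
)
from chimerascope.splits import LocalAlignment, SplitCandidate


def la(chrom, p, q, length, strand="+", rid="r", mate=1, score=None, ed=0, read_len=100):
    return LocalAlignment(
        read_id=rid, mate=mate, chrom=chrom, p=p, q=q, length=length, strand=strand,
        score=score if score is not None else 2 * length, edit_distance=ed,
        read_length=read_len,
    )


_FID = [0]


def make_fusion(n_split=2, n_bridge=0, p1=1000, p2=5000, multimap=1, rid_prefix="r",
                strandedness="none", mate_consistent=True, split_positions=None):
    bpcs = []
    bid = 0
    for i in range(n_split):
        bid += 1
        pos1 = split_positions[i] if split_positions else p1
        sc = SplitCandidate(
            first=la("chr1", pos1, 0, 50, rid=f"{rid_prefix}{bid}"),
            second=la("chr2", p2, 50, 50, rid=f"{rid_prefix}{bid}"),
            gap=0,
        )
        b = split_bpc(bid, sc, multimap_count=multimap)
        b.mate_consistent = mate_consistent
        bpcs.append(b)
    for _ in range(n_bridge):
        bid += 1
        bpcs.append(
            bridge_bpc(
                bid,
                EndToEndAlignment(f"{rid_prefix}{bid}", 1, "chr1", ((p1 - 60, p1 + 15),), "+", "genome", read_length=75),
                EndToEndAlignment(f"{rid_prefix}{bid}", 2, "chr2", ((p2 + 10, p2 + 85),), "-", "genome", read_length=75),
            )
        )
    clusters = cluster_bpcs(bpcs)
    fusions = form_putative_fusions(clusters, bpcs, strandedness, None)
    assert len(fusions) == 1
    _FID[0] += 1
    fusions[0].id = _FID[0]  # unique across separately built fixtures
    return fusions[0]


class TestFusionScore:
    def test_stated_default_weights(self):
        """2 unique mated SPLITs + 1 BRIDGE = 3 + 3 + 1 = 7."""
        f = make_fusion(n_split=2, n_bridge=1)
        assert fusion_score(f) == 7.0

    def test_zero_support(self):
        f = make_fusion(n_split=1)
        f.bpcs = []
        assert fusion_score(f) == 0.0

    def test_monotone_in_support(self):
        small = make_fusion(n_split=1, n_bridge=0)
        for ns, nb in [(1, 1), (2, 1), (3, 2)]:
            bigger = make_fusion(n_split=ns, n_bridge=nb)
            assert fusion_score(bigger) >= fusion_score(small)

    def test_multimapped_and_unmated_weights(self):
        multi = make_fusion(n_split=1, multimap=3)
        assert fusion_score(multi) == 1.0
        unmated = make_fusion(n_split=1, mate_consistent=None)
        assert fusion_score(unmated) == 2.0


class TestResolveMultimapped:
    def test_dominant_fusion_wins(self):
        strong = make_fusion(n_split=10, p1=1000, p2=5000, rid_prefix="s")
        weak = make_fusion(n_split=2, p1=50_000, p2=90_000, rid_prefix="w")
        shared = split_bpc(
            99,
            SplitCandidate(
                first=la("chr1", 1000, 0, 50, rid="shared"),
                second=la("chr2", 5000, 50, 50, rid="shared"),
            gap=0),
            multimap_count=2,
        )
        strong.bpcs.append(shared)
        weak.bpcs.append(shared)
        out = resolve_multimapped([weak, strong])
        holders = [f for f in out if any(b.bpc_id == 99 for b in f.bpcs)]
        assert holders == [strong]

    def test_every_read_supports_one_fusion(self):
        f1 = make_fusion(n_split=3, rid_prefix="a")
        f2 = make_fusion(n_split=3, p1=50_000, p2=90_000, rid_prefix="a")  # same read ids
        out = resolve_multimapped([f1, f2])
        seen = {}
        for f in out:
            for b in f.bpcs:
                key = (b.members[0].read_id, b.members[0].mate)
                assert key not in seen
                seen[key] = f.id

    def test_symmetric_tie_breaks_to_smallest_key(self):
        f1 = make_fusion(n_split=2, rid_prefix="x")
        f2 = make_fusion(n_split=2, p1=50_000, p2=90_000, rid_prefix="x")
        out = resolve_multimapped([f1, f2])
        winner = [f for f in out if f.bpcs]
        assert len(winner) == 1
        assert winner[0].key == min(f1.key, f2.key)


class TestHomogeneity:
    def test_sole_fusion_weight_one(self):
        f = make_fusion(n_split=3)
        assert compute_homogeneity([f])[f.id] == 1.0

    def test_shared_metacluster_division(self):
        """8 supporting alignments out of 40 in the metacluster: weight 0.2."""
        f1 = make_fusion(n_split=8, rid_prefix="a")
        f2 = make_fusion(n_split=32, p2=5100, rid_prefix="b")  # shares the 5' locus
        w = compute_homogeneity([f1, f2])
        assert w[f1.id] == pytest.approx(8 / 40)
        assert w[f2.id] == pytest.approx(32 / 40)

    def test_weights_per_metacluster_sum_to_at_most_one(self):
        fusions = [
            make_fusion(n_split=4, rid_prefix="a"),
            make_fusion(n_split=6, p2=5100, rid_prefix="b"),
            make_fusion(n_split=2, p2=5200, rid_prefix="c"),
        ]
        w = compute_homogeneity(fusions)
        assert sum(w.values()) <= 1.0 + 1e-9


class TestCoverageFeatures:
    def test_identical_footprints_fraction(self):
        """10 SPLITs with one distinct footprint: unique fraction 0.1."""
        f = make_fusion(n_split=10)
        usf, dev, uniq, _f5, _f3 = compute_coverage_features(f)
        assert usf == pytest.approx(0.1)
        assert uniq  # multimap_count == 1

    def test_centered_offsets_have_low_deviation(self):
        f = make_fusion(n_split=2)
        # first segments end at read offset 50 of a 100 bp read: exactly L/2
        _usf, dev, _uniq, _f5, _f3 = compute_coverage_features(f)
        assert dev == pytest.approx(0.0)

    def test_all_multimapped_fails_unique_requirement(self):
        f = make_fusion(n_split=3, multimap=4)
        _usf, _dev, uniq, _f5, _f3 = compute_coverage_features(f)
        assert not uniq
        verdict = apply_filters(f, FusionFeatures(has_unique_split=False), FilterThresholds())
        assert "has_unique_split" in verdict.reasons


@pytest.fixture(scope="module")
def aligner():
    rng = np.random.default_rng(11)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 20_000))
    return seq, InternalAligner({"g": seq})


class TestHomology:

    def test_chimeric_junction_scores_near_half(self, aligner):
        seq, al = aligner
        junction = seq[1000:1300] + seq[10_000:10_300]
        s = compute_homology_score(junction, [al])
        assert 0.4 <= s <= 0.6

    def test_contiguous_reference_sequence_scores_one(self, aligner):
        seq, al = aligner
        junction = seq[3000:3600]
        s = compute_homology_score(junction, [al])
        assert s == pytest.approx(1.0, abs=0.02)

    def test_reverse_complement_invariance(self, aligner):
        from chimerascope.refdb import revcomp

        seq, al = aligner
        junction = seq[1000:1300] + seq[10_000:10_300]
        s1 = compute_homology_score(junction, [al])
        s2 = compute_homology_score(revcomp(junction), [al])
        assert s1 == pytest.approx(s2, abs=0.05)


class TestInsertValidity:
    def test_three_sigma_boundary(self):
        m = InsertSizeModel(mean=300, sd=80, n=100)
        assert compute_insert_validity([540], m, 1) == 1.0
        assert compute_insert_validity([541], m, 1) == 0.0

    def test_all_valid(self):
        m = InsertSizeModel(mean=300, sd=80, n=100)
        assert compute_insert_validity([250, 300, 350, 400, 100], m, 5) == 1.0

    def test_not_applicable_without_bridges(self):
        m = InsertSizeModel(mean=300, sd=80, n=100)
        assert compute_insert_validity([], m, 0) == 1.0

    def test_pair_placement_on_junction(self):
        from chimerascope.refdb import revcomp

        rng = np.random.default_rng(12)
        target = "".join("ACGT"[i] for i in rng.integers(0, 4, 1_000))
        s1, s2 = target[100:175], revcomp(target[325:400])
        assert pair_outer_distance(s1, s2, target) == 300.0


class TestStrandConcordance:
    def test_concordant_forward_protocol(self):
        f = make_fusion(n_split=4, strandedness="forward")
        conc, a5, a3 = compute_strand_concordance(f, "forward", f.strand_5p, f.strand_3p)
        assert conc == 1.0 and not a5 and not a3

    def test_antisense_partner_flagged(self):
        f = make_fusion(n_split=4, strandedness="forward")
        # annotated strand opposes the transcribed strand at the 3' partner
        opposite = "-" if f.strand_3p == "+" else "+"
        conc, _a5, a3 = compute_strand_concordance(f, "forward", f.strand_5p, opposite)
        assert conc == 1.0 and a3

    def test_unstranded_inert(self):
        f = make_fusion(n_split=4)
        assert compute_strand_concordance(f, "none", "+", "+") == (1.0, False, False)


class TestRefinement:
    def test_mate_within_intron_size_kept(self):
        f = make_fusion(n_split=1)
        locs = {("r1", 2): [("chr2", 5200, 5275)]}
        enforce_split_mate_consistency(f, locs, paired=True)
        assert f.n_split == 1 and f.splits[0].mate_consistent

    def test_contradicting_mate_removes_split(self):
        f = make_fusion(n_split=1)
        locs = {("r1", 2): [("chr7", 1_000_000, 1_000_075)]}
        enforce_split_mate_consistency(f, locs, paired=True)
        assert f.n_split == 0

    def test_single_end_identity(self):
        f = make_fusion(n_split=2)
        before = list(f.bpcs)
        enforce_split_mate_consistency(f, {}, paired=False)
        assert f.bpcs == before

    def test_bridge_only_fusion_absorbed_nearby(self):
        backed = make_fusion(n_split=3, n_bridge=0, rid_prefix="a")
        bridge_only = make_fusion(n_split=0, n_bridge=2, p1=1000 + 3000, p2=5000 + 2500, rid_prefix="b")
        out = merge_bridge_only_fusions([backed, bridge_only])
        assert len(out) == 1
        assert out[0].n_split == 3 and out[0].n_bridge == 2

    def test_distant_events_not_merged(self):
        backed = make_fusion(n_split=3, rid_prefix="a")
        faraway = make_fusion(n_split=0, n_bridge=2, p1=900_000, p2=700_000, rid_prefix="b")
        out = merge_bridge_only_fusions([backed, faraway])
        assert len(out) == 2

    def test_merge_respects_direction(self):
        backed = make_fusion(n_split=3, rid_prefix="a")
        flipped = make_fusion(n_split=0, n_bridge=2, p1=2000, p2=6000, rid_prefix="b")
        # force opposite directionality on the bridge-only event
        flipped.cluster_5p.side = "left"
        flipped.cluster_3p.side = "right"
        out = merge_bridge_only_fusions([backed, flipped])
        assert len(out) == 2


class TestApplyFilters:
    def test_defaults_pass_clean_fusion(self):
        f = make_fusion(n_split=3, n_bridge=1)
        v = apply_filters(f, FusionFeatures(has_unique_split=True), FilterThresholds())
        assert v.passed and v.reasons == []

    def test_single_multimapped_split_fails_twice(self):
        f = make_fusion(n_split=1, multimap=5)
        feats = FusionFeatures(has_unique_split=False, unique_split_fraction=1.0)
        v = apply_filters(f, feats, FilterThresholds())
        assert set(v.reasons) >= {"min_support", "has_unique_split"}

    def test_biotype_rule_and_override(self):
        f = make_fusion(n_split=3)
        feats = FusionFeatures(
            has_unique_split=True, biotypes_5p=("processed_pseudogene",),
            biotypes_3p=("protein_coding",),
        )
        assert "biotype_5p" in apply_filters(f, feats, FilterThresholds()).reasons
        ok = apply_filters(
            f, feats, FilterThresholds(allow_discarded_biotypes=True)
        )
        assert ok.passed

    def test_intergenic_control(self):
        f = make_fusion(n_split=3)
        feats = FusionFeatures(has_unique_split=True, intergenic_3p=True)
        assert apply_filters(f, feats, FilterThresholds()).passed
        v = apply_filters(f, feats, FilterThresholds(allow_intergenic=False))
        assert "intergenic" in v.reasons

    def test_relaxing_thresholds_never_shrinks_pass_set(self, rng):
        """Monotonicity: decreasing filtering limits only increases recall."""
        fusions = []
        featsets = []
        for i in range(30):
            f = make_fusion(
                n_split=int(rng.integers(0, 4)), n_bridge=1 + int(rng.integers(0, 2)),
                p1=1000 + 10_000 * i, p2=5000 + 10_000 * i, rid_prefix=f"f{i}_",
            )
            feats = FusionFeatures(
                homogeneity_weight=float(rng.random()),
                unique_split_fraction=float(rng.random()),
                mean_breakpoint_offset_dev=float(rng.random() * 0.5),
                has_unique_split=bool(rng.random() < 0.7),
                homology_score=float(rng.random()),
                valid_insert_ratio=float(rng.random()),
                strand_concordance=float(rng.random()),
            )
            fusions.append(f)
            featsets.append(feats)
        base = FilterThresholds()
        passing = {
            f.id
            for f, ft in zip(fusions, featsets)
            if apply_filters(f, ft, base, stranded=True).passed
        }
        relaxations = [
            FilterThresholds(min_support=1),
            FilterThresholds(min_homogeneity=0.0),
            FilterThresholds(min_unique_split_fraction=0.0),
            FilterThresholds(max_breakpoint_offset_dev=1.0),
            FilterThresholds(max_homology_score=1.1),
            FilterThresholds(min_valid_insert_ratio=0.0),
            FilterThresholds(min_strand_concordance=0.0),
        ]
        for th in relaxations:
            wider = {
                f.id
                for f, ft in zip(fusions, featsets)
                if apply_filters(f, ft, th, stranded=True).passed
            }
            assert passing <= wider


class TestThresholdConfig:
    def test_round_trip_file(self, tmp_path):
        th = FilterThresholds(min_support=5, allow_intergenic=False)
        path = tmp_path / "thresholds.cfg"
        th.save(str(path))
        assert FilterThresholds.load(str(path)) == th

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "bad.cfg"
        p.write_text("nonsense=1\n")
        with pytest.raises(ValueError):
            FilterThresholds.load(str(p))
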