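"""End-to-end fusion-calling pipeline.

Steps: (1) end-to-end alignment of reads to the transcriptome and,
optionally, the genome; (2) local alignment of the remaining unmapped
reads; (3) SPLIT detection from local alignments; (4) pair analysis -
insert-size model, discordant (BRIDGE) pairs - skipped for single-end
data; (5) clustering, rescue and putative-fusion assembly; (6) refinement
and filtering; (7) reporting.  Each run writes its effective configuration
and a pre-filter feature checkpoint to the working directory so that
filtering can be repeated with adjusted thresholds without re-alignment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import pysam

from . import clusters as cl
from . import filters as fl
from .alignment import (
    AlignScoring,
    EndToEndAlignment,
    InsertSizeModel,
    InternalAligner,
    classify_pair,
    estimate_insert_model,
    pair_insert_size,
)
from .refdb import TranscriptDB, load_annotation
from .report import (
    REPORT_COLUMNS,
    build_record,
    read_report,
    reconstruct_junction_sequence,
    write_report,
)
from .splits import SplitParams, form_split_candidates

logger = logging.getLogger(__name__)

MITO_NAMES = {"chrM", "MT", "chrMT", "M"}


@dataclass
class PipelineConfig:
    reads1: str = ""
    reads2: Optional[str] = None
    genome_fasta: str = ""
    gtf: str = ""
    workdir: str = "."
    strandedness: str = "none"  # none | forward | reverse
    I_max: int = 20_000
    split_params: SplitParams = field(default_factory=SplitParams)
    thresholds: fl.FilterThresholds = field(default_factory=fl.FilterThresholds)
    scoring: AlignScoring = field(default_factory=AlignScoring)
    discard_mito: bool = True
    map_genome: bool = True  # optional genome end-to-end pass for unmapped reads
    max_mismatches: int = 5
    seed_k: int = 20
    cluster_tol: int = 10
    edge_slack: int = 0
    junction_flank: int = 500
    report_junction_seq: bool = False
    compute_expression: bool = False
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


@dataclass
class Resources:
    """Prebuilt reference resources, reusable across runs on one genome."""

    db: TranscriptDB
    genome_aligner: InternalAligner
    tx_aligner: InternalAligner
    tx_order: List[str]

    @classmethod
    def build(cls, db: TranscriptDB, config: PipelineConfig) -> "Resources":
        genome_seqs = {
            name: str(db.genome[name][:]) for name in db.genome.keys()
        }
        tx_order = sorted(db.transcripts)
        tx_seqs = {t: db.transcript_sequence(t) for t in tx_order}
        scoring = config.scoring
        ga = InternalAligner(
            genome_seqs, k=config.seed_k, scoring=scoring,
            max_mismatches=config.max_mismatches,
        )
        ta = InternalAligner(
            tx_seqs, k=config.seed_k, scoring=scoring,
            max_mismatches=config.max_mismatches,
        )
        return cls(db=db, genome_aligner=ga, tx_aligner=ta, tx_order=tx_order)


def load_fastq(path: str) -> Tuple[List[str], List[str]]:
    names, seqs = [], []
    with pysam.FastxFile(path) as fh:
        for rec in fh:
            names.append(rec.name)
            seqs.append(rec.sequence.upper())
    return names, seqs


def _project_hit(db: TranscriptDB, tx_id: str, hit, read_id: str, mate: int, L: int) -> EndToEndAlignment:
    blocks, tx_strand = db.project_to_genome(tx_id, hit.pos, L)
    strand = tx_strand if hit.strand == "+" else ("-" if tx_strand == "+" else "+")
    return EndToEndAlignment(
        read_id=read_id,
        mate=mate,
        chrom=db.transcripts[tx_id].chrom,
        blocks=tuple(blocks),
        strand=strand,
        mapped_to="transcriptome",
        multimap_count=hit.multimap_count,
        mismatches=hit.mismatches,
        transcript_id=tx_id,
        t_start=hit.pos,
        t_end=hit.pos + L,
        read_length=L,
    )


@dataclass
class CallResult:
    records: List
    fusions: List[cl.PutativeFusion]
    features: Dict[int, fl.FusionFeatures]
    verdicts: Dict[int, fl.Verdict]
    insert_model: Optional[InsertSizeModel]
    n_reads: int
    n_end_to_end: int
    n_unmapped: int
    n_split_bpcs: int
    n_bridge_bpcs: int
    expression: Optional[Dict[str, float]] = None


def call_fusions(
    read_ids: Sequence[str],
    seqs1: Sequence[str],
    seqs2: Optional[Sequence[str]],
    resources: Resources,
    config: PipelineConfig,
) -> CallResult:
    """Run steps 1-7 in memory and return records plus intermediates."""
    db = resources.db
    paired = seqs2 is not None
    mates = [(1, seqs1)] + ([(2, seqs2)] if paired else [])
    if not paired:
        mates = [(0, seqs1)]

    # ---- Step 1: end-to-end alignment -------------------------------
    end_hits: Dict[Tuple[str, int], EndToEndAlignment] = {}
    unmapped: List[Tuple[str, int, str]] = []  # (read_id, mate, seq)
    n_mapped = 0
    for mate, seqs in mates:
        tx_hits = resources.tx_aligner.map_end_to_end_batch(seqs)
        pend: List[int] = []
        for i, hit in enumerate(tx_hits):
            if hit is None:
                pend.append(i)
                continue
            aln = _project_hit(db, hit.seq_name, hit, read_ids[i], mate, len(seqs[i]))
            if config.discard_mito and aln.chrom in MITO_NAMES:
                continue
            end_hits[(read_ids[i], mate)] = aln
            n_mapped += 1
        if config.map_genome and pend:
            g_hits = resources.genome_aligner.map_end_to_end_batch([seqs[i] for i in pend])
            still = []
            for j, hit in zip(pend, g_hits):
                if hit is None:
                    still.append(j)
                    continue
                if config.discard_mito and hit.seq_name in MITO_NAMES:
                    continue
                end_hits[(read_ids[j], mate)] = EndToEndAlignment(
                    read_id=read_ids[j],
                    mate=mate,
                    chrom=hit.seq_name,
                    blocks=((hit.pos, hit.pos + len(seqs[j])),),
                    strand=hit.strand,
                    mapped_to="genome",
                    multimap_count=hit.multimap_count,
                    mismatches=hit.mismatches,
                    read_length=len(seqs[j]),
                )
                n_mapped += 1
            pend = still
        unmapped.extend((read_ids[i], mate, seqs[i]) for i in pend)

    # ---- Step 2: local alignment of unmapped reads -------------------
    locals_by_read: Dict[Tuple[str, int], list] = {}
    read_seqs: Dict[Tuple[str, int], str] = {}
    for rid, mate, seq in unmapped:
        read_seqs[(rid, mate)] = seq
        alns = resources.genome_aligner.local_alignments(seq, read_id=rid, mate=mate)
        if config.discard_mito:
            alns = [a for a in alns if a.chrom not in MITO_NAMES]
        if alns:
            locals_by_read[(rid, mate)] = alns

    # ---- Step 3: SPLIT detection -------------------------------------
    bpcs: List[cl.BreakpointCandidate] = []
    used_locals = set()
    bpc_id = 0
    for key in sorted(locals_by_read):
        cands = form_split_candidates(locals_by_read[key], config.split_params)
        for sc in cands:
            bpc_id += 1
            bpcs.append(cl.split_bpc(bpc_id, sc, multimap_count=max(1, len(cands))))
            used_locals.add((key, sc.first.p, sc.first.chrom))
            used_locals.add((key, sc.second.p, sc.second.chrom))
    n_split_bpcs = len(bpcs)
    unused_locals = [
        a
        for key, alns in sorted(locals_by_read.items())
        for a in alns
        if (key, a.p, a.chrom) not in used_locals
    ]

    # ---- Step 4: pair analysis (skipped for single-end) --------------
    insert_model: Optional[InsertSizeModel] = None
    n_bridge = 0
    proper_blocks: Dict[str, List[Tuple[int, int]]] = {}
    proper_alns: List[EndToEndAlignment] = []
    if paired:
        inserts: List[float] = []
        for rid in read_ids:
            a1 = end_hits.get((rid, 1))
            a2 = end_hits.get((rid, 2))
            if a1 is None or a2 is None:
                continue
            if classify_pair(a1, a2, config.I_max) == "proper":
                ins = pair_insert_size(a1, a2)
                if ins is not None:
                    inserts.append(ins)
                for a in (a1, a2):
                    proper_alns.append(a)
                    for blk in a.blocks:
                        proper_blocks.setdefault(a.chrom, []).append(blk)
            else:
                if a1.multimap_count == 1 and a2.multimap_count == 1:
                    bpc_id += 1
                    bpcs.append(cl.bridge_bpc(bpc_id, a1, a2))
                    n_bridge += 1
        if len(inserts) >= 2:
            insert_model = estimate_insert_model(inserts)

    # ---- Step 5: clustering, rescue, fusion assembly -----------------
    reach = insert_model.upper if insert_model else 600.0
    clusters = cl.cluster_bpcs(bpcs, tol=config.cluster_tol, bridge_reach=reach)
    assign = cl.member_cluster_map(clusters)
    links = cl.partner_links(bpcs, assign)
    rescued = cl.rescue_alignments(
        clusters,
        unused_locals,
        read_seqs,
        resources.genome_aligner.fetch,
        links,
        scoring=config.scoring,
        insert_model=insert_model,
        next_bpc_id=bpc_id,
    )
    bpcs.extend(rescued)
    fusions = cl.form_putative_fusions(clusters, bpcs, config.strandedness, db)

    # ---- Step 6: refinement, features, filtering ---------------------
    mate_locations: Dict[Tuple[str, int], List[Tuple[str, int, int]]] = {}
    for (rid, mate), aln in end_hits.items():
        mate_locations.setdefault((rid, mate), []).append((aln.chrom, aln.start, aln.end))
    for (rid, mate), alns in locals_by_read.items():
        for a in alns:
            mate_locations.setdefault((rid, mate), []).append((a.chrom, a.p, a.ref_end))
    for f in fusions:
        fl.enforce_split_mate_consistency(f, mate_locations, config.I_max, paired=paired)
    fusions = [f for f in fusions if f.bpcs]
    fusions = fl.merge_bridge_only_fusions(fusions, config.I_max)
    fusions = fl.resolve_multimapped(fusions)
    fusions = [f for f in fusions if f.bpcs]

    homogeneity = fl.compute_homogeneity(fusions)
    depth = fl.DepthIndex(proper_blocks) if proper_blocks else None
    genome_len = {
        n: int(e - s)
        for n, s, e in zip(
            resources.genome_aligner.index.names,
            resources.genome_aligner.index.starts,
            resources.genome_aligner.index.ends,
        )
    }
    rid_index = {rid: i for i, rid in enumerate(read_ids)}
    bridge_seqs: Dict[Tuple[str, int], str] = {}
    if paired:
        for f in fusions:
            for b in f.bridges:
                rid = b.members[0].read_id
                i = rid_index.get(rid)
                if i is not None:
                    bridge_seqs[(rid, 1)] = seqs1[i]
                    bridge_seqs[(rid, 2)] = seqs2[i]
    ins_flank = int(insert_model.upper) + 100 if insert_model else 700
    ins_flank = min(ins_flank, 1200)

    features: Dict[int, fl.FusionFeatures] = {}
    verdicts: Dict[int, fl.Verdict] = {}
    records = []
    stranded = config.strandedness in ("forward", "reverse")
    for f in fusions:
        usf, dev, uniq, f5, f3 = fl.compute_coverage_features(f, depth)
        junction, j_off, _trunc = reconstruct_junction_sequence(
            f, resources.genome_aligner.fetch, lambda c: genome_len[c],
            flank=min(config.junction_flank, 300), db=db,
        )
        # symmetric window around the junction keeps the score of a genuine
        # chimera near 0.5 regardless of how short either transcript side is
        eff = min(j_off, len(junction) - j_off)
        homology = fl.compute_homology_score(
            junction[j_off - eff : j_off + eff],
            [resources.genome_aligner, resources.tx_aligner],
            config.scoring,
        )
        if f.n_bridge and insert_model is not None:
            junction_ins, _ins_off, _ = reconstruct_junction_sequence(
                f, resources.genome_aligner.fetch, lambda c: genome_len[c],
                flank=ins_flank, db=db,
            )
            inserts = fl.bridge_inserts_via_junction(f, junction_ins, bridge_seqs)
        else:
            inserts = []
        ivr = fl.compute_insert_validity(inserts, insert_model, f.n_bridge)
        ann5 = ann3 = None
        bio5: Tuple[str, ...] = ()
        bio3: Tuple[str, ...] = ()
        inter5 = inter3 = False
        if f.cluster_5p.breakpoint_pos is not None:
            a5 = db.annotate_position(f.cluster_5p.chrom, f.cluster_5p.breakpoint_pos, config.edge_slack)
            ann5 = a5.strands[0] if a5.strands else None
            bio5 = tuple(a5.biotypes)
            inter5 = a5.category == "intergenic"
        if f.cluster_3p.breakpoint_pos is not None:
            a3 = db.annotate_position(f.cluster_3p.chrom, f.cluster_3p.breakpoint_pos, config.edge_slack)
            ann3 = a3.strands[0] if a3.strands else None
            bio3 = tuple(a3.biotypes)
            inter3 = a3.category == "intergenic"
        conc, anti5, anti3 = fl.compute_strand_concordance(
            f, config.strandedness, ann5, ann3
        )
        feats = fl.FusionFeatures(
            homogeneity_weight=homogeneity.get(f.id, 1.0),
            unique_split_fraction=usf,
            mean_breakpoint_offset_dev=dev,
            has_unique_split=uniq,
            flank_coverage_5p=f5,
            flank_coverage_3p=f3,
            homology_score=homology,
            valid_insert_ratio=ivr,
            strand_concordance=conc,
            antisense_5p=anti5,
            antisense_3p=anti3,
            biotypes_5p=bio5,
            biotypes_3p=bio3,
            intergenic_5p=inter5,
            intergenic_3p=inter3,
        )
        verdict = fl.apply_filters(f, feats, config.thresholds, stranded=stranded)
        features[f.id] = feats
        verdicts[f.id] = verdict
        records.append(
            build_record(
                f,
                feats,
                verdict,
                fl.fusion_score(f),
                db,
                config.edge_slack,
                junction_seq=(junction if config.report_junction_seq else "."),
            )
        )

    expression = None
    if config.compute_expression:
        from .alignment import estimate_expression

        expression = estimate_expression(proper_alns, db)

    return CallResult(
        records=records,
        fusions=fusions,
        features=features,
        verdicts=verdicts,
        insert_model=insert_model,
        n_reads=len(read_ids) * (2 if paired else 1),
        n_end_to_end=n_mapped,
        n_unmapped=len(unmapped),
        n_split_bpcs=n_split_bpcs,
        n_bridge_bpcs=n_bridge,
        expression=expression,
    )


# ---------------------------------------------------------------------------
# file-level orchestration


def run_pipeline(
    config: PipelineConfig, resources: Optional[Resources] = None
) -> pd.DataFrame:
    """Execute the full pipeline from files; returns the report DataFrame.

    Writes to ``config.workdir``: ``report.tsv`` (passing fusions),
    ``features.tsv`` (all putative fusions with their feature vector - the
    re-filtering checkpoint), ``config.json`` and ``insert_model.json``.
    """
    os.makedirs(config.workdir, exist_ok=True)
    with open(os.path.join(config.workdir, "config.json"), "w") as fh:
        fh.write(config.to_json())
    try:
        if resources is None:
            db = load_annotation(config.gtf, config.genome_fasta)
            resources = Resources.build(db, config)
        read_ids, seqs1 = load_fastq(config.reads1)
        seqs2 = None
        if config.reads2:
            ids2, seqs2 = load_fastq(config.reads2)
            if len(ids2) != len(read_ids):
                raise ValueError("mate FASTQ files differ in read count")
        result = call_fusions(read_ids, seqs1, seqs2, resources, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    feat_path = os.path.join(config.workdir, "features.tsv")
    write_report(result.records, feat_path)
    passing = [r for r in result.records if r.filter_status == "PASS"]
    report_path = os.path.join(config.workdir, "report.tsv")
    write_report(passing, report_path)
    if result.insert_model is not None:
        with open(os.path.join(config.workdir, "insert_model.json"), "w") as fh:
            json.dump(dataclasses.asdict(result.insert_model), fh)
    logger.info(
        "pipeline done: %d reads, %d putative fusions, %d pass",
        result.n_reads, len(result.records), len(passing),
    )
    return read_report(report_path)


def refilter(workdir: str, thresholds: fl.FilterThresholds, stranded: bool = False) -> pd.DataFrame:
    """Re-apply filter thresholds to a saved feature checkpoint without
    re-running alignment or clustering."""
    df = read_report(os.path.join(workdir, "features.tsv"))
    status = []
    reasons_col = []
    for _, row in df.iterrows():
        reasons = []
        if row["n_split"] + row["n_bridge"] < thresholds.min_support:
            reasons.append("min_support")
        if row["homogeneity"] < thresholds.min_homogeneity:
            reasons.append("min_homogeneity")
        if row["n_split"] > 0:
            if row["unique_split_fraction"] < thresholds.min_unique_split_fraction:
                reasons.append("min_unique_split_fraction")
            if row["breakpoint_offset_dev"] > thresholds.max_breakpoint_offset_dev:
                reasons.append("max_breakpoint_offset_dev")
            if row["n_bridge"] == 0 and not row["has_unique_split"]:
                reasons.append("has_unique_split")
        if row["homology_score"] > thresholds.max_homology_score:
            reasons.append("max_homology_score")
        if row["valid_insert_ratio"] < thresholds.min_valid_insert_ratio:
            reasons.append("min_valid_insert_ratio")
        if stranded and row["strand_concordance"] < thresholds.min_strand_concordance:
            reasons.append("min_strand_concordance")
        if not thresholds.allow_intergenic and (
            row["break_5p"] == "intergenic" or row["break_3p"] == "intergenic"
        ):
            reasons.append("intergenic")
        if not thresholds.allow_discarded_biotypes:
            # biotype verdicts are positional facts carried over from the run
            reasons.extend(
                r for r in str(row["filter_reasons"]).split(";") if r.startswith("biotype")
            )
        status.append("PASS" if not reasons else "FAIL")
        reasons_col.append(";".join(reasons) or ".")
    df = df.copy()
    df["filter_status"] = status
    df["filter_reasons"] = reasons_col
    out = df[df["filter_status"] == "PASS"].reset_index(drop=True)
    out.to_csv(os.path.join(workdir, "report.tsv"), sep="\t", index=False)
    return out
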