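"""Reference genome and annotation store.

Loads a genome FASTA plus an Ensembl-dialect GTF and exposes transcript
models, transcriptome->genome coordinate projection, positional annotation
(exon edge / inside exon / inside intron / intergenic) and biotype lookup.

All internal coordinates are 0-based half-open; report writers convert to
1-based inclusive at the edge of the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import gffutils
import numpy as np
from intervaltree import IntervalTree
from pyfaidx import Fasta

Interval = Tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """One transcript: ordered, non-overlapping exons on a single strand."""

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: List[Interval]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a0, b0), (a1, _b1) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        if self.length < 1:
            raise ValueError(f"empty transcript {self.transcript_id}")

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exons_in_transcription_order(self) -> List[Interval]:
        """Exons ordered 5'->3' along the transcript (reversed for minus strand)."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns(self) -> List[Interval]:
        return [
            (b0, a1) for (_a0, b0), (a1, _b1) in zip(self.exons, self.exons[1:]) if a1 > b0
        ]


@dataclass
class RegionAnnotation:
    """Positional classification of one genomic coordinate."""

    category: str  # exon_edge | inside_exon | inside_intron | intergenic
    gene_ids: List[str] = field(default_factory=list)
    gene_names: List[str] = field(default_factory=list)
    biotypes: List[str] = field(default_factory=list)
    strands: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.category == "intergenic") != (len(self.gene_ids) == 0):
            raise ValueError("intergenic iff no genes")


class TranscriptDB:
    """Queryable store of transcript models with a per-chromosome interval index."""

    def __init__(self, transcripts: List[TranscriptModel], genome: Optional[Fasta] = None):
        self.transcripts: Dict[str, TranscriptModel] = {
            t.transcript_id: t for t in transcripts
        }
        self.genome = genome
        self._tx_index: Dict[str, IntervalTree] = {}
        self._exon_index: Dict[str, IntervalTree] = {}
        self._exon_edges: Dict[str, set] = {}
        for t in transcripts:
            self._tx_index.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t)
            edges = self._exon_edges.setdefault(t.chrom, set())
            etree = self._exon_index.setdefault(t.chrom, IntervalTree())
            for a, b in t.exons:
                etree.addi(a, b, t)
                edges.add(a)
                edges.add(b - 1)  # last base of the exon

    # -- basic queries -------------------------------------------------

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def chroms(self) -> List[str]:
        return sorted(self._tx_index)

    def genes(self) -> Dict[str, List[TranscriptModel]]:
        out: Dict[str, List[TranscriptModel]] = {}
        for t in self.transcripts.values():
            out.setdefault(t.gene_id, []).append(t)
        return out

    def transcripts_overlapping(self, chrom: str, start: int, end: int) -> List[TranscriptModel]:
        tree = self._tx_index.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def exons_overlapping(self, chrom: str, start: int, end: int) -> List[Tuple[Interval, TranscriptModel]]:
        tree = self._exon_index.get(chrom)
        if tree is None:
            return []
        return [((iv.begin, iv.end), iv.data) for iv in tree.overlap(start, end)]

    # -- sequences -----------------------------------------------------

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if self.genome is None:
            raise ValueError("no genome attached")
        return str(self.genome[chrom][start:end]).upper()

    def transcript_sequence(self, transcript_id: str) -> str:
        """Spliced transcript sequence, 5'->3' (reverse-complemented on minus strand)."""
        t = self.transcripts[transcript_id]
        seq = "".join(self.fetch(t.chrom, a, b) for a, b in t.exons)
        return revcomp(seq) if t.strand == "-" else seq

    # -- coordinate projection -----------------------------------------

    def project_to_genome(self, transcript_id: str, t_start: int, t_len: int) -> Tuple[List[Interval], str]:
        """Map a transcript-coordinate slice onto genomic exon blocks.

        Transcript coordinates run 5'->3' along the spliced transcript, so on
        minus-strand transcripts position 0 is the 3'-most genomic base of the
        last genomic exon.  Returns (blocks sorted in genomic order, strand);
        block lengths sum to ``t_len``.
        """
        t = self.transcripts[transcript_id]
        if t_start < 0 or t_len < 0 or t_start + t_len > t.length:
            raise ValueError(
                f"slice [{t_start}, {t_start + t_len}) out of range for "
                f"{transcript_id} (length {t.length})"
            )
        blocks: List[Interval] = []
        offset = 0
        for a, b in t.exons_in_transcription_order():
            elen = b - a
            lo = max(t_start, offset)
            hi = min(t_start + t_len, offset + elen)
            if lo < hi:
                if t.strand == "+":
                    blocks.append((a + (lo - offset), a + (hi - offset)))
                else:
                    # transcript coords count from the genomic right end
                    blocks.append((b - (hi - offset), b - (lo - offset)))
            offset += elen
        return sorted(blocks), t.strand

    # -- positional annotation -----------------------------------------

    def annotate_position(self, chrom: str, pos: int, edge_slack: int = 0) -> RegionAnnotation:
        """Classify a genomic position against the annotation.

        ``edge_slack`` widens what counts as an exon edge: a breakpoint within
        that many bases of an annotated exon boundary is still reported as
        ``exon_edge`` (default 0 = exact).
        """
        hits = self.exons_overlapping(chrom, pos - edge_slack, pos + edge_slack + 1)
        if hits:
            edge_hits = [
                t for (a, b), t in hits if min(abs(pos - a), abs(pos - (b - 1))) <= edge_slack
            ]
            if edge_hits:
                return RegionAnnotation("exon_edge", *_collect(edge_hits))
            inside = [t for (a, b), t in hits if a <= pos < b]
            if inside:
                return RegionAnnotation("inside_exon", *_collect(inside))
        txs = self.transcripts_overlapping(chrom, pos, pos + 1)
        if txs:
            return RegionAnnotation("inside_intron", *_collect(txs))
        return RegionAnnotation("intergenic")

    def gene_strand(self, gene_id: str) -> Optional[str]:
        for t in self.transcripts.values():
            if t.gene_id == gene_id:
                return t.strand
        return None


def _collect(transcripts) -> Tuple[List[str], List[str], List[str], List[str]]:
    gene_ids: List[str] = []
    names: List[str] = []
    biotypes: List[str] = []
    strands: List[str] = []
    for t in transcripts:
        if t.gene_id not in gene_ids:
            gene_ids.append(t.gene_id)
            names.append(t.gene_name)
            biotypes.append(t.biotype)
            strands.append(t.strand)
    order = np.argsort(gene_ids)
    return (
        [gene_ids[i] for i in order],
        [names[i] for i in order],
        [biotypes[i] for i in order],
        [strands[i] for i in order],
    )


def load_annotation(gtf_path: str, genome_path: str) -> TranscriptDB:
    """Build a :class:`TranscriptDB` from an Ensembl-dialect GTF + FASTA.

    Exon features are grouped by ``transcript_id``; exons listed out of order
    in the file are stored sorted by genomic start.  A transcript on a
    chromosome absent from the FASTA is an error naming that chromosome.
    """
    genome = Fasta(str(genome_path))
    try:
        db = gffutils.create_db(
            str(gtf_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - gffutils error text varies
        raise ValueError(f"malformed GTF {gtf_path}: {exc}") from exc

    by_tx: Dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        try:
            tx_id = feat.attributes["transcript_id"][0]
            gene_id = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ValueError(
                f"GTF exon at {feat.seqid}:{feat.start} missing {exc} attribute"
            ) from exc
        gene_name = feat.attributes.get("gene_name", [gene_id])[0]
        biotype = feat.attributes.get(
            "gene_biotype", feat.attributes.get("transcript_biotype", ["protein_coding"])
        )[0]
        rec = by_tx.setdefault(
            tx_id,
            {
                "gene_id": gene_id,
                "gene_name": gene_name,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "biotype": biotype,
                "exons": [],
            },
        )
        rec["exons"].append((feat.start - 1, feat.end))  # GTF is 1-based inclusive

    transcripts = []
    for tx_id, rec in by_tx.items():
        if rec["chrom"] not in genome:
            raise ValueError(
                f"chromosome {rec['chrom']!r} of transcript {tx_id} not in FASTA"
            )
        transcripts.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=rec["gene_id"],
                gene_name=rec["gene_name"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                biotype=rec["biotype"],
            )
        )
    return TranscriptDB(transcripts, genome=genome)


def is_discarded_biotype(biotype: str) -> bool:
    """Pseudogene / processed-transcript partners are dropped by default."""
    b = biotype.lower()
    return "pseudogene" in b or "processed_transcript" in b
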