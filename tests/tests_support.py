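"""Shared builders for tests."""

from chimerascope.alignment import EndToEndAlignment
from chimerascope.clusters import bridge_bpc, cluster_bpcs, form_putative_fusions, split_bpc
from chimerascope.splits import LocalAlignment, SplitCandidate


def make_simple_fusion(idx: int, n_split: int = 2, n_bridge: int = 0):
    """A self-consistent putative fusion at a locus offset by ``idx``."""
    base1 = 1000 + 50_000 * idx
    base2 = 5_000_000 + 50_000 * idx
    bpcs = []
    bid = 0
    for _ in range(n_split):
        bid += 1
        rid = f"f{idx}_r{bid}"
        bpcs.append(
            split_bpc(
                bid,
                SplitCandidate(
                    first=LocalAlignment(rid, 1, "chr1", base1, 0, 50, "+", 100, 0, 100),
                    second=LocalAlignment(rid, 1, "chr2", base2, 50, 50, "+", 100, 0, 100),
                    gap=0,
                ),
            )
        )
        bpcs[-1].mate_consistent = True
    for _ in range(n_bridge):
        bid += 1
        rid = f"f{idx}_r{bid}"
        bpcs.append(
            bridge_bpc(
                bid,
                EndToEndAlignment(rid, 1, "chr1", ((base1 - 60, base1 + 15),), "+", "genome", read_length=75),
                EndToEndAlignment(rid, 2, "chr2", ((base2 + 10, base2 + 85),), "-", "genome", read_length=75),
            )
        )
    clusters = cluster_bpcs(bpcs)
    fusions = form_putative_fusions(clusters, bpcs, "none", None)
    assert len(fusions) == 1
    fusions[0].id = idx + 1
    return fusions[0]
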