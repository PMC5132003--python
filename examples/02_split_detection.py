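"""SPLIT-read detection on a single chimeric read.

A read straddling a fusion junction aligns locally on both sides; the two
local alignments satisfy the SPLIT conditions and imply an exact
breakpoint pair.
"""

import numpy as np

from chimerascope.alignment import InternalAligner
from chimerascope.splits import form_split_candidates, implied_breakpoint

rng = np.random.default_rng(0)
genome = {
    "chr1": "".join("ACGT"[b] for b in rng.integers(0, 4, 50_000)),
    "chr2": "".join("ACGT"[b] for b in rng.integers(0, 4, 50_000)),
}
aligner = InternalAligner(genome)

# 40 bases ending at chr1:9999 fused to 35 bases starting at chr2:20000
read = genome["chr1"][9960:10000] + genome["chr2"][20000:20035]
alignments = aligner.local_alignments(read, read_id="example")
print(f"local alignments of the 75 bp read: {len(alignments)}")
for a in alignments:
    print(f"  {a.chrom}:{a.p}-{a.p + a.length} read[{a.q}:{a.q + a.length}] "
          f"strand={a.strand} score={a.score}")

candidates = form_split_candidates(alignments)
donor, acceptor = implied_breakpoint(candidates[0])
print(f"SPLIT implies junction {donor.chrom}:{donor.pos} ({donor.role}) | "
      f"{acceptor.chrom}:{acceptor.pos} ({acceptor.role})")
# expected: chr1:9999 upstream | chr2:20000 downstream - the exact planted junction
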