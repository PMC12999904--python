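"""Collinear-block chaining and duplication-mode classification.

Builds a 12-anchor diagonal (a planted collinear block) plus scattered
noise, recovers the block, then classifies a tandem pair and a singleton.
"""

from asterfam import chain_anchors, classify_duplications
from asterfam.models import AnchorPair, GeneModel

anchors = [
    AnchorPair(f"a{i}", f"b{i}", "spA_chr1", "spB_chr1", 10 + i, 40 + i)
    for i in range(12)
]
anchors += [
    AnchorPair("nx1", "ny1", "spA_chr1", "spB_chr1", 100, 300),
    AnchorPair("nx2", "ny2", "spA_chr1", "spB_chr1", 200, 120),
]
blocks = chain_anchors(anchors, min_block_size=10)
for blk in blocks:
    print(f"{blk.block_id}: {blk.score} anchors, orientation {blk.orientation}")

genes = []
for gid, rank in (("g1", 5), ("g2", 6), ("g3", 50)):
    g = GeneModel(gene_id=gid, species="spA", chromosome="spA_chr1",
                  start=rank * 1000, end=rank * 1000 + 500, strand="+")
    g.rank = rank
    genes.append(g)
calls = classify_duplications(genes, [("g1", "g2")], [], [])
for c in calls:
    print(f"{c.gene_id}: {c.mode}")
# The adjacent homologs g1/g2 are tandem duplicates (TD); g3 has no
# homolog and is a singleton. The 12-anchor diagonal is the only chain
# long enough to be called a collinear block.
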