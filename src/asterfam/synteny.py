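"""Collinear-block chaining and duplication-mode classification.

Blocks are longest strictly monotone chains of anchor gene pairs in rank
space (both orientations), with a bounded rank gap between consecutive
anchors, found by longest-chain dynamic programming; chains shorter than
the minimum block size are discarded, so a collinear block always has at
least ``min_block_size`` anchors.

Duplication modes follow the DupGen priority scheme: WGD (anchored in an
intra-species block) > tandem (adjacent homolog on the same chromosome) >
proximal (nearby homolog) > transposed (the copy of a homolog pair lacking
outgroup synteny while its partner retains it) > dispersed (any other
homolog-bearing gene); genes without homologs are singletons.
"""

from __future__ import annotations

from asterfam._util import round_half_up
from asterfam.models import AnchorPair, DuplicationCall, GeneModel, SyntenyBlock


def _best_chain(
    anchors: list[AnchorPair], inverted: bool, max_rank_gap: int
) -> list[AnchorPair]:
    """Longest strict chain; rank_b decreasing when ``inverted``."""
    sgn = -1 if inverted else 1
    order = sorted(anchors, key=lambda a: (a.rank_a, sgn * a.rank_b))
    n = len(order)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            a, b = order[j], order[i]
            da = b.rank_a - a.rank_a
            db = (b.rank_b - a.rank_b) * sgn
            if 0 < da <= max_rank_gap and 0 < db <= max_rank_gap:
                if best_len[j] + 1 > best_len[i]:
                    best_len[i] = best_len[j] + 1
                    prev[i] = j
    if not order:
        return []
    end = max(range(n), key=lambda i: (best_len[i], -order[i].rank_a))
    chain = []
    while end != -1:
        chain.append(order[end])
        end = prev[end]
    return chain[::-1]


def chain_anchors(
    anchors: list[AnchorPair],
    min_block_size: int = 10,
    max_rank_gap: int = 25,
) -> list[SyntenyBlock]:
    """Greedy extraction of monotone anchor chains per chromosome pair.

    Each anchor joins at most one block; the longest remaining chain is
    taken first (ties by leftmost start, same orientation before
    inverted), until no chain reaches ``min_block_size``.
    """
    by_pair: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        by_pair.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[SyntenyBlock] = []
    counter = 0
    for (ca, cb) in sorted(by_pair):
        pool = by_pair[(ca, cb)]
        while True:
            candidates = []
            for flag, name in ((False, "same"), (True, "inverted")):
                chain = _best_chain(pool, flag, max_rank_gap)
                if len(chain) >= min_block_size:
                    candidates.append((-len(chain), chain[0].rank_a, flag, name, chain))
            if not candidates:
                break
            candidates.sort(key=lambda c: c[:3])
            _, _, _, orientation, chain = candidates[0]
            counter += 1
            sp_a = _species_of_chrom(ca)
            sp_b = _species_of_chrom(cb)
            blocks.append(
                SyntenyBlock(
                    block_id=f"block{counter}",
                    species_a=sp_a,
                    species_b=sp_b,
                    chrom_a=ca,
                    chrom_b=cb,
                    anchors=tuple(chain),
                    orientation=orientation,
                )
            )
            used = set(map(id, chain))
            pool = [a for a in pool if id(a) not in used]
    return blocks


def _species_of_chrom(chrom: str) -> str:
    """Species prefix from a '<species>_<chrom>' identifier, else the id."""
    return chrom.rsplit("_", 1)[0] if "_" in chrom else chrom


def classify_duplications(
    family_genes: list[GeneModel],
    homolog_pairs: list[tuple[str, str]],
    intra_blocks: list[SyntenyBlock],
    outgroup_blocks: list[SyntenyBlock],
    proximal_max_gap: int = 10,
) -> list[DuplicationCall]:
    """One duplication mode per gene under the WGD>TD>PD>TRD>DSD priority."""
    info = {g.gene_id: g for g in family_genes}
    partners: dict[str, list[str]] = {g.gene_id: [] for g in family_genes}
    for a, b in homolog_pairs:
        for x in (a, b):
            if x not in info:
                raise KeyError(f"homolog gene {x!r} absent from the annotation")
        if a != b:
            partners[a].append(b)
            partners[b].append(a)

    wgd_evidence: dict[str, str] = {}
    for blk in intra_blocks:
        for g in blk.gene_ids():
            if g in info:
                wgd_evidence.setdefault(g, blk.block_id)
    outgroup_syntenic: set[str] = set()
    for blk in outgroup_blocks:
        outgroup_syntenic.update(g for g in blk.gene_ids() if g in info)

    calls = []
    for g in family_genes:
        gid = g.gene_id
        mode, evidence = "singleton", ""
        if gid in wgd_evidence:
            mode, evidence = "WGD", wgd_evidence[gid]
        else:
            hom = sorted(set(partners[gid]))
            same_chrom = [
                h for h in hom if info[h].chromosome == g.chromosome
            ]
            tandem = [h for h in same_chrom if abs(info[h].rank - g.rank) == 1]
            proximal = [
                h
                for h in same_chrom
                if 2 <= abs(info[h].rank - g.rank) <= proximal_max_gap
            ]
            transposed_from = [
                h for h in hom if gid not in outgroup_syntenic and h in outgroup_syntenic
            ]
            if tandem:
                mode, evidence = "TD", tandem[0]
            elif proximal:
                mode, evidence = "PD", proximal[0]
            elif transposed_from:
                mode, evidence = "TRD", transposed_from[0]
            elif hom:
                mode, evidence = "DSD", hom[0]
        calls.append(DuplicationCall(gene_id=gid, mode=mode, evidence=evidence))
    return calls


def synteny_conservation_table(
    cross_species_blocks: list[SyntenyBlock],
    category_of: dict[str, str],
) -> list[dict]:
    """Conservation-class composition of syntenic genes per species pair.

    Each anchored gene (deduplicated within a species pair) contributes its
    class; percentages are half-up to 2 decimals. A final ``all`` row pools
    every species pair.
    """
    per_pair: dict[tuple[str, str], set[str]] = {}
    for blk in cross_species_blocks:
        key = tuple(sorted((blk.species_a, blk.species_b)))
        per_pair.setdefault(key, set()).update(blk.gene_ids())

    def _row(name_a: str, name_b: str, genes: set[str]) -> dict:
        counts = {"conserved": 0, "variable": 0, "rare": 0}
        for g in genes:
            if g not in category_of:
                raise KeyError(f"anchored gene {g!r} has no conservation class")
            counts[category_of[g]] += 1
        total = sum(counts.values())
        row = {"species_a": name_a, "species_b": name_b, "n_genes": total}
        for cat, c in counts.items():
            row[f"n_{cat}"] = c
            row[f"pct_{cat}"] = round_half_up(100.0 * c / total, 2) if total else 0.0
        return row

    rows = [_row(a, b, genes) for (a, b), genes in sorted(per_pair.items())]
    if rows:
        pooled: set[str] = set()
        for genes in per_pair.values():
            pooled |= genes
        rows.append(_row("all", "all", pooled))
    return rows
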