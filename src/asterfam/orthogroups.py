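"""Orthologous gene groups (OGGs) and their conservation classes.

Orthogroups are built from a similarity table by reciprocal best hits
(RBH): for each gene and each other species, keep its top-scoring partner;
an edge survives only if it is mutual, and connected components of the
surviving graph are the OGGs. Each OGG is classed by its species presence:
*conserved* (all N species), *variable* (exactly N-1, tolerating a single
loss), *rare* (1 to N-2 species).
"""

from __future__ import annotations

import warnings

from asterfam._util import round_half_up
from asterfam.models import GeneModel, OrthoGroup


def classify_ogg(presence: dict[str, int], n_species: int) -> str:
    """Conservation class from a per-species copy-number vector."""
    if len(presence) != n_species:
        raise ValueError("presence vector length must equal n_species")
    k = sum(1 for v in presence.values() if v > 0)
    if k == n_species:
        return "conserved"
    if k == n_species - 1:
        return "variable"
    return "rare"


def build_oggs(
    homology: list[tuple[str, str, float]], genes: list[GeneModel]
) -> list[OrthoGroup]:
    """RBH graph construction followed by connected components.

    Score ties resolve to the lexicographically smallest partner id, so the
    grouping is deterministic. Genes without any mutual best hit become
    singleton OGGs.
    """
    species_of = {g.gene_id: g.species for g in genes}
    all_species = sorted({g.species for g in genes})
    if len(all_species) < 2:
        raise ValueError("roster must span at least two species")

    best: dict[tuple[str, str], tuple[float, str]] = {}  # (gene, other_sp) -> (score, partner)
    for a, b, score in homology:
        if a == b:
            warnings.warn(f"ignoring self-pair {a}")
            continue
        if a not in species_of or b not in species_of:
            continue
        sa, sb = species_of[a], species_of[b]
        if sa == sb:
            continue
        for g, other_sp, partner in ((a, sb, b), (b, sa, a)):
            key = (g, other_sp)
            cur = best.get(key)
            # higher score wins; equal scores fall back to the smaller id
            if cur is None or (-score, partner) < (-cur[0], cur[1]):
                best[key] = (score, partner)

    parent = {g.gene_id: g.gene_id for g in genes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (g, _sp), (_score, partner) in best.items():
        back = best.get((partner, species_of[g]))
        if back is not None and back[1] == g:
            ra, rb = find(g), find(partner)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    components: dict[str, list[str]] = {}
    for g in genes:
        components.setdefault(find(g.gene_id), []).append(g.gene_id)

    oggs = []
    width = len(str(len(components)))
    for i, root in enumerate(sorted(components, key=lambda r: min(components[r])), 1):
        members = tuple(sorted(components[root]))
        presence = {sp: 0 for sp in all_species}
        for m in members:
            presence[species_of[m]] += 1
        oggs.append(
            OrthoGroup(
                ogg_id=f"OGG{i:0{width}d}",
                members=members,
                presence=presence,
                category=classify_ogg(presence, len(all_species)),
            )
        )
    return oggs


def category_proportions(genes_per_category: dict[str, int], total: int) -> dict[str, float]:
    """Percentage of the roster in each class, half-up to 2 decimals."""
    if sum(genes_per_category.values()) > total:
        raise ValueError("category counts exceed the total")
    return {
        cat: round_half_up(100.0 * count / total, 2)
        for cat, count in genes_per_category.items()
    }


def presence_matrix(oggs: list[OrthoGroup]) -> tuple[list[str], list[str], list[list[int]]]:
    """(ogg ids, species, copy-number rows) for heatmap-style export."""
    species = sorted({sp for o in oggs for sp in o.presence})
    rows = [[o.presence.get(sp, 0) for sp in species] for o in oggs]
    return [o.ogg_id for o in oggs], species, rows
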