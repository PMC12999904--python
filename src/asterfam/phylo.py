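"""Alignment trimming, p-distances, neighbor joining and label propagation.

Subfamily/cluster assignment anchors unknown family members to reference
proteins of known subfamily (RAF, MEKK or ZIK for plant MAPKKKs): a
distance tree is built over references plus candidates and each candidate
inherits the labels of its nearest reference leaf by patristic distance.
Neighbor joining stands in for likelihood tree search; for label
propagation only local neighborhoods matter, and NJ is exact on additive
distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

GAP_CHARS = {"-", "."}

_CLUSTER_RANGES = {"MEKK": range(1, 6), "ZIK": range(6, 8), "RAF": range(8, 15)}


@dataclass(frozen=True)
class TrimConfig:
    """Column filter: keep columns whose non-gap fraction >= gap_threshold."""

    gap_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.gap_threshold <= 1:
            raise ValueError("gap_threshold must be in (0, 1]")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")


@dataclass(frozen=True)
class ReferencePanel:
    """Reference proteins with subfamily and optional cluster labels.

    Clusters are constrained to their subfamily's range: 1-5 under MEKK,
    6-7 under ZIK, 8-14 under RAF.
    """

    labels: dict[str, tuple[str, int | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ref, (subfam, cluster) in self.labels.items():
            if subfam not in _CLUSTER_RANGES:
                raise ValueError(f"{ref}: unknown subfamily {subfam!r}")
            if cluster is not None and cluster not in _CLUSTER_RANGES[subfam]:
                raise ValueError(f"{ref}: cluster {cluster} invalid for {subfam}")

    def subfamilies(self) -> set[str]:
        return {s for s, _ in self.labels.values()}


def trim_alignment(
    alignment: dict[str, str], config: TrimConfig = TrimConfig()
) -> dict[str, str]:
    """Drop poorly aligned columns; inclusive at the threshold boundary."""
    rows = list(alignment.values())
    if not rows:
        return {}
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("ragged alignment: rows differ in length")
    n = len(rows)
    keep = [
        j
        for j in range(length)
        if sum(r[j] not in GAP_CHARS for r in rows) / n >= config.gap_threshold
    ]
    return {name: "".join(seq[j] for j in keep) for name, seq in alignment.items()}


def pairwise_distance(alignment: dict[str, str]) -> DistanceMatrix:
    """p-distance over columns where neither sequence has a gap.

    A pair with no comparable columns gets distance 1 (with a warning), the
    most conservative choice for downstream clustering.
    """
    labels = list(alignment)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    seqs = [alignment[l] for l in labels]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mismatch = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in GAP_CHARS or b in GAP_CHARS:
                    continue
                comparable += 1
                mismatch += a != b
            if comparable == 0:
                warnings.warn(
                    f"no comparable columns between {labels[i]} and {labels[j]};"
                    " distance set to 1"
                )
                dist = 1.0
            else:
                dist = mismatch / comparable
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining, deterministic and clamp-corrected.

    Ties in the Q matrix resolve to the smallest (label_i, label_j) pair;
    a negative branch length is clamped to zero with the deficit moved to
    its sister so the pair's summed length is preserved.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    # sort key for deterministic tie-breaks: the smallest leaf name under a node
    mins = list(dm.labels)
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((mins[i], mins[j])))
                if best is None or (q, pair_key) < (best[0], best[1]):
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])
        # grow matrix with the new node's distances
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = (d[i, k] + d[j, k] - d[i, j]) / 2
        nodes.append(parent)
        mins.append(min(mins[i], mins[j]))
        active = [k for k in active if k not in (i, j)] + [new]

    i, j = active
    a, b = nodes[i], nodes[j]
    # place the root on the final edge; path lengths are unaffected
    a.length = d[i, j]
    b.length = 0.0
    return TreeNode(children=[a, b])


def assign_labels(
    tree: TreeNode, panel: ReferencePanel
) -> dict[str, tuple[str, int | None]]:
    """Propagate subfamily/cluster labels from nearest reference leaves.

    Every subfamily must have at least one reference in the tree. Ties in
    patristic distance resolve to the smallest reference id.
    """
    tip_names = [t.name for t in tree.tips()]
    refs_in_tree = [name for name in tip_names if name in panel.labels]
    present = {panel.labels[r][0] for r in refs_in_tree}
    missing = set(_CLUSTER_RANGES) - present
    if missing:
        raise ValueError(f"reference panel missing subfamilies in tree: {sorted(missing)}")
    tipdm = tree.tip_tip_distances()
    out: dict[str, tuple[str, int | None]] = {}
    for name in tip_names:
        if name in panel.labels:
            out[name] = panel.labels[name]
            continue
        best_ref = min(refs_in_tree, key=lambda r: (tipdm[name, r], r))
        out[name] = panel.labels[best_ref]
    return out
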