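"""Expression-level analyses: FPKM, fold-change screening and qPCR.

The RNA-seq side starts from count or FPKM tables (read mapping and
transcript assembly are upstream of this package). A gene is called
stress-responsive when |log2 fold change| exceeds 1 between treated and
control means, computed with a pseudocount. The qPCR side implements the
2^-ddCt method against a reference gene with the 0 h sample as control,
plus ANOVA/Tukey compact letter displays for timepoint comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DECall:
    gene_id: str
    log2fc: float
    responsive: bool


@dataclass(frozen=True)
class QpcrRecord:
    gene_id: str
    condition: str
    timepoint: float
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for ct in (self.ct_target, self.ct_reference):
            if not 0 < ct < 45:
                raise ValueError(f"Ct {ct} outside the plausible (0, 45) range")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class FoldChangeResult:
    gene_id: str
    condition: str
    timepoint: float
    mean_fold: float
    sd_fold: float
    letter: str = ""


def fpkm(count: int, transcript_length_bp: int, total_mapped: int) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if count < 0 or transcript_length_bp <= 0 or total_mapped <= 0:
        raise ValueError("count must be >= 0; length and library size > 0")
    return count * 1e9 / (transcript_length_bp * total_mapped)


def de_screen(
    treated: float, control: float, gene_id: str = "", pseudocount: float = 1.0
) -> DECall:
    """log2 fold change with a pseudocount; responsive iff strictly > 1."""
    if treated < 0 or control < 0:
        raise ValueError("expression values must be non-negative")
    log2fc = math.log2((treated + pseudocount) / (control + pseudocount))
    return DECall(gene_id=gene_id, log2fc=log2fc, responsive=abs(log2fc) > 1)


def ddct(
    records: list[QpcrRecord], control_records: list[QpcrRecord]
) -> FoldChangeResult:
    """Relative expression by 2^-ddCt, per-replicate, versus the 0 h control.

    ddCt for each replicate is its dCt minus the mean control dCt; the
    reported mean and sd (sample sd, ddof=1) are taken over replicate
    folds.
    """
    if not records or not control_records:
        raise ValueError("need >=1 replicate in both treatment and control")
    first = records[0]
    control_mean_dct = float(np.mean([r.dct for r in control_records]))
    folds = np.array([2.0 ** -(r.dct - control_mean_dct) for r in records])
    sd = float(folds.std(ddof=1)) if len(folds) > 1 else 0.0
    return FoldChangeResult(
        gene_id=first.gene_id,
        condition=first.condition,
        timepoint=first.timepoint,
        mean_fold=float(folds.mean()),
        sd_fold=sd,
    )


def letter_groups(
    folds_by_timepoint: dict[float, list[float]], alpha: float = 0.05
) -> dict[float, str]:
    """Compact letter display from one-way ANOVA + Tukey HSD on log2 folds.

    Groups that cannot be distinguished at ``alpha`` share a letter;
    letters are assigned from the highest group mean downward using the
    insert-and-absorb construction, so a group overlapping two separated
    groups gets both letters (e.g. "ab").
    """
    keys = sorted(folds_by_timepoint)
    if len(keys) < 2 or any(len(folds_by_timepoint[k]) < 2 for k in keys):
        raise ValueError("need >=2 groups with >=2 replicates each")
    logs = [np.log2(np.asarray(folds_by_timepoint[k], dtype=float)) for k in keys]
    means = [float(x.mean()) for x in logs]
    _, p_anova = stats.f_oneway(*logs)

    n = len(keys)
    significant: set[tuple[int, int]] = set()
    if not math.isnan(p_anova) and p_anova < alpha:
        tukey = stats.tukey_hsd(*logs)
        for i in range(n):
            for j in range(i + 1, n):
                if tukey.pvalue[i, j] < alpha:
                    significant.add((i, j))

    # insert-and-absorb: split the all-groups set on each significant pair
    sets: list[set[int]] = [set(range(n))]
    for i, j in sorted(significant):
        new_sets: list[set[int]] = []
        for s in sets:
            if i in s and j in s:
                new_sets.extend((s - {i}, s - {j}))
            else:
                new_sets.append(s)
        sets = [s for s in new_sets if s and not any(s < t for t in new_sets)]
        # drop duplicates, keep deterministic order
        uniq: list[set[int]] = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq

    order = sorted(range(n), key=lambda i: -means[i])
    sets.sort(key=lambda s: min(order.index(i) for i in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters_of: dict[int, str] = {i: "" for i in range(n)}
    for letter, s in zip(alphabet, sets):
        for i in sorted(s, key=lambda i: -means[i]):
            letters_of[i] += letter
    return {keys[i]: "".join(sorted(letters_of[i])) for i in range(n)}


def row_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across samples (population sd); constant rows -> 0."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to row-scale")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    out = np.zeros_like(values)
    nz = sd[:, 0] > 0
    out[nz] = (values[nz] - mean[nz]) / sd[nz]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
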