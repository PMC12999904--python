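"""Gene-structure metrics and nonparametric group comparison.

Metrics are computed on the retained (longest) transcript: total gene
length, CDS segment count, intron count and summed intron length, and the
protein length implied by the CDS. Group differences are assessed with the
two-sided Wilcoxon rank-sum (Mann–Whitney) test, exact for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from asterfam.models import GeneModel

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class StructureRecord:
    gene_id: str
    gene_length: int
    cds_count: int
    intron_count: int
    total_intron_length: int
    aa_length: int
    subfamily: str = ""
    cluster: str = ""
    category: str = ""


def structure_metrics(gene: GeneModel, cds_seq: str | None = None) -> StructureRecord:
    """Interval arithmetic on the single retained transcript.

    Introns are the gaps between consecutive exons; a terminal stop codon
    (detected from ``cds_seq`` when given) is excluded from the amino-acid
    length.
    """
    if len(gene.transcripts) != 1:
        raise ValueError(
            f"{gene.gene_id}: expected exactly one retained transcript, "
            f"got {len(gene.transcripts)}"
        )
    t = gene.transcripts[0]
    exons = t.exons
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 <= e1:
            raise ValueError(f"{gene.gene_id}: overlapping exons {s1}-{e1}, {s2}-{e2}")
    intron_count = len(exons) - 1
    tx_span = exons[-1][1] - exons[0][0] + 1
    total_intron = tx_span - sum(e - s + 1 for s, e in exons)
    cds_len = t.cds_length()
    aa_length = cds_len // 3
    if cds_seq is not None and len(cds_seq) % 3 == 0 and cds_seq[-3:] in _STOPS:
        aa_length -= 1
    return StructureRecord(
        gene_id=gene.gene_id,
        gene_length=gene.end - gene.start + 1,
        cds_count=len(t.cds),
        intron_count=intron_count,
        total_intron_length=total_intron,
        aa_length=aa_length,
    )


def group_compare(values_a: list[float], values_b: list[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two unpaired samples.

    Exact enumeration when both groups have n <= 8 (and no ties force the
    approximation), normal approximation with tie correction otherwise.
    Returns (U statistic, p value).
    """
    if not values_a or not values_b:
        raise ValueError("both groups must be non-empty")
    method = "exact" if len(values_a) <= 8 and len(values_b) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(values_a, values_b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
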