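"""Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction.

For each codon the synonymous site count is the fraction of valid one-step
nucleotide changes that preserve the amino acid; changes creating a stop
codon are excluded and the fraction is renormalised over the remaining
changes. Sites are averaged over the two sequences. Codon pairs differing
at several positions are counted by averaging the synonymous/nonsynonymous
step classification over all orderings of single steps, discarding
pathways that pass through a stop codon. The proportions ps = Sd/S and
pn = Nd/N are corrected for multiple hits with the Jukes–Cantor formula
d = -(3/4)·ln(1 - (4/3)p), giving Ks and Ka; omega = Ka/Ks is undefined
when Ks = 0 or a proportion reaches 3/4.
"""

from __future__ import annotations

import math
import warnings
from functools import lru_cache
from itertools import permutations
from statistics import mean

from Bio.Data.CodonTable import standard_dna_table

from asterfam.models import KaKsPair

_BASES = "ACGT"
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)


def translate(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return "".join(CODON_TABLE.get(cds[i : i + 3], "*") for i in range(0, len(cds), 3))


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Synonymous site count of one codon (0..3), stop paths renormalised."""
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = CODON_TABLE[codon]
    total = 0.0
    for pos in range(3):
        valid = syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            syn += CODON_TABLE[alt] == aa
        if valid:
            total += syn / valid
    return total


def _count_path_steps(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) contribution of one codon pair, pathway-averaged."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    syn_counts: list[int] = []
    non_counts: list[int] = []
    for order in permutations(diffs):
        cur = codon_a
        syn = non = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if not blocked:
            syn_counts.append(syn)
            non_counts.append(non)
    if not syn_counts:
        # every pathway crosses a stop; count all steps as nonsynonymous
        return 0.0, float(len(diffs))
    return mean(syn_counts), mean(non_counts)


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def backtranslate(
    protein_alignment: tuple[str, str], cds_a: str, cds_b: str
) -> tuple[str, str]:
    """Thread each CDS through its gapped protein row, codon by codon.

    Every aligned residue must translate from its source codon; mismatches
    raise with the offending alignment column.
    """
    rows = []
    for row, cds in zip(protein_alignment, (cds_a, cds_b)):
        if len(cds) % 3:
            raise ValueError("CDS length not divisible by 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        # drop a trailing stop codon so the CDS matches the protein row
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        out = []
        k = 0
        for col, aa in enumerate(row):
            if aa == "-":
                out.append("---")
                continue
            if k >= len(codons):
                raise ValueError(f"CDS shorter than protein row at column {col + 1}")
            codon = codons[k]
            if CODON_TABLE.get(codon, "X") != aa:
                raise ValueError(
                    f"translation mismatch at alignment column {col + 1}: "
                    f"codon {codon} does not encode {aa}"
                )
            out.append(codon)
            k += 1
        if k != len(codons):
            raise ValueError("CDS longer than the aligned protein row")
        rows.append("".join(out))
    return rows[0], rows[1]


def ng86(aln: tuple[str, str], gene_a: str = "a", gene_b: str = "b") -> KaKsPair:
    """NG86 site/difference counts and JC-corrected rates for one pair."""
    row_a, row_b = aln
    if len(row_a) != len(row_b) or len(row_a) % 3:
        raise ValueError("codon alignment rows must have equal length divisible by 3")
    S = N = Sd = Nd = 0.0
    compared = 0
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i : i + 3], row_b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon in compared column {i // 3 + 1}")
        compared += 1
        sa, sb = synonymous_sites(ca), synonymous_sites(cb)
        S += (sa + sb) / 2
        N += 3 - (sa + sb) / 2
        sd, nd = _count_path_steps(ca, cb)
        Sd += sd
        Nd += nd
    if compared == 0:
        raise ValueError("no gap-free codon columns to compare")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(ps)
    Ka = jukes_cantor(pn)
    omega = None
    if Ks is not None and Ka is not None and Ks > 0:
        omega = Ka / Ks
    return KaKsPair(
        gene_a=gene_a,
        gene_b=gene_b,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        ps=ps,
        pn=pn,
        Ks=Ks,
        Ka=Ka,
        omega=omega,
    )


def align_proteins(a: str, b: str) -> tuple[str, str]:
    """Global protein alignment (BLOSUM62, gap open -10 / extend -1).

    Used when precomputed alignments are not supplied; the first alignment
    in Biopython's deterministic ordering is taken.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def aggregate(
    pairs: list[KaKsPair],
    ogg_of: dict[str, str],
    cluster_of: dict[str, str] | None = None,
) -> tuple[list[dict], list[dict]]:
    """Two-level arithmetic means: pairs -> OGG, OGG means -> cluster.

    OGG means run over pairs with a defined omega only; an OGG whose
    omegas are all undefined is omitted with a warning. Cluster means are
    unweighted over their constituent OGG means.
    """
    by_ogg: dict[str, list[KaKsPair]] = {}
    for p in pairs:
        oa, ob = ogg_of.get(p.gene_a), ogg_of.get(p.gene_b)
        if oa is None or ob is None or oa != ob:
            raise ValueError(f"pair {p.gene_a}/{p.gene_b} does not map to one OGG")
        by_ogg.setdefault(oa, []).append(p)

    ogg_rows = []
    for ogg_id in sorted(by_ogg):
        defined = [p for p in by_ogg[ogg_id] if p.omega is not None]
        if not defined:
            warnings.warn(f"OGG {ogg_id}: no defined Ka/Ks values; omitted")
            continue
        ogg_rows.append(
            {
                "ogg_id": ogg_id,
                "mean_ka": mean(p.Ka for p in defined),
                "mean_ks": mean(p.Ks for p in defined),
                "mean_omega": mean(p.omega for p in defined),
                "n_pairs": len(defined),
            }
        )

    cluster_rows = []
    if cluster_of:
        by_cluster: dict[str, list[dict]] = {}
        for row in ogg_rows:
            cl = cluster_of.get(row["ogg_id"])
            if cl is not None:
                by_cluster.setdefault(cl, []).append(row)
        for cl in sorted(by_cluster):
            rows = by_cluster[cl]
            cluster_rows.append(
                {
                    "cluster": cl,
                    "mean_ka": mean(r["mean_ka"] for r in rows),
                    "mean_ks": mean(r["mean_ks"] for r in rows),
                    "mean_omega": mean(r["mean_omega"] for r in rows),
                    "n_oggs": len(rows),
                }
            )
    return ogg_rows, cluster_rows
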