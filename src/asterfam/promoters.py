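"""Promoter extraction, IUPAC cis-element scanning and frequency matrices.

Promoters are the 2 kb immediately upstream of the translation start
(first CDS base), strand-aware and truncated at chromosome edges. The
element library is a table of named IUPAC consensi, each tagged with one
of four functional classes (stress, light, hormone, development); scanning
reports every match on both strands, with minus-strand hits located at the
plus-strand start of their window and palindromic double-matches collapsed
to a single hit.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from asterfam._util import round_half_up
from asterfam.models import ElementHit, GeneModel, PromoterSeq

FUNCTIONAL_CLASSES = ("stress", "light", "hormone", "development")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    name: str
    consensus: str
    functional_class: str

    def __post_init__(self) -> None:
        if not self.consensus or any(c not in IUPAC for c in self.consensus):
            raise ValueError(f"{self.name}: consensus must be non-empty IUPAC")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"{self.name}: unknown class {self.functional_class!r}")


@dataclass
class MotifLibrary:
    motifs: list[Motif]

    def __post_init__(self) -> None:
        names = [m.name for m in self.motifs]
        if len(names) != len(set(names)):
            raise ValueError("element names must be unique")

    def __iter__(self):
        return iter(self.motifs)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotifLibrary":
        with open(path) as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        return cls([Motif(r["element"], r["consensus"].upper(), r["functional_class"]) for r in rows])


def default_motif_library() -> MotifLibrary:
    """The packaged library: high-frequency plant promoter elements."""
    with resources.as_file(resources.files("asterfam") / "data" / "motifs.tsv") as p:
        return MotifLibrary.from_tsv(p)


def extract_promoter(
    gene: GeneModel, genome: dict[str, str], window: int = 2000
) -> PromoterSeq:
    """The ``window`` bases 5' of the translation start, strand-aware.

    Plus strand: [cds_start - window, cds_start - 1]; minus strand: the
    reverse complement of [cds_end + 1, cds_end + window]. Truncation at a
    chromosome edge sets ``truncated``.
    """
    if len(gene.transcripts) != 1:
        raise ValueError(f"{gene.gene_id}: expected one retained transcript")
    cds = gene.transcripts[0].cds
    if not cds:
        raise ValueError(f"{gene.gene_id}: no CDS on the retained transcript")
    chrom = genome[gene.chromosome]
    if gene.strand == "+":
        cds_start = min(s for s, _ in cds)
        lo = max(1, cds_start - window)
        hi = cds_start - 1
        seq = chrom[lo - 1 : hi] if hi >= lo else ""
        truncated = cds_start - window < 1
    else:
        cds_end = max(e for _, e in cds)
        lo = cds_end + 1
        hi = min(len(chrom), cds_end + window)
        seq = revcomp(chrom[lo - 1 : hi]) if hi >= lo else ""
        truncated = cds_end + window > len(chrom)
    return PromoterSeq(gene_id=gene.gene_id, sequence=seq.upper(), truncated=truncated)


@lru_cache(maxsize=None)
def _iupac_regex(consensus: str) -> re.Pattern:
    """Overlap-tolerant regex for one consensus; promoter N never matches
    because character classes enumerate concrete bases only."""
    body = "".join(
        IUPAC[c] if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in consensus
    )
    return re.compile(f"(?=({body}))")


def match_positions(seq: str, consensus: str) -> set[int]:
    """0-based start offsets of every (overlapping) match."""
    return {m.start() for m in _iupac_regex(consensus).finditer(seq)}


def scan(promoter: PromoterSeq, library: MotifLibrary) -> list[ElementHit]:
    """All (possibly overlapping) IUPAC matches on both strands.

    Minus-strand matches are found by scanning the reverse-complemented
    consensus and reported at the plus-strand start of the window; an
    element matching the same window on both strands (palindrome) yields
    one hit. Ambiguous promoter bases (N) never match.
    """
    seq = promoter.sequence
    hits: list[ElementHit] = []
    for motif in library:
        m = len(motif.consensus)
        if m > len(seq):
            continue
        fwd = match_positions(seq, motif.consensus)
        rev = match_positions(seq, revcomp(motif.consensus))
        for i in sorted(fwd | rev):
            hits.append(
                ElementHit(
                    gene_id=promoter.gene_id,
                    element_name=motif.name,
                    start=i + 1,
                    strand="+" if i in fwd else "-",
                    functional_class=motif.functional_class,
                    length=m,
                )
            )
    hits.sort(key=lambda h: (h.element_name, h.start, h.strand))
    return hits


def element_proportions(
    hits: list[ElementHit],
    grouping: dict[str, str],
    level: str = "species",
) -> pd.DataFrame:
    """Per-group element frequencies normalised to the group's total hits.

    Rows are groups at the requested level (species, subfamily or OGG),
    columns elements; every row sums to 1. Groups with no hits are absent.
    """
    if level not in {"species", "subfamily", "OGG"}:
        raise ValueError(f"unknown grouping level {level!r}")
    counts: dict[str, dict[str, int]] = {}
    for h in hits:
        if h.gene_id not in grouping:
            raise KeyError(f"gene {h.gene_id!r} missing from the grouping map")
        g = grouping[h.gene_id]
        counts.setdefault(g, {}).setdefault(h.element_name, 0)
        counts[g][h.element_name] += 1
    df = pd.DataFrame(counts).T.fillna(0.0).sort_index()
    df = df[sorted(df.columns)]
    return df.div(df.sum(axis=1), axis=0)


def class_proportions(class_counts: dict[str, int], total: int) -> dict[str, float]:
    """Class-level shares in percent, half-up to 1 decimal."""
    return {
        cls: round_half_up(100.0 * n / total, 1) for cls, n in class_counts.items()
    }


def zscore_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores with population sd; constant columns become zeros."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to scale columns")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    out = np.zeros_like(values)
    nz = sd > 0
    out[:, nz] = (values[:, nz] - mean[nz]) / sd[nz]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
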