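"""Family-member identification: domain-scan filtering, isoform reduction
and positional renaming.

A candidate protein survives when at least one domain hit passes the
E-value cutoff with sufficient model coverage ("complete" domain) and the
protein itself is long enough. Validated loci keep their longest CDS
isoform and are renamed by chromosomal position with a species prefix, the
field's convention for gene-family rosters.
"""

from __future__ import annotations

from dataclasses import dataclass

from asterfam._util import natural_key
from asterfam.models import DomainHit, GeneModel


@dataclass(frozen=True)
class IdentificationConfig:
    evalue_cutoff: float = 1e-10
    min_protein_length: int = 100
    require_complete_domain: bool = True
    domain_completeness_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.min_protein_length < 1:
            raise ValueError("min_protein_length must be >= 1")


def filter_candidates(
    hits: list[DomainHit],
    proteins: dict[str, int],
    config: IdentificationConfig = IdentificationConfig(),
) -> set[str]:
    """Protein ids with >=1 hit passing E-value, coverage and length filters.

    ``proteins`` maps protein id to amino-acid length and must cover every
    hit. With several hits per protein the best (lowest-E) qualifying hit
    decides.
    """
    passed: set[str] = set()
    for h in hits:
        if h.protein_id not in proteins:
            raise KeyError(f"protein {h.protein_id!r} missing from the length map")
        if h.full_sequence_evalue > config.evalue_cutoff:
            continue
        if (
            config.require_complete_domain
            and h.model_coverage() < config.domain_completeness_fraction
        ):
            continue
        if proteins[h.protein_id] < config.min_protein_length:
            continue
        passed.add(h.protein_id)
    return passed


def longest_isoform(genes: list[GeneModel]) -> list[GeneModel]:
    """Keep one transcript per gene: greatest summed CDS length, ties by
    lexicographically smallest transcript id."""
    out = []
    for g in genes:
        if not g.transcripts:
            raise ValueError(f"gene {g.gene_id} has no transcripts")
        best = min(g.transcripts, key=lambda t: (-t.cds_length(), t.transcript_id))
        out.append(g.with_transcripts((best,)))
    return out


def rename_by_position(genes: list[GeneModel], prefix: str) -> list[GeneModel]:
    """Assign ``prefix`` + zero-padded index by (chromosome, start, id).

    Chromosomes compare in natural order so chr2 precedes chr10. The pad
    width is the digit count of the family size, keeping names sortable.
    """
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene id {g.gene_id!r}")
        seen.add(g.gene_id)
    ordered = sorted(
        genes, key=lambda g: (natural_key(g.chromosome), g.start, g.gene_id)
    )
    width = len(str(len(ordered))) if ordered else 1
    for i, g in enumerate(ordered, start=1):
        g.family_name = f"{prefix}{i:0{width}d}"
    return ordered
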