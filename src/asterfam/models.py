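"""Core record types shared across the pipeline stages.

Coordinates follow GFF3 conventions throughout: 1-based, inclusive, with
strand "+" or "-". A gene's *rank* is its 1-based position along its
chromosome when all annotated genes are ordered by start coordinate; ranks
are the substrate for tandem/proximal calling and collinear-block chaining.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

Interval = tuple[int, int]


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class GeneModel:
    """One gene locus with its transcript structure."""

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    transcripts: tuple[Transcript, ...] = ()
    rank: int = 0
    family_name: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    def with_transcripts(self, transcripts: tuple[Transcript, ...]) -> "GeneModel":
        return replace(self, transcripts=transcripts)


@dataclass(frozen=True)
class DomainHit:
    """One hmmsearch domain hit in domtblout convention (1-based coords)."""

    protein_id: str
    model_id: str
    full_sequence_evalue: float
    model_from: int
    model_to: int
    ali_from: int
    ali_to: int
    model_length: int

    def model_coverage(self) -> float:
        return (self.model_to - self.model_from + 1) / self.model_length


@dataclass
class OrthoGroup:
    """A cross-species orthologous gene group with its conservation class."""

    ogg_id: str
    members: tuple[str, ...]
    presence: dict[str, int]  # species -> copy number
    category: str = ""  # conserved / variable / rare


@dataclass(frozen=True)
class KaKsPair:
    """Nei–Gojobori site and difference counts for one codon-aligned pair.

    ``omega`` is None when Ks = 0 or the Jukes–Cantor correction is
    undefined (p >= 3/4) for either rate.
    """

    gene_a: str
    gene_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float | None
    Ka: float | None
    omega: float | None


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int


@dataclass
class SyntenyBlock:
    block_id: str
    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    anchors: tuple[AnchorPair, ...]
    orientation: str  # same / inverted

    @property
    def score(self) -> int:
        return len(self.anchors)

    def gene_ids(self) -> set[str]:
        out: set[str] = set()
        for a in self.anchors:
            out.add(a.gene_a)
            out.add(a.gene_b)
        return out


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    mode: str  # WGD / TD / PD / TRD / DSD / singleton
    evidence: str = ""


@dataclass(frozen=True)
class PromoterSeq:
    gene_id: str
    sequence: str
    truncated: bool

    @property
    def actual_length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ElementHit:
    gene_id: str
    element_name: str
    start: int  # 1-based offset within the promoter, plus-strand coords
    strand: str
    functional_class: str
    length: int = 0

    @property
    def end(self) -> int:
        return self.start + self.length - 1
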