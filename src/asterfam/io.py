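"""Flat-file I/O: GFF3, FASTA, HMMER domain tables and the pipeline TSVs.

GFF3 files are read into :class:`~asterfam.models.GeneModel` records and
written back with gene/mRNA/exon/CDS features only, which is the vocabulary
every stage of this pipeline consumes. FASTA goes through Biopython.
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from asterfam._util import natural_key
from asterfam.models import DomainHit, GeneModel, Transcript


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _parse_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key] = value
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into GeneModel records.

    Ranks are assigned per chromosome by ascending start (ties by gene id).
    """
    genes: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    tx_parts: dict[str, dict[str, list]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = (
                line.rstrip("\n").split("\t")
            )
            a = _parse_attributes(attrs)
            start, end = int(start), int(end)
            if ftype == "gene":
                gid = a["ID"]
                genes[gid] = {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "species": a.get("species", ""),
                    "tx": [],
                }
            elif ftype == "mRNA":
                tid = a["ID"]
                tx_parent[tid] = a["Parent"]
                tx_parts[tid] = {"exon": [], "cds": []}
            elif ftype == "exon":
                tx_parts[a["Parent"]]["exon"].append((start, end))
            elif ftype == "CDS":
                tx_parts[a["Parent"]]["cds"].append((start, end))
    for tid, parent in tx_parent.items():
        parts = tx_parts[tid]
        genes[parent]["tx"].append(
            Transcript(
                transcript_id=tid,
                exons=tuple(sorted(parts["exon"])),
                cds=tuple(sorted(parts["cds"])),
            )
        )
    out = []
    for gid, g in genes.items():
        out.append(
            GeneModel(
                gene_id=gid,
                species=g["species"],
                chromosome=g["chrom"],
                start=g["start"],
                end=g["end"],
                strand=g["strand"],
                transcripts=tuple(sorted(g["tx"], key=lambda t: t.transcript_id)),
            )
        )
    assign_ranks(out)
    return out


def assign_ranks(genes: list[GeneModel]) -> None:
    """Set 1-based per-chromosome ranks ordered by start, in place."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(chrom_genes, start=1):
            g.rank = i


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (natural_key(g.chromosome), g.start, g.gene_id)):
        attrs = f"ID={g.gene_id}"
        if g.species:
            attrs += f";species={g.species}"
        lines.append(
            f"{g.chromosome}\tasterfam\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for t in g.transcripts:
            lines.append(
                f"{g.chromosome}\tasterfam\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={t.transcript_id};Parent={g.gene_id}"
            )
            for s, e in t.exons:
                lines.append(
                    f"{g.chromosome}\tasterfam\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={t.transcript_id}"
                )
            for s, e in t.cds:
                lines.append(
                    f"{g.chromosome}\tasterfam\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"Parent={t.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_domain_table(path: str | Path) -> list[DomainHit]:
    """Read the tab-separated domain-hit table.

    Columns: target protein, query model, full-sequence E-value, model
    length, model from/to, alignment from/to — the subset of HMMER3
    domtblout fields this pipeline uses.
    """
    hits = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            hits.append(
                DomainHit(
                    protein_id=row[0],
                    model_id=row[1],
                    full_sequence_evalue=float(row[2]),
                    model_length=int(row[3]),
                    model_from=int(row[4]),
                    model_to=int(row[5]),
                    ali_from=int(row[6]),
                    ali_to=int(row[7]),
                )
            )
    return hits


def write_domain_table(hits: list[DomainHit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow("#target model evalue mlen mfrom mto alifrom alito".split())
        for h in hits:
            w.writerow(
                [
                    h.protein_id,
                    h.model_id,
                    f"{h.full_sequence_evalue:g}",
                    h.model_length,
                    h.model_from,
                    h.model_to,
                    h.ali_from,
                    h.ali_to,
                ]
            )


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def write_tsv(rows: list[dict], path: str | Path, columns: list[str] | None = None) -> None:
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=columns, delimiter="\t", lineterminator="\n")
        w.writeheader()
        w.writerows(rows)
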