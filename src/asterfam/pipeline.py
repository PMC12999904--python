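"""End-to-end orchestration of the comparative-genomics stages.

The pipeline consumes the standard flat files (GFF3, FASTA, domain-hit
tables, homology/motif/expression TSVs, one directory per dataset) and
runs identification, structure metrics, subfamily classification,
orthogrouping, Ka/Ks, duplication/synteny, promoter profiling and the
expression screens, writing every stage's TSV outputs plus a JSON run
manifest. Stages communicate only through their files, so any stage's
inputs can be swapped for externally produced equivalents.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from asterfam._util import round_half_up
from asterfam.expression import QpcrRecord, ddct, de_screen, fpkm, row_scale
from asterfam.identify import IdentificationConfig, filter_candidates, longest_isoform, rename_by_position
from asterfam.io import read_domain_table, read_fasta, read_gff3, read_tsv, write_tsv
from asterfam.kaks import aggregate, align_proteins, backtranslate, ng86, translate
from asterfam.models import AnchorPair, DuplicationCall, GeneModel
from asterfam.orthogroups import build_oggs, category_proportions, presence_matrix
from asterfam.phylo import (
    ReferencePanel,
    TrimConfig,
    assign_labels,
    neighbor_joining,
    pairwise_distance,
    trim_alignment,
)
from asterfam.promoters import MotifLibrary, element_proportions, extract_promoter, scan, zscore_columns
from asterfam.synteny import chain_anchors, classify_duplications, synteny_conservation_table

STAGES = (
    "identify",
    "structure",
    "classify",
    "orthogroups",
    "selection",
    "synteny",
    "duplication",
    "promoters",
    "expression",
)


@dataclass
class PipelineConfig:
    input_dir: Path
    output_dir: Path
    species: list[str]
    outgroup: str = "outg"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    identification: IdentificationConfig = field(default_factory=IdentificationConfig)
    gap_threshold: float = 0.2
    min_block_size: int = 10
    max_rank_gap: int = 25
    homology_score_floor: float = 80.0
    proximal_max_gap: int = 10
    promoter_window: int = 2000
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def correlate(x: list[float], y: list[float]) -> tuple[float, float]:
    """Pearson's r with its two-sided p from the t transform (df = n - 2)."""
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def crosstab_dup_by_category(
    calls: list[DuplicationCall], categories: dict[str, str]
) -> pd.DataFrame:
    """Duplication-mode by conservation-class contingency table.

    Rows are modes, one count column and one half-up percentage column per
    class; percentages are within-class (column) shares.
    """
    modes = ["WGD", "TD", "PD", "TRD", "DSD", "singleton"]
    cats = ["conserved", "variable", "rare"]
    counts = {c: {m: 0 for m in modes} for c in cats}
    for call in calls:
        if call.gene_id not in categories:
            raise KeyError(f"gene {call.gene_id!r} has no conservation class")
        counts[categories[call.gene_id]][call.mode] += 1
    out = pd.DataFrame({c: counts[c] for c in cats})
    for c in cats:
        total = out[c].sum()
        out[f"{c}_pct"] = [
            round_half_up(100.0 * v / total, 2) if total else 0.0 for v in out[c]
        ]
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(cfg: PipelineConfig, stage: str, dependency: str) -> None:
    if not cfg.stages.get(dependency, False):
        raise StageError(stage, f"requires the {dependency!r} stage output")


def run(cfg: PipelineConfig) -> dict:
    """Execute every enabled stage; returns the manifest dictionary."""
    ind, outd = cfg.input_dir, cfg.output_dir
    outd.mkdir(parents=True, exist_ok=True)
    from asterfam import __version__ as version

    manifest: dict = {
        "version": version,
        "stages": [],
        "parameters": {
            "gap_threshold": cfg.gap_threshold,
            "min_block_size": cfg.min_block_size,
            "max_rank_gap": cfg.max_rank_gap,
            "evalue_cutoff": cfg.identification.evalue_cutoff,
            "min_protein_length": cfg.identification.min_protein_length,
            "pseudocount": cfg.pseudocount,
            "seed": cfg.seed,
        },
        "inputs": {},
        "counts": {},
    }
    results: dict = {"manifest": manifest}

    roster: dict[str, list[GeneModel]] = {}
    annotation: dict[str, list[GeneModel]] = {}
    cds: dict[str, str] = {}

    for sp in cfg.species:
        gff = ind / f"{sp}.gff3"
        manifest["inputs"][gff.name] = _sha256(gff)
        annotation[sp] = read_gff3(gff)
        cds.update(read_fasta(ind / f"{sp}.cds.fa"))

    # ------------------------------------------------------------------ 1
    if cfg.stages.get("identify", False):
        roster_rows = []
        for sp in cfg.species:
            hits = read_domain_table(ind / f"{sp}.domains.tsv")
            proteins = {k: len(v) for k, v in read_fasta(ind / f"{sp}.protein.fa").items()}
            accepted = filter_candidates(hits, proteins, cfg.identification)
            genes = [g for g in annotation[sp] if g.gene_id in accepted]
            genes = longest_isoform(genes)
            genes = rename_by_position(genes, prefix=f"{sp}_FAM")
            roster[sp] = genes
            manifest["counts"][f"{sp}.family_size"] = len(genes)
            roster_rows += [
                {
                    "gene_id": g.gene_id,
                    "species": sp,
                    "chromosome": g.chromosome,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "family_name": g.family_name,
                }
                for g in genes
            ]
        write_tsv(roster_rows, outd / "roster.tsv")
        manifest["stages"].append("identify")
    family_genes = [g for sp in cfg.species for g in roster.get(sp, [])]
    results["roster"] = roster

    # ------------------------------------------------------------------ 2
    if cfg.stages.get("structure", False):
        _require(cfg, "structure", "identify")
        from asterfam.structure import structure_metrics

        rows = []
        for g in family_genes:
            rec = structure_metrics(g, cds.get(g.gene_id))
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "species": g.species,
                    "gene_length": rec.gene_length,
                    "cds_count": rec.cds_count,
                    "intron_count": rec.intron_count,
                    "total_intron_length": rec.total_intron_length,
                    "aa_length": rec.aa_length,
                }
            )
        write_tsv(rows, outd / "structure.tsv")
        manifest["stages"].append("structure")

    # ------------------------------------------------------------------ 3
    subfamily_of: dict[str, tuple[str, int | None]] = {}
    if cfg.stages.get("classify", False):
        _require(cfg, "classify", "identify")
        panel_rows = read_tsv(ind / "refs.tsv")
        panel = ReferencePanel(
            {r["ref"]: (r["subfamily"], int(r["cluster"])) for r in panel_rows}
        )
        for sp in cfg.species:
            aln = read_fasta(ind / f"{sp}.aln.fa")
            keep = set(panel.labels) | {g.gene_id for g in roster[sp]}
            aln = {k: v for k, v in aln.items() if k in keep}
            trimmed = trim_alignment(aln, TrimConfig(cfg.gap_threshold))
            dm = pairwise_distance(trimmed)
            tree = neighbor_joining(dm)
            (outd / f"{sp}.nwk").write_text(str(tree))
            labels = assign_labels(tree, panel)
            for gid, lab in labels.items():
                if gid not in panel.labels:
                    subfamily_of[gid] = lab
        write_tsv(
            [
                {"gene_id": g, "subfamily": s, "cluster": c if c is not None else ""}
                for g, (s, c) in sorted(subfamily_of.items())
            ],
            outd / "subfamilies.tsv",
        )
        manifest["stages"].append("classify")
    results["subfamily_of"] = subfamily_of

    # ------------------------------------------------------------------ 4
    homology_rows = read_tsv(ind / "homology.tsv")
    oggs = []
    category_of: dict[str, str] = {}
    ogg_of: dict[str, str] = {}
    if cfg.stages.get("orthogroups", False):
        _require(cfg, "orthogroups", "identify")
        edges = [
            (r["gene_a"], r["gene_b"], float(r["score"]))
            for r in homology_rows
        ]
        oggs = build_oggs(edges, family_genes)
        for o in oggs:
            for m in o.members:
                ogg_of[m] = o.ogg_id
                category_of[m] = o.category
        ids, sps, matrix = presence_matrix(oggs)
        write_tsv(
            [
                {"ogg_id": i, "category": o.category,
                 **dict(zip(sps, row)), "n_members": len(o.members)}
                for i, o, row in zip(ids, oggs, matrix)
            ],
            outd / "oggs.tsv",
        )
        per_cat: dict[str, int] = {"conserved": 0, "variable": 0, "rare": 0}
        for o in oggs:
            per_cat[o.category] += len(o.members)
        props = category_proportions(per_cat, len(family_genes))
        write_tsv(
            [
                {"category": c, "n_genes": per_cat[c], "pct_genes": props[c]}
                for c in per_cat
            ],
            outd / "ogg_gene_shares.tsv",
        )
        manifest["counts"]["n_oggs"] = len(oggs)
        manifest["stages"].append("orthogroups")
    results["oggs"] = oggs
    results["category_of"] = category_of

    # ------------------------------------------------------------------ 5
    kaks_pairs = []
    if cfg.stages.get("selection", False):
        _require(cfg, "selection", "orthogroups")
        members_by_ogg: dict[str, list[str]] = {}
        for g, o in sorted(ogg_of.items()):
            members_by_ogg.setdefault(o, []).append(g)
        for o in sorted(members_by_ogg):
            ms = members_by_ogg[o]
            for i in range(len(ms)):
                for j in range(i + 1, len(ms)):
                    a, b = ms[i], ms[j]
                    pa, pb = translate(_strip_stop(cds[a])), translate(_strip_stop(cds[b]))
                    # equal-length proteins pair positionally; only indel
                    # cases need the global-alignment fallback
                    rows = (pa, pb) if len(pa) == len(pb) else align_proteins(pa, pb)
                    codon_aln = backtranslate(rows, cds[a], cds[b])
                    kaks_pairs.append(ng86(codon_aln, a, b))
        write_tsv(
            [
                {
                    "gene_a": p.gene_a, "gene_b": p.gene_b,
                    "S": round(p.S, 4), "N": round(p.N, 4),
                    "Sd": round(p.Sd, 4), "Nd": round(p.Nd, 4),
                    "Ks": "" if p.Ks is None else round(p.Ks, 6),
                    "Ka": "" if p.Ka is None else round(p.Ka, 6),
                    "omega": "" if p.omega is None else round(p.omega, 6),
                }
                for p in kaks_pairs
            ],
            outd / "kaks_pairs.tsv",
        )
        cluster_of_ogg = _majority_cluster(ogg_of, subfamily_of)
        ogg_rows, cluster_rows = aggregate(kaks_pairs, ogg_of, cluster_of_ogg)
        write_tsv(
            [{k: (round(v, 6) if isinstance(v, float) else v) for k, v in r.items()}
             for r in ogg_rows],
            outd / "kaks_oggs.tsv",
        )
        if cluster_rows:
            write_tsv(
                [{k: (round(v, 6) if isinstance(v, float) else v) for k, v in r.items()}
                 for r in cluster_rows],
                outd / "kaks_clusters.tsv",
            )
        manifest["counts"]["n_kaks_pairs"] = len(kaks_pairs)
        manifest["stages"].append("selection")
    results["kaks_pairs"] = kaks_pairs

    # ------------------------------------------------------------------ 6
    rank_of: dict[str, tuple[str, int]] = {}
    for sp in cfg.species:
        for g in annotation[sp]:
            rank_of[g.gene_id] = (g.chromosome, g.rank)
    species_of = {g.gene_id: g.species for sp in cfg.species for g in annotation[sp]}
    cross_blocks = []
    if cfg.stages.get("synteny", False):
        _require(cfg, "synteny", "orthogroups")
        anchors = []
        for r in homology_rows:
            a, b = r["gene_a"], r["gene_b"]
            if float(r["score"]) < cfg.homology_score_floor:
                continue
            if a not in rank_of or b not in rank_of:
                continue
            if species_of.get(a) == species_of.get(b):
                continue
            (ca, ra), (cb, rb) = rank_of[a], rank_of[b]
            if (cb, b) < (ca, a):
                a, b, ca, ra, cb, rb = b, a, cb, rb, ca, ra
            anchors.append(AnchorPair(a, b, ca, cb, ra, rb))
        cross_blocks = chain_anchors(anchors, cfg.min_block_size, cfg.max_rank_gap)
        write_tsv(
            [
                {
                    "block_id": blk.block_id, "chrom_a": blk.chrom_a,
                    "chrom_b": blk.chrom_b, "orientation": blk.orientation,
                    "n_anchors": blk.score,
                    "gene_a": a.gene_a, "gene_b": a.gene_b,
                }
                for blk in cross_blocks
                for a in blk.anchors
            ],
            outd / "synteny_blocks.tsv",
            ["block_id", "chrom_a", "chrom_b", "orientation", "n_anchors", "gene_a", "gene_b"],
        )
        fam_ids = {g.gene_id for g in family_genes}
        table = synteny_conservation_table(
            [blk for blk in cross_blocks],
            {g: category_of[g] for g in fam_ids if g in category_of},
        )
        write_tsv(table, outd / "synteny_conservation.tsv")
        results["synteny_conservation"] = table
        manifest["counts"]["n_cross_blocks"] = len(cross_blocks)
        manifest["stages"].append("synteny")
    results["cross_blocks"] = cross_blocks

    # ------------------------------------------------------------------ 7
    calls: list[DuplicationCall] = []
    if cfg.stages.get("duplication", False):
        _require(cfg, "duplication", "orthogroups")
        out_annot = read_gff3(ind / f"{cfg.outgroup}.gff3")
        for g in out_annot:
            rank_of[g.gene_id] = (g.chromosome, g.rank)
        for sp in cfg.species:
            sp_ids = {g.gene_id for g in annotation[sp]}
            intra_pairs, outgroup_anchors, intra_anchors = [], [], []
            for r in homology_rows:
                a, b = r["gene_a"], r["gene_b"]
                if float(r["score"]) < cfg.homology_score_floor:
                    continue
                in_a, in_b = a in sp_ids, b in sp_ids
                if in_a and in_b:
                    intra_pairs.append((a, b))
                    (ca, ra), (cb, rb) = rank_of[a], rank_of[b]
                    if ca != cb or ra != rb:
                        intra_anchors.append(AnchorPair(a, b, ca, cb, ra, rb))
                elif (in_a or in_b) and (
                    a.startswith(cfg.outgroup) or b.startswith(cfg.outgroup)
                ):
                    if b in sp_ids:
                        a, b = b, a
                    (ca, ra), (cb, rb) = rank_of[a], rank_of[b]
                    outgroup_anchors.append(AnchorPair(a, b, ca, cb, ra, rb))
            intra_blocks = chain_anchors(intra_anchors, cfg.min_block_size, cfg.max_rank_gap)
            outgroup_blocks = chain_anchors(outgroup_anchors, cfg.min_block_size, cfg.max_rank_gap)
            fam = roster[sp]
            fam_ids = {g.gene_id for g in fam}
            pairs = [(a, b) for a, b in intra_pairs if a in fam_ids and b in fam_ids]
            calls += classify_duplications(
                fam, pairs, intra_blocks, outgroup_blocks, cfg.proximal_max_gap
            )
        write_tsv(
            [{"gene_id": c.gene_id, "mode": c.mode, "evidence": c.evidence} for c in calls],
            outd / "duplication_calls.tsv",
        )
        if category_of:
            xtab = crosstab_dup_by_category(
                [c for c in calls if c.gene_id in category_of], category_of
            )
            xtab.to_csv(outd / "dup_by_category.tsv", sep="\t")
            results["dup_by_category"] = xtab
        manifest["stages"].append("duplication")
    results["duplication_calls"] = calls

    # ------------------------------------------------------------------ 8
    hits_all = []
    if cfg.stages.get("promoters", False):
        _require(cfg, "promoters", "identify")
        library = MotifLibrary.from_tsv(ind / "motifs.tsv")
        prom_rows = []
        for sp in cfg.species:
            genome = read_fasta(ind / f"{sp}.genome.fa")
            for g in roster[sp]:
                prom = extract_promoter(g, genome, cfg.promoter_window)
                prom_rows.append(
                    {"gene_id": g.gene_id, "length": prom.actual_length,
                     "truncated": prom.truncated}
                )
                hits_all += scan(prom, library)
        write_tsv(prom_rows, outd / "promoters.tsv")
        write_tsv(
            [
                {"gene_id": h.gene_id, "element": h.element_name, "start": h.start,
                 "strand": h.strand, "class": h.functional_class}
                for h in hits_all
            ],
            outd / "element_hits.tsv",
        )
        gene_species = {g.gene_id: sp for sp in cfg.species for g in roster[sp]}
        props = element_proportions(hits_all, gene_species, "species")
        props.to_csv(outd / "element_proportions.tsv", sep="\t")
        if len(props) >= 2:
            zscore_columns(props).to_csv(outd / "element_zscores.tsv", sep="\t")
        manifest["counts"]["n_element_hits"] = len(hits_all)
        manifest["stages"].append("promoters")
    results["element_hits"] = hits_all

    # ------------------------------------------------------------------ 9
    de_calls = []
    if cfg.stages.get("expression", False):
        expr = pd.DataFrame(read_tsv(ind / "expression.tsv"))
        expr["count"] = expr["count"].astype(int)
        expr["length"] = expr["length"].astype(int)
        # library size: the mapped-read totals if provided, else the column sums
        if "total_mapped" in expr.columns:
            totals = expr.groupby("sample")["total_mapped"].first().astype(int)
        else:
            totals = expr.groupby("sample")["count"].sum()
        expr["fpkm"] = [
            fpkm(c, l, int(totals[s]))
            for c, l, s in zip(expr["count"], expr["length"], expr["sample"])
        ]
        mat = expr.pivot_table(index="gene", columns="sample", values="fpkm")
        cond_of = dict(zip(expr["sample"], expr["condition"]))
        control_cols = [c for c in mat.columns if cond_of[c] == "control"]
        treated_cols = [c for c in mat.columns if cond_of[c] != "control"]
        for gid in mat.index:
            de_calls.append(
                de_screen(
                    float(mat.loc[gid, treated_cols].mean()),
                    float(mat.loc[gid, control_cols].mean()),
                    gene_id=gid,
                    pseudocount=cfg.pseudocount,
                )
            )
        write_tsv(
            [
                {"gene_id": d.gene_id, "log2fc": round(d.log2fc, 4),
                 "responsive": d.responsive}
                for d in de_calls
            ],
            outd / "de_calls.tsv",
        )
        row_scale(mat).round(4).to_csv(outd / "fpkm_rowscaled.tsv", sep="\t")
        qpcr_path = ind / "qpcr.tsv"
        if qpcr_path.exists():
            recs: dict[tuple, list[QpcrRecord]] = {}
            for r in read_tsv(qpcr_path):
                rec = QpcrRecord(
                    r["gene"], r["condition"], float(r["timepoint"]),
                    int(r["replicate"]), float(r["ct_target"]), float(r["ct_reference"]),
                )
                recs.setdefault((rec.gene_id, rec.condition, rec.timepoint), []).append(rec)
            fold_rows = []
            for (gid, cond, tp) in sorted(recs):
                control = recs.get((gid, cond, 0.0))
                if control is None:
                    raise StageError("expression", f"no 0 h control for {gid}/{cond}")
                res = ddct(recs[(gid, cond, tp)], control)
                fold_rows.append(
                    {"gene_id": gid, "condition": cond, "timepoint": tp,
                     "mean_fold": round(res.mean_fold, 4), "sd_fold": round(res.sd_fold, 4)}
                )
            write_tsv(fold_rows, outd / "qpcr_folds.tsv")
        manifest["counts"]["n_responsive"] = sum(d.responsive for d in de_calls)
        manifest["stages"].append("expression")
    results["de_calls"] = de_calls

    (outd / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


def _strip_stop(cds: str) -> str:
    from asterfam.kaks import STOP_CODONS

    return cds[:-3] if len(cds) >= 3 and cds[-3:] in STOP_CODONS else cds


def _majority_cluster(
    ogg_of: dict[str, str], subfamily_of: dict[str, tuple[str, int | None]]
) -> dict[str, str]:
    """Cluster label per OGG: most common assigned cluster of its members."""
    votes: dict[str, dict[str, int]] = {}
    for g, o in ogg_of.items():
        lab = subfamily_of.get(g)
        if lab is None or lab[1] is None:
            continue
        key = f"{lab[0]}_{lab[1]}"
        votes.setdefault(o, {}).setdefault(key, 0)
        votes[o][key] += 1
    return {
        o: max(v, key=lambda k: (v[k], k)) for o, v in votes.items()
    }
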