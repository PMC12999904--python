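"""Synthetic multi-species genome fixtures with planted ground truth.

The generator emulates the study design this package analyses: a
gene-family complement across N related species plus an outgroup, with

* orthogroups planted as conserved / variable / rare presence patterns,
* coding pairs carrying exact planted synonymous and nonsynonymous
  substitution counts (one substitution per codon, so the Nei–Gojobori
  counts are integer-exact),
* duplication events of five modes (WGD block, tandem, proximal,
  transposed with an outgroup-syntenic ancestral copy, dispersed),
* collinear blocks of at least ``block_length`` anchors between the first
  two species, within the first species (WGD) and against the outgroup,
* promoters of a fixed window whose background is scrubbed of every
  library motif before the planned element instances are inserted,
* treatment-versus-control expression counts with planted log2 fold
  changes, and a qPCR Ct table with planted induction curves.

Every file is emitted in a standard plain-text format (FASTA, GFF3,
HMMER-style domain table, TSV) and all randomness flows from per-stream
generators derived from one master seed, so equal configurations produce
byte-identical outputs.

Placement is engineered so that planted collinear blocks are the only
chains reaching the minimum block size: genes inside planted runs sit in
consecutive gene slots, while all other family genes are kept at least one
``max_rank_gap`` window away from the runs and are scattered at low
density, below the chaining threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from asterfam._util import subseed
from asterfam.io import write_domain_table, write_fasta, write_gff3, write_tsv
from asterfam.kaks import CODON_TABLE, STOP_CODONS, translate
from asterfam.models import DomainHit, GeneModel, Transcript
from asterfam.promoters import (
    IUPAC,
    MotifLibrary,
    default_motif_library,
    match_positions,
    revcomp,
)

_NONSTOP_CODONS = sorted(CODON_TABLE)
_BASES = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"
_MAX_RANK_GAP = 25  # chaining gap bound the layout must defeat
_RUN_START = 4  # 0-based slot where planted runs begin

_SUBFAMILY_OF_CLUSTER = {
    **{c: "MEKK" for c in range(1, 6)},
    **{c: "ZIK" for c in (6, 7)},
    **{c: "RAF" for c in range(8, 15)},
}


@dataclass
class SyntheticConfig:
    """Study-shaped generator settings; defaults mirror the ten-species design."""

    n_species: int = 10
    genes_per_chromosome: int = 200
    chromosomes_per_species: int = 2
    n_oggs: int = 50
    category_mix: tuple[float, float, float] = (0.3, 0.5, 0.2)
    planted_omegas: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0)
    dup_events: dict = field(
        default_factory=lambda: {"WGD": 1, "TD": 3, "PD": 3, "TRD": 2, "DSD": 3}
    )
    block_length: int = 12
    motif_plan: dict = field(
        default_factory=lambda: {
            "ABRE": 2,
            "MYC": 2,
            "STRE": 1,
            "Box-4": 1,
            "GT1-motif": 1,
            "CAT-box": 1,
        }
    )
    seed: int = 0
    promoter_window: int = 2000
    ancestor_codon_range: tuple[int, int] = (150, 220)
    intron_length_range: tuple[int, int] = (80, 400)
    spacer_range: tuple[int, int] = (50, 200)

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.genes_per_chromosome < 20:
            raise ValueError("genes_per_chromosome must be >= 20")
        if self.chromosomes_per_species < 1:
            raise ValueError("chromosomes_per_species must be >= 1")
        if self.n_oggs < 1:
            raise ValueError("n_oggs must be >= 1")
        if any(f < 0 for f in self.category_mix) or abs(sum(self.category_mix) - 1) > 1e-9:
            raise ValueError("category_mix must be non-negative and sum to 1")
        if self.block_length < 10:
            raise ValueError("block_length must be >= 10")
        if any(not 0 < w <= 2 for w in self.planted_omegas):
            raise ValueError("planted_omegas must lie in (0, 2]")
        bad = set(self.dup_events) - {"WGD", "TD", "PD", "TRD", "DSD"}
        if bad:
            raise ValueError(f"unknown duplication modes: {sorted(bad)}")

    @property
    def species(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]


@dataclass
class TruthTables:
    """Planted ground truth, keyed by the identifiers the files use."""

    ogg_membership: dict[str, str] = field(default_factory=dict)
    ogg_category: dict[str, str] = field(default_factory=dict)
    ogg_subfamily: dict[str, str] = field(default_factory=dict)
    ogg_cluster: dict[str, int] = field(default_factory=dict)
    dup_mode: dict[str, str] = field(default_factory=dict)
    planted_blocks: list[dict] = field(default_factory=list)
    planted_pair_counts: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    planted_motif_positions: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    planted_log2fc: dict[str, float] = field(default_factory=dict)
    family_roster: dict[str, list[str]] = field(default_factory=dict)
    domain_decoys: dict[str, str] = field(default_factory=dict)
    retained_transcript: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# codon-level machinery


def _one_step_alternatives(codon: str) -> tuple[list[str], list[str]]:
    """(synonymous, nonsynonymous) single-base non-stop neighbours."""
    aa = CODON_TABLE[codon]
    syn, non = [], []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            (syn if CODON_TABLE[alt] == aa else non).append(alt)
    return syn, non


def _random_cds(rng, n_codons: int) -> str:
    """In-frame stop-free CDS of ``n_codons`` codons starting with ATG."""
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 1)
    return "ATG" + "".join(body)


def _mutate(cds: str, syn_subs: int, nonsyn_subs: int, rng) -> str:
    """One planted substitution per codon, never touching the start codon."""
    n = len(cds) // 3
    total = syn_subs + nonsyn_subs
    if total > n - 1:
        raise ValueError(
            f"cannot place {total} substitutions in {n} codons while keeping the start codon"
        )
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    # sample positions from codons that admit the requested change, so no
    # substitution can create a stop (Met/Trp codons have no synonymous
    # one-step neighbour and are skipped for synonymous placements)
    syn_eligible = [i for i in range(1, n) if _one_step_alternatives(codons[i])[0]]
    if len(syn_eligible) < syn_subs:
        raise ValueError(
            f"only {len(syn_eligible)} codons admit a synonymous substitution; "
            f"{syn_subs} requested"
        )
    syn_pos = set(
        int(i) for i in rng.choice(syn_eligible, size=syn_subs, replace=False)
    ) if syn_subs else set()
    non_eligible = [
        i for i in range(1, n)
        if i not in syn_pos and _one_step_alternatives(codons[i])[1]
    ]
    if len(non_eligible) < nonsyn_subs:
        raise ValueError(
            f"only {len(non_eligible)} codons admit a nonsynonymous substitution; "
            f"{nonsyn_subs} requested"
        )
    non_pos = set(
        int(i) for i in rng.choice(non_eligible, size=nonsyn_subs, replace=False)
    ) if nonsyn_subs else set()
    new = list(codons)
    for pos in sorted(syn_pos | non_pos):
        syn_alts, non_alts = _one_step_alternatives(codons[pos])
        alts = syn_alts if pos in syn_pos else non_alts
        new[pos] = alts[int(rng.integers(len(alts)))]
    return "".join(new)


def evolve_codon_pair(
    ancestor_len_codons: int, syn_subs: int, nonsyn_subs: int, seed: int
) -> tuple[str, str]:
    """A CDS pair differing at exactly the planted substitution counts.

    At most one substitution is planted per codon, so the pairwise
    synonymous/nonsynonymous difference counts are unambiguous integers;
    no substitution creates a stop codon and both sequences stay in frame.
    """
    if syn_subs < 0 or nonsyn_subs < 0:
        raise ValueError("substitution counts must be non-negative")
    if syn_subs + nonsyn_subs > ancestor_len_codons:
        raise ValueError("more substitutions requested than codons available")
    rng = subseed(seed, "evolve")
    ancestor = _random_cds(rng, ancestor_len_codons)
    derived = _mutate(ancestor, syn_subs, nonsyn_subs, rng)
    return ancestor, derived


# ---------------------------------------------------------------------------
# promoter construction


def _concretize(consensus: str, rng) -> str:
    return "".join(
        c if len(IUPAC[c]) == 1 else IUPAC[c][int(rng.integers(len(IUPAC[c])))]
        for c in consensus
    )


def _scrubbed_background(rng, n: int, library: MotifLibrary) -> str:
    """Random sequence with every library motif occurrence erased."""
    seq = list(rng.choice(list(_BASES), size=n))
    patterns = []
    for m in library:
        patterns.append(m.consensus)
        patterns.append(revcomp(m.consensus))
    for _ in range(60):
        text = "".join(seq)
        dirty = False
        for pat in patterns:
            for off in match_positions(text, pat):
                dirty = True
                for k in range(off, off + len(pat)):
                    seq[k] = _BASES[int(rng.integers(4))]
        if not dirty:
            return "".join(seq)
    raise RuntimeError("background scrubbing did not converge")


def _build_promoter(
    rng, window: int, library: MotifLibrary, plan: dict[str, int]
) -> tuple[str, list[tuple[str, int, str]]]:
    """Motif-free background plus the planned element insertions.

    The finished promoter is re-scanned and must contain exactly the
    planted hits; self-matching plans (elements embedded in one another)
    are rejected after bounded retries.
    """
    by_name = {m.name: m for m in library}
    for name in plan:
        if name not in by_name:
            raise ValueError(f"motif plan names unknown element {name!r}")
    for _ in range(100):
        bg = list(_scrubbed_background(rng, window, library))
        occupied: list[tuple[int, int]] = []
        planted: list[tuple[str, int, str]] = []
        feasible = True
        for name in sorted(plan):
            motif = by_name[name]
            m = len(motif.consensus)
            for _k in range(plan[name]):
                for _try in range(200):
                    pos = int(rng.integers(0, window - m + 1))
                    if all(pos + m <= s or pos >= e for s, e in occupied):
                        break
                else:
                    feasible = False
                    break
                strand = "+" if rng.integers(2) == 0 else "-"
                realized = _concretize(motif.consensus, rng)
                ins = realized if strand == "+" else revcomp(realized)
                bg[pos : pos + m] = ins
                # a palindromic instance is reported once, on the plus strand
                if match_positions(ins, motif.consensus) and match_positions(
                    ins, revcomp(motif.consensus)
                ):
                    strand = "+"
                occupied.append((pos, pos + m))
                planted.append((name, pos + 1, strand))
            if not feasible:
                break
        if not feasible:
            continue
        seq = "".join(bg)
        observed = []
        for m in library:
            fwd = match_positions(seq, m.consensus)
            rev = match_positions(seq, revcomp(m.consensus))
            for i in sorted(fwd | rev):
                observed.append((m.name, i + 1, "+" if i in fwd else "-"))
        if sorted(observed) == sorted(planted):
            return seq, sorted(planted, key=lambda p: p[1])
    raise ValueError(
        "motif plan could not be planted without extra matches; "
        "check for elements embedded in one another"
    )


# ---------------------------------------------------------------------------
# gene plans and layout


@dataclass
class _GenePlan:
    gene_id: str
    species: str
    ogg_id: str | None
    cds: str  # without the terminal stop codon
    promoter: str = ""
    motif_positions: list = field(default_factory=list)
    strand: str = "+"
    kind: str = "family"  # family / filler / decoy / outgroup
    second_isoform: bool = False


def _category_counts(n_oggs: int, mix: tuple[float, float, float]) -> tuple[int, int, int]:
    raw = [n_oggs * f for f in mix]
    base = [math.floor(r) for r in raw]
    rem = n_oggs - sum(base)
    order = sorted(range(3), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:rem]:
        base[i] += 1
    return tuple(base)


class _Chromosome:
    """Slot allocator for one chromosome; slot index + 1 is the gene rank."""

    def __init__(self, n_slots: int):
        self.n_slots = n_slots
        self.slots: dict[int, _GenePlan] = {}
        self.random_floor = 0  # random placement must stay at/above this slot

    def place(self, slot: int, plan: _GenePlan) -> None:
        if not 0 <= slot < self.n_slots:
            raise ValueError(
                f"slot {slot} out of range; increase genes_per_chromosome"
            )
        if slot in self.slots:
            raise ValueError(f"slot {slot} already occupied")
        self.slots[slot] = plan

    def place_run(self, start: int, plans: list[_GenePlan]) -> int:
        for i, p in enumerate(plans):
            self.place(start + i, p)
        end = start + len(plans) - 1
        self.random_floor = max(self.random_floor, end + _MAX_RANK_GAP + 2)
        return end

    def free_random_slots(self) -> list[int]:
        return [s for s in range(self.random_floor, self.n_slots) if s not in self.slots]


# ---------------------------------------------------------------------------
# dataset generation


def _plan_oggs(config: SyntheticConfig, rng) -> list[dict]:
    n_cons, n_var, n_rare = _category_counts(config.n_oggs, config.category_mix)
    species = config.species
    n = config.n_species
    oggs = []
    width = len(str(config.n_oggs))
    omegas = list(config.planted_omegas)
    for i in range(config.n_oggs):
        if i < n_cons:
            category, present = "conserved", list(species)
        elif i < n_cons + n_var:
            category = "variable"
            missing = species[(i - n_cons) % n]
            present = [s for s in species if s != missing]
        else:
            category = "rare"
            k = int(rng.integers(1, max(2, n - 1)))  # 1 .. n-2 species
            idx = rng.permutation(n)[:k]
            present = sorted(species[j] for j in idx)
        cluster = (i % 14) + 1
        oggs.append(
            {
                "ogg_id": f"OGG{i + 1:0{width}d}",
                "category": category,
                "present": present,
                "cluster": cluster,
                "subfamily": _SUBFAMILY_OF_CLUSTER[cluster],
                "omega": omegas[i % len(omegas)] if omegas else 0.2,
            }
        )
    return oggs


def _make_members(config: SyntheticConfig, oggs: list[dict], rng, truth: TruthTables):
    """Create one gene per present species per OGG, with planted divergence."""
    counters = {sp: 0 for sp in config.species}
    plans: dict[str, _GenePlan] = {}
    lo, hi = config.ancestor_codon_range
    for ogg in oggs:
        n_codons = int(rng.integers(lo, hi + 1))
        ancestor = _random_cds(rng, n_codons)
        ref_gene = None
        ogg["members"] = {}
        for sp in sorted(ogg["present"]):
            counters[sp] += 1
            gid = f"{sp}g{counters[sp]:03d}"
            if ref_gene is None:
                cds = ancestor
                ref_gene = gid
            else:
                sd = max(1, round(n_codons * float(rng.uniform(0.04, 0.10))))
                nd = round(ogg["omega"] * sd * 3.0)
                while sd + nd > n_codons - 1 and sd + nd > 0:
                    sd = max(1, sd - 1)
                    nd = max(0, nd - 1)
                cds = _mutate(ancestor, sd, nd, rng)
                truth.planted_pair_counts[(ref_gene, gid)] = (sd, nd)
            plan = _GenePlan(gene_id=gid, species=sp, ogg_id=ogg["ogg_id"], cds=cds)
            plans[gid] = plan
            ogg["members"][sp] = gid
            truth.ogg_membership[gid] = ogg["ogg_id"]
            truth.dup_mode[gid] = "singleton"
        truth.ogg_category[ogg["ogg_id"]] = ogg["category"]
        truth.ogg_subfamily[ogg["ogg_id"]] = ogg["subfamily"]
        truth.ogg_cluster[ogg["ogg_id"]] = ogg["cluster"]
    return plans, counters


def _copy_gene(source: _GenePlan, counters, rng, truth: TruthTables) -> _GenePlan:
    sp = source.species
    counters[sp] += 1
    gid = f"{sp}g{counters[sp]:03d}"
    cds = _mutate(source.cds, 2, 1, rng)
    truth.planted_pair_counts[(source.gene_id, gid)] = (2, 1)
    truth.ogg_membership[gid] = source.ogg_id
    return _GenePlan(gene_id=gid, species=sp, ogg_id=source.ogg_id, cds=cds)


def generate_dataset(config: SyntheticConfig, outdir: str | Path):
    """Write the full fixture set and return (paths, TruthTables)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = default_motif_library()
    truth = TruthTables()
    rng_ogg = subseed(config.seed, "oggs")
    rng_seq = subseed(config.seed, "sequences")
    rng_place = subseed(config.seed, "placement")
    rng_prom = subseed(config.seed, "promoters")
    rng_dom = subseed(config.seed, "domains")
    rng_hom = subseed(config.seed, "homology")
    rng_expr = subseed(config.seed, "expression")
    rng_qpcr = subseed(config.seed, "qpcr")
    rng_aln = subseed(config.seed, "alignment")

    species = config.species
    sp1 = species[0]
    sp2 = species[1]
    oggs = _plan_oggs(config, rng_ogg)
    plans, counters = _make_members(config, oggs, rng_seq, truth)

    dup = {k: int(v) for k, v in config.dup_events.items()}
    n_wgd = dup.get("WGD", 0)
    n_td, n_pd, n_trd, n_dsd = (dup.get(k, 0) for k in ("TD", "PD", "TRD", "DSD"))
    L = config.block_length

    # --- choose run OGGs -------------------------------------------------
    def eligible(require: set[str]) -> list[dict]:
        return [o for o in oggs if require <= set(o["present"])]

    cross_pool = [o for o in eligible({sp1, sp2}) if o["category"] != "rare"]
    if len(cross_pool) < L:
        raise ValueError("not enough shared OGGs to plant the cross-species block")
    cross_run = cross_pool[:L]
    used = {o["ogg_id"] for o in cross_run}
    wgd_pool = [o for o in eligible({sp1}) if o["ogg_id"] not in used and o["category"] != "rare"]
    if len(wgd_pool) < n_wgd * L:
        raise ValueError("not enough OGGs to plant the requested WGD blocks")
    wgd_runs = [wgd_pool[e * L : (e + 1) * L] for e in range(n_wgd)]
    for run in wgd_runs:
        used |= {o["ogg_id"] for o in run}
    if n_trd > L:
        raise ValueError("TRD events cannot exceed block_length")

    # --- duplication copies ---------------------------------------------
    copies: dict[str, _GenePlan] = {}
    wgd_copy_runs: list[list[tuple[_GenePlan, _GenePlan]]] = []
    for run in wgd_runs:
        pairs = []
        for o in run:
            src = plans[o["members"][sp1]]
            cp = _copy_gene(src, counters, rng_seq, truth)
            copies[cp.gene_id] = cp
            truth.dup_mode[src.gene_id] = "WGD"
            truth.dup_mode[cp.gene_id] = "WGD"
            pairs.append((src, cp))
        wgd_copy_runs.append(pairs)

    pool = [
        plans[o["members"][sp1]]
        for o in oggs
        if sp1 in o["members"] and o["ogg_id"] not in used
    ]
    need = n_td + n_pd + n_dsd
    if len(pool) < need:
        raise ValueError("not enough spare genes in the first species for TD/PD/DSD events")
    td_pairs, pd_pairs, dsd_pairs, trd_pairs = [], [], [], []
    k = 0
    for _ in range(n_td):
        src = pool[k]; k += 1
        cp = _copy_gene(src, counters, rng_seq, truth)
        copies[cp.gene_id] = cp
        truth.dup_mode[src.gene_id] = truth.dup_mode[cp.gene_id] = "TD"
        td_pairs.append((src, cp))
    for _ in range(n_pd):
        src = pool[k]; k += 1
        cp = _copy_gene(src, counters, rng_seq, truth)
        copies[cp.gene_id] = cp
        truth.dup_mode[src.gene_id] = truth.dup_mode[cp.gene_id] = "PD"
        pd_pairs.append((src, cp))
    for _ in range(n_dsd):
        src = pool[k]; k += 1
        cp = _copy_gene(src, counters, rng_seq, truth)
        copies[cp.gene_id] = cp
        truth.dup_mode[src.gene_id] = truth.dup_mode[cp.gene_id] = "DSD"
        dsd_pairs.append((src, cp))
    for i in range(n_trd):
        src = plans[cross_run[i]["members"][sp1]]
        cp = _copy_gene(src, counters, rng_seq, truth)
        copies[cp.gene_id] = cp
        # the ancestral copy keeps outgroup synteny and classifies as DSD
        truth.dup_mode[src.gene_id] = "DSD"
        truth.dup_mode[cp.gene_id] = "TRD"
        trd_pairs.append((src, cp))

    # --- outgroup mirror of the cross-run region -------------------------
    outg = "outg"
    outg_plans: list[_GenePlan] = []
    outg_pairs: list[tuple[str, str]] = []
    for i, o in enumerate(cross_run):
        src = plans[o["members"][sp1]]
        gid = f"{outg}g{i + 1:03d}"
        cds = _mutate(src.cds, 3, 2, rng_seq)
        outg_plans.append(_GenePlan(gene_id=gid, species=outg, ogg_id=None, cds=cds, kind="outgroup"))
        outg_pairs.append((src.gene_id, gid))

    # --- layout ----------------------------------------------------------
    n_chrom = config.chromosomes_per_species
    if (n_wgd or n_dsd or n_trd) and n_chrom < 2:
        raise ValueError("WGD/DSD/TRD events need chromosomes_per_species >= 2")
    chroms: dict[tuple[str, int], _Chromosome] = {
        (sp, c): _Chromosome(config.genes_per_chromosome)
        for sp in species
        for c in range(n_chrom)
    }
    chroms[(outg, 0)] = _Chromosome(config.genes_per_chromosome)

    placed: set[str] = set()

    def run_plans(run, sp):
        return [plans[o["members"][sp]] for o in run]

    # planted cross-species block: same order on sp1 chr1 and sp2 chr1
    end1 = chroms[(sp1, 0)].place_run(_RUN_START, run_plans(cross_run, sp1))
    chroms[(sp2, 0)].place_run(_RUN_START, run_plans(cross_run, sp2))
    chroms[(outg, 0)].place_run(_RUN_START, outg_plans)
    placed |= {p.gene_id for p in run_plans(cross_run, sp1)}
    placed |= {p.gene_id for p in run_plans(cross_run, sp2)}
    truth.planted_blocks.append(
        {
            "kind": "cross",
            "species_a": sp1,
            "species_b": sp2,
            "chrom_a": f"{sp1}_chr1",
            "chrom_b": f"{sp2}_chr1",
            "anchors": [
                (cross_run[i]["members"][sp1], cross_run[i]["members"][sp2])
                for i in range(L)
            ],
        }
    )
    truth.planted_blocks.append(
        {
            "kind": "outgroup",
            "species_a": sp1,
            "species_b": outg,
            "chrom_a": f"{sp1}_chr1",
            "chrom_b": f"{outg}_chr1",
            "anchors": list(outg_pairs),
        }
    )

    # planted WGD blocks: sources after the cross run on chr1, copies on chr2
    start = end1 + _MAX_RANK_GAP + 2
    copy_start = _RUN_START
    for pairs in wgd_copy_runs:
        srcs = [s for s, _ in pairs]
        cps = [c for _, c in pairs]
        end1 = chroms[(sp1, 0)].place_run(start, srcs)
        chroms[(sp1, 1)].place_run(copy_start, cps)
        truth.planted_blocks.append(
            {
                "kind": "wgd",
                "species_a": sp1,
                "species_b": sp1,
                "chrom_a": f"{sp1}_chr1",
                "chrom_b": f"{sp1}_chr2",
                "anchors": [(s.gene_id, c.gene_id) for s, c in pairs],
            }
        )
        placed |= {p.gene_id for p in srcs + cps}
        start = end1 + _MAX_RANK_GAP + 2
        copy_start += L + _MAX_RANK_GAP + 2

    # tandem and proximal pairs: isolated anchors, spaced beyond the gap bound
    pos = chroms[(sp1, 0)].random_floor
    for src, cp in td_pairs:
        chroms[(sp1, 0)].place(pos, src)
        chroms[(sp1, 0)].place(pos + 1, cp)
        placed |= {src.gene_id, cp.gene_id}
        pos += _MAX_RANK_GAP + 3
    chroms[(sp1, 0)].random_floor = max(chroms[(sp1, 0)].random_floor, pos)
    pd_chrom = chroms[(sp1, 1 if n_chrom > 1 else 0)]
    pos = pd_chrom.random_floor
    for src, cp in pd_pairs:
        pd_chrom.place(pos, src)
        pd_chrom.place(pos + 3, cp)
        placed |= {src.gene_id, cp.gene_id}
        pos += _MAX_RANK_GAP + 5
    pd_chrom.random_floor = max(pd_chrom.random_floor, pos)

    # everything else is scattered at low density
    def place_random(sp: str, plan: _GenePlan) -> None:
        order = rng_place.permutation(n_chrom)
        for c in order:
            free = chroms[(sp, int(c))].free_random_slots()
            if free:
                slot = free[int(rng_place.integers(len(free)))]
                chroms[(sp, int(c))].place(slot, plan)
                return
        raise ValueError(
            f"no free slots left for {plan.gene_id}; increase genes_per_chromosome"
        )

    # dispersed/transposed sources stay on chr1; their copies go to chr2
    for src, _cp in dsd_pairs:
        free = chroms[(sp1, 0)].free_random_slots()
        chroms[(sp1, 0)].place(free[int(rng_place.integers(len(free)))], src)
        placed.add(src.gene_id)
    for _src, cp in dsd_pairs + trd_pairs:
        free = chroms[(sp1, 1)].free_random_slots()
        chroms[(sp1, 1)].place(free[int(rng_place.integers(len(free)))], cp)
        placed.add(cp.gene_id)

    for sp in species:
        for plan in sorted(
            (p for p in list(plans.values()) + list(copies.values())
             if p.species == sp and p.gene_id not in placed),
            key=lambda p: p.gene_id,
        ):
            place_random(sp, plan)
            placed.add(plan.gene_id)

    all_family = {**plans, **copies}
    for plan in all_family.values():
        plan.strand = "+" if rng_place.integers(2) == 0 else "-"
        plan.second_isoform = bool(rng_place.random() < 0.3)
    truth.family_roster = {
        sp: sorted(p.gene_id for p in all_family.values() if p.species == sp)
        for sp in species
    }
    truth.retained_transcript = {gid: f"{gid}.t1" for gid in all_family}

    # --- promoters --------------------------------------------------------
    for gid in sorted(all_family):
        plan = all_family[gid]
        seq, planted = _build_promoter(
            rng_prom, config.promoter_window, library, config.motif_plan
        )
        plan.promoter = seq
        plan.motif_positions = planted
        truth.planted_motif_positions[gid] = planted

    paths = _emit_files(
        config, outdir, library, oggs, all_family, outg_plans, outg_pairs,
        td_pairs + pd_pairs + dsd_pairs + trd_pairs,
        [p for run in wgd_copy_runs for p in run],
        chroms, truth,
        rng_dom, rng_hom, rng_expr, rng_qpcr, rng_aln,
    )
    return paths, truth


# ---------------------------------------------------------------------------
# file emission


def _split_exons(full_cds: str, rng, intron_range: tuple[int, int]) -> tuple[list[str], list[int]]:
    """Cut a CDS into exon pieces at codon boundaries with intron lengths."""
    n = len(full_cds)
    n_exons = int(rng.integers(1, 6))
    boundaries = list(range(3, n, 3))
    n_exons = min(n_exons, len(boundaries) + 1)
    cuts = sorted(rng.choice(boundaries, size=n_exons - 1, replace=False)) if n_exons > 1 else []
    pieces, prev = [], 0
    for c in cuts:
        pieces.append(full_cds[prev:c])
        prev = c
    pieces.append(full_cds[prev:])
    lo, hi = intron_range
    introns = [
        int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        for _ in range(len(pieces) - 1)
    ]
    return pieces, introns


def _assemble_gene(plan: _GenePlan, cursor: int, rng, config: SyntheticConfig):
    """Return (genomic_text, GeneModel-relative data) for one family gene.

    ``cursor`` is the 0-based chromosome offset where this gene's text will
    start. Plus strand layout: spacer, promoter, body; minus strand:
    spacer, reverse-complemented body, reverse-complemented promoter.
    """
    lo, hi = config.spacer_range
    spacer_len = int(rng.integers(lo, hi + 1))
    spacer = "".join(_BASES[i] for i in rng.integers(0, 4, size=spacer_len))
    full_cds = plan.cds + "TAA"
    pieces, introns = _split_exons(full_cds, rng, config.intron_length_range)
    body_parts, sense_exons = [], []
    off = 0
    for i, piece in enumerate(pieces):
        sense_exons.append((off + 1, off + len(piece)))
        body_parts.append(piece)
        off += len(piece)
        if i < len(introns):
            iseq = "".join(_BASES[j] for j in rng.integers(0, 4, size=introns[i]))
            body_parts.append(iseq)
            off += introns[i]
    body = "".join(body_parts)
    iso2_sense = sense_exons[:-1] if plan.second_isoform and len(sense_exons) > 1 else None

    if plan.strand == "+":
        text = spacer + plan.promoter + body
        body_start = cursor + len(spacer) + len(plan.promoter) + 1  # 1-based
        to_plus = lambda s, e: (body_start + s - 1, body_start + e - 1)
    else:
        text = spacer + revcomp(body) + revcomp(plan.promoter)
        body_start = cursor + len(spacer) + 1
        span = len(body)
        to_plus = lambda s, e: (body_start + span - e, body_start + span - s)

    exons = tuple(sorted(to_plus(s, e) for s, e in sense_exons))
    transcripts = [Transcript(f"{plan.gene_id}.t1", exons, exons)]
    if iso2_sense:
        exons2 = tuple(sorted(to_plus(s, e) for s, e in iso2_sense))
        transcripts.append(Transcript(f"{plan.gene_id}.t2", exons2, exons2))
    gene = GeneModel(
        gene_id=plan.gene_id,
        species=plan.species,
        chromosome="",  # filled by caller
        start=min(s for s, _ in exons),
        end=max(e for _, e in exons),
        strand=plan.strand,
        transcripts=tuple(sorted(transcripts, key=lambda t: t.transcript_id)),
    )
    return text, gene


def _filler_gene(sp: str, chrom_idx: int, slot: int, cursor: int, rng, n_codons: int = 9):
    spacer = "".join(_BASES[i] for i in rng.integers(0, 4, size=20))
    core = _random_cds(rng, n_codons)
    full = core + "TAA"
    start = cursor + len(spacer) + 1
    exons = ((start, start + len(full) - 1),)
    gid = f"{sp}x{chrom_idx + 1}_{slot + 1:03d}"
    gene = GeneModel(
        gene_id=gid,
        species=sp,
        chromosome="",
        start=start,
        end=exons[0][1],
        strand="+",
        transcripts=(Transcript(f"{gid}.t1", exons, exons),),
    )
    return spacer + full, gene, core


def _emit_files(
    config, outdir, library, oggs, all_family, outg_plans, outg_pairs,
    small_dup_pairs, wgd_pairs, chroms, truth,
    rng_dom, rng_hom, rng_expr, rng_qpcr, rng_aln,
):
    rng_genome = subseed(config.seed, "genome")
    species = config.species
    outg = "outg"
    paths: dict[str, Path] = {}

    genomes: dict[str, dict[str, str]] = {sp: {} for sp in species + [outg]}
    genes_by_sp: dict[str, list[GeneModel]] = {sp: [] for sp in species + [outg]}
    cds_by_sp: dict[str, dict[str, str]] = {sp: {} for sp in species + [outg]}
    prot_by_sp: dict[str, dict[str, str]] = {sp: {} for sp in species + [outg]}
    decoy_slots = {0: ("evalue", 120), 1: ("coverage", 120), 2: ("length", 90)}

    for (sp, ci) in sorted(chroms):
        chrom = chroms[(sp, ci)]
        chrom_name = f"{sp}_chr{ci + 1}"
        parts: list[str] = []
        cursor = 0
        for slot in range(chrom.n_slots):
            plan = chrom.slots.get(slot)
            if plan is not None:
                text, gene = _assemble_gene(plan, cursor, rng_genome, config)
                full_cds = plan.cds + "TAA"
                cds_by_sp[sp][gene.gene_id] = full_cds
                prot_by_sp[sp][gene.gene_id] = translate(plan.cds)
            elif sp != outg and ci == 0 and slot in decoy_slots:
                kind, n_codons = decoy_slots[slot]
                text, gene, core = _filler_gene(sp, ci, slot, cursor, rng_genome, n_codons)
                gene.gene_id = f"{sp}d{slot + 1}"
                gene.transcripts = (
                    Transcript(f"{gene.gene_id}.t1", gene.transcripts[0].exons,
                               gene.transcripts[0].cds),
                )
                cds_by_sp[sp][gene.gene_id] = core + "TAA"
                prot_by_sp[sp][gene.gene_id] = translate(core)
                truth.domain_decoys[gene.gene_id] = kind
            else:
                text, gene, core = _filler_gene(sp, ci, slot, cursor, rng_genome)
                cds_by_sp[sp][gene.gene_id] = core + "TAA"
                prot_by_sp[sp][gene.gene_id] = translate(core)
            gene.chromosome = chrom_name
            parts.append(text)
            cursor += len(text)
            genes_by_sp[sp].append(gene)
        genomes[sp][chrom_name] = "".join(parts)

    for sp in species + [outg]:
        paths[f"{sp}.genome"] = outdir / f"{sp}.genome.fa"
        write_fasta(genomes[sp], paths[f"{sp}.genome"])
        paths[f"{sp}.gff"] = outdir / f"{sp}.gff3"
        write_gff3(genes_by_sp[sp], paths[f"{sp}.gff"])
        paths[f"{sp}.cds"] = outdir / f"{sp}.cds.fa"
        write_fasta(dict(sorted(cds_by_sp[sp].items())), paths[f"{sp}.cds"])
        paths[f"{sp}.protein"] = outdir / f"{sp}.protein.fa"
        write_fasta(dict(sorted(prot_by_sp[sp].items())), paths[f"{sp}.protein"])

    # --- domain-hit tables (family hits pass; decoys violate one filter) --
    model, mlen = "PF00069", 265
    for sp in species:
        hits = []
        for gid in truth.family_roster[sp]:
            aa_len = len(prot_by_sp[sp][gid])
            ev = 10.0 ** -float(rng_dom.uniform(20, 60))
            hits.append(DomainHit(gid, model, ev, 1, mlen, 1, min(aa_len, mlen), mlen))
        for gid, kind in sorted(truth.domain_decoys.items()):
            if not gid.startswith(sp):
                continue
            aa_len = len(prot_by_sp[sp][gid])
            if kind == "evalue":
                hits.append(DomainHit(gid, model, 1e-5, 1, mlen, 1, aa_len, mlen))
            elif kind == "coverage":
                hits.append(DomainHit(gid, model, 1e-30, 1, mlen // 2, 1, aa_len, mlen))
            else:  # protein shorter than the length floor
                hits.append(DomainHit(gid, model, 1e-30, 1, mlen, 1, aa_len, mlen))
        hits.sort(key=lambda h: h.protein_id)
        paths[f"{sp}.domains"] = outdir / f"{sp}.domains.tsv"
        write_domain_table(hits, paths[f"{sp}.domains"])

    # --- homology table ---------------------------------------------------
    species_of = {g: sp for sp in species for g in truth.family_roster[sp]}
    by_ogg: dict[str, list[str]] = {}
    for g, ogg_id in sorted(truth.ogg_membership.items()):
        by_ogg.setdefault(ogg_id, []).append(g)
    rows = []
    for ogg_id in sorted(by_ogg):
        members = by_ogg[ogg_id]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if species_of[a] != species_of[b]:
                    rows.append(
                        {"gene_a": a, "gene_b": b,
                         "score": round(float(rng_hom.uniform(90, 100)), 2)}
                    )
    for src, cp in small_dup_pairs + wgd_pairs:
        rows.append(
            {"gene_a": src.gene_id, "gene_b": cp.gene_id,
             "score": round(float(rng_hom.uniform(90, 100)), 2)}
        )
    for a, b in outg_pairs:
        rows.append(
            {"gene_a": a, "gene_b": b,
             "score": round(float(rng_hom.uniform(90, 100)), 2)}
        )
    all_ids = sorted(species_of)
    ogg_species: dict[str, set] = {}
    for g, o in truth.ogg_membership.items():
        if g in species_of:
            ogg_species.setdefault(o, set()).add(species_of[g])
    for _ in range(config.n_oggs):
        for _try in range(50):
            a = all_ids[int(rng_hom.integers(len(all_ids)))]
            b = all_ids[int(rng_hom.integers(len(all_ids)))]
            # a decoy only ever competes against an existing true partner,
            # so the reciprocal best hit is never the decoy
            if (
                a != b
                and species_of[a] != species_of[b]
                and truth.ogg_membership[a] != truth.ogg_membership[b]
                and species_of[b] in ogg_species[truth.ogg_membership[a]]
                and species_of[a] in ogg_species[truth.ogg_membership[b]]
            ):
                rows.append(
                    {"gene_a": a, "gene_b": b,
                     "score": round(float(rng_hom.uniform(30, 60)), 2)}
                )
                break
    paths["homology"] = outdir / "homology.tsv"
    write_tsv(rows, paths["homology"], ["gene_a", "gene_b", "score"])

    # --- motif library copy ----------------------------------------------
    paths["motifs"] = outdir / "motifs.tsv"
    write_tsv(
        [
            {"element": m.name, "consensus": m.consensus,
             "functional_class": m.functional_class}
            for m in library
        ],
        paths["motifs"],
        ["element", "consensus", "functional_class"],
    )

    # --- expression counts with planted fold changes ----------------------
    sp1 = species[0]
    fc_cycle = [0.0, 1.5, 0.0, -1.5, 0.5, 2.0, -0.5, 0.0, 3.0, -2.0]
    sample_totals = {
        f"{condition}_r{rep}": int(1_000_000 * float(rng_expr.uniform(0.9, 1.1)))
        for condition in ("control", "drought")
        for rep in (1, 2, 3)
    }
    expr_rows = []
    for i, gid in enumerate(truth.family_roster[sp1]):
        fc = fc_cycle[i % len(fc_cycle)]
        truth.planted_log2fc[gid] = fc
        base = float(rng_expr.uniform(10, 100))
        length = len(cds_by_sp[sp1][gid])
        for condition, level in (("control", base), ("drought", base * 2.0 ** fc)):
            for rep in (1, 2, 3):
                sample = f"{condition}_r{rep}"
                total = sample_totals[sample]
                noisy = level * 2.0 ** float(rng_expr.normal(0, 0.05))
                count = max(0, round(noisy * length * total / 1e9))
                expr_rows.append(
                    {
                        "gene": gid,
                        "sample": sample,
                        "condition": condition,
                        "replicate": rep,
                        "count": count,
                        "length": length,
                        "total_mapped": total,
                    }
                )
    paths["expression"] = outdir / "expression.tsv"
    write_tsv(expr_rows, paths["expression"],
              ["gene", "sample", "condition", "replicate", "count", "length", "total_mapped"])

    # --- qPCR Ct table ----------------------------------------------------
    qpcr_rows = []
    peaks = [8.0, 16.0, 32.0, 64.0]
    for i, gid in enumerate(truth.family_roster[sp1][:4]):
        for c_idx, condition in enumerate(("drought", "salt", "alkali")):
            peak = peaks[(i + c_idx) % len(peaks)]
            for t in (0, 1, 3, 6, 12, 24):
                fold = 1.0 + (peak - 1.0) * (t / 24.0)
                for rep in (1, 2, 3):
                    ct_ref = 20.0 + float(rng_qpcr.normal(0, 0.05))
                    ct_t = ct_ref + 5.0 - math.log2(fold) + float(rng_qpcr.normal(0, 0.05))
                    qpcr_rows.append(
                        {
                            "gene": gid,
                            "condition": condition,
                            "timepoint": t,
                            "replicate": rep,
                            "ct_target": round(ct_t, 3),
                            "ct_reference": round(ct_ref, 3),
                        }
                    )
    paths["qpcr"] = outdir / "qpcr.tsv"
    write_tsv(qpcr_rows, paths["qpcr"],
              ["gene", "condition", "timepoint", "replicate", "ct_target", "ct_reference"])

    # --- subfamily signature alignments and reference panel ---------------
    sig_len = 120
    base = {}
    base["MEKK"] = "".join(_AA[i] for i in rng_aln.integers(0, len(_AA), size=sig_len))
    for fam in ("ZIK", "RAF"):
        chars = list(base["MEKK"])
        for j in range(sig_len):
            if rng_aln.random() < 0.5:
                chars[j] = _AA[int(rng_aln.integers(len(_AA)))]
        base[fam] = "".join(chars)

    def noisy(fam: str) -> str:
        chars = list(base[fam])
        for j in range(sig_len):
            if rng_aln.random() < 0.05:
                chars[j] = _AA[int(rng_aln.integers(len(_AA)))]
        return "".join(chars)

    panel_rows = []
    ref_seqs = {}
    ref_clusters = {"MEKK": (1, 2), "ZIK": (6, 7), "RAF": (8, 9)}
    for fam in ("MEKK", "ZIK", "RAF"):
        for k, cluster in enumerate(ref_clusters[fam], start=1):
            rid = f"ATref_{fam}{k}"
            ref_seqs[rid] = noisy(fam)
            panel_rows.append({"ref": rid, "subfamily": fam, "cluster": cluster})
    paths["panel"] = outdir / "refs.tsv"
    write_tsv(panel_rows, paths["panel"], ["ref", "subfamily", "cluster"])

    subfam_of_gene = {
        g: truth.ogg_subfamily[ogg_id] for g, ogg_id in truth.ogg_membership.items()
    }
    for sp in species:
        rows_aln = dict(ref_seqs)
        for gid in truth.family_roster[sp]:
            rows_aln[gid] = noisy(subfam_of_gene[gid])
        # plant sparse columns that the gap-threshold trim should drop
        gap_cols = sorted(int(c) for c in rng_aln.choice(sig_len, size=8, replace=False))
        names = list(rows_aln)
        for col in gap_cols:
            for name in names:
                if rng_aln.random() < 0.9:
                    s = rows_aln[name]
                    rows_aln[name] = s[:col] + "-" + s[col + 1 :]
        paths[f"{sp}.aln"] = outdir / f"{sp}.aln.fa"
        write_fasta(rows_aln, paths[f"{sp}.aln"])

    # --- truth tables ------------------------------------------------------
    t = outdir / "truth"
    t.mkdir(exist_ok=True)
    write_tsv(
        [{"gene": g, "ogg": o} for g, o in sorted(truth.ogg_membership.items())],
        t / "ogg_membership.tsv", ["gene", "ogg"],
    )
    write_tsv(
        [
            {"ogg": o, "category": truth.ogg_category[o],
             "subfamily": truth.ogg_subfamily[o], "cluster": truth.ogg_cluster[o]}
            for o in sorted(truth.ogg_category)
        ],
        t / "ogg_category.tsv", ["ogg", "category", "subfamily", "cluster"],
    )
    write_tsv(
        [{"gene": g, "mode": m} for g, m in sorted(truth.dup_mode.items())],
        t / "dup_mode.tsv", ["gene", "mode"],
    )
    block_rows = []
    for bi, blk in enumerate(truth.planted_blocks, start=1):
        for a, b in blk["anchors"]:
            block_rows.append(
                {"block": bi, "kind": blk["kind"], "species_a": blk["species_a"],
                 "species_b": blk["species_b"], "gene_a": a, "gene_b": b}
            )
    write_tsv(block_rows, t / "blocks.tsv",
              ["block", "kind", "species_a", "species_b", "gene_a", "gene_b"])
    write_tsv(
        [
            {"gene_a": a, "gene_b": b, "syn": s, "nonsyn": n}
            for (a, b), (s, n) in sorted(truth.planted_pair_counts.items())
        ],
        t / "pair_counts.tsv", ["gene_a", "gene_b", "syn", "nonsyn"],
    )
    write_tsv(
        [
            {"gene": g, "element": e, "position": p, "strand": s}
            for g in sorted(truth.planted_motif_positions)
            for (e, p, s) in truth.planted_motif_positions[g]
        ],
        t / "motifs.tsv", ["gene", "element", "position", "strand"],
    )
    write_tsv(
        [{"gene": g, "log2fc": fc} for g, fc in sorted(truth.planted_log2fc.items())],
        t / "log2fc.tsv", ["gene", "log2fc"],
    )
    write_tsv(
        [{"species": sp, "gene": g} for sp in species for g in truth.family_roster[sp]],
        t / "roster.tsv", ["species", "gene"],
    )
    write_tsv(
        [{"gene": g, "violation": v} for g, v in sorted(truth.domain_decoys.items())],
        t / "decoys.tsv", ["gene", "violation"],
    )
    paths["truth"] = t
    return paths
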