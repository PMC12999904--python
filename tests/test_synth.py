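import hashlib
from pathlib import Path

import pytest

from asterfam.io import read_fasta, read_gff3
from asterfam.kaks import CODON_TABLE, STOP_CODONS
from asterfam.synth import (
    SyntheticConfig,
    _category_counts,
    evolve_codon_pair,
    generate_dataset,
)


def codon_diff_oracle(a: str, b: str):
    """Independent recount: per-codon differences classified by translation."""
    syn = non = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca == cb:
            continue
        assert sum(x != y for x, y in zip(ca, cb)) == 1, "one substitution per codon"
        if CODON_TABLE[ca] == CODON_TABLE[cb]:
            syn += 1
        else:
            non += 1
    return syn, non


class TestEvolveCodonPair:
    def test_no_substitutions_identical(self):
        a, b = evolve_codon_pair(100, 0, 0, 3)
        assert a == b

    def test_five_synonymous(self):
        a, b = evolve_codon_pair(100, 5, 0, 3)
        assert codon_diff_oracle(a, b) == (5, 0)

    def test_ten_of_each(self):
        a, b = evolve_codon_pair(50, 10, 10, 3)
        assert codon_diff_oracle(a, b) == (10, 10)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_sequences_are_valid_cds(self, seed):
        for seq in evolve_codon_pair(80, 6, 4, seed):
            assert len(seq) % 3 == 0
            assert seq.startswith("ATG")
            assert all(
                seq[i : i + 3] not in STOP_CODONS for i in range(0, len(seq), 3)
            )

    def test_deterministic_per_seed(self):
        assert evolve_codon_pair(60, 3, 3, 5) == evolve_codon_pair(60, 3, 3, 5)

    def test_overfull_request_rejected(self):
        with pytest.raises(ValueError):
            evolve_codon_pair(10, 8, 8, 1)


class TestConfigValidation:
    def test_category_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="category_mix"):
            SyntheticConfig(category_mix=(0.5, 0.5, 0.5))

    def test_block_length_floor(self):
        with pytest.raises(ValueError, match="block_length"):
            SyntheticConfig(block_length=5)

    def test_rounded_category_mix(self):
        assert _category_counts(50, (0.3, 0.5, 0.2)) == (15, 25, 10)
        assert sum(_category_counts(7, (0.34, 0.33, 0.33))) == 7


def _digest_tree(root: Path) -> dict:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(root))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def test_equal_seeds_give_byte_identical_outputs(tmp_path):
    cfg = dict(
        n_species=3, n_oggs=24, genes_per_chromosome=120, block_length=10,
        dup_events={"TD": 1, "PD": 1, "DSD": 1, "TRD": 1},
        motif_plan={"MYC": 1}, promoter_window=300, seed=5,
    )
    generate_dataset(SyntheticConfig(**cfg), tmp_path / "a")
    generate_dataset(SyntheticConfig(**cfg), tmp_path / "b")
    assert _digest_tree(tmp_path / "a") == _digest_tree(tmp_path / "b")


class TestPlantedStructure:
    def test_presence_matches_categories(self, small_dataset):
        cfg, _outdir, truth = small_dataset
        present: dict[str, set] = {}
        for g, ogg in truth.ogg_membership.items():
            present.setdefault(ogg, set()).add(g[:4])
        for ogg, cat in truth.ogg_category.items():
            k = len(present[ogg])
            if cat == "conserved":
                assert k == cfg.n_species
            elif cat == "variable":
                assert k == cfg.n_species - 1
            else:
                assert 1 <= k <= cfg.n_species - 2

    def test_every_gene_in_exactly_one_ogg(self, small_dataset):
        _cfg, _outdir, truth = small_dataset
        roster = [g for genes in truth.family_roster.values() for g in genes]
        assert sorted(roster) == sorted(truth.ogg_membership)

    def test_emitted_cds_are_valid(self, small_dataset):
        cfg, outdir, truth = small_dataset
        for sp in cfg.species:
            seqs = read_fasta(outdir / f"{sp}.cds.fa")
            for gid in truth.family_roster[sp]:
                seq = seqs[gid]
                assert len(seq) % 3 == 0
                assert seq.startswith("ATG")
                body = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
                assert all(c not in STOP_CODONS for c in body)
                assert seq[-3:] in STOP_CODONS

    def test_tandem_pairs_are_rank_adjacent(self, small_dataset):
        cfg, outdir, truth = small_dataset
        sp1 = cfg.species[0]
        ranks = {g.gene_id: (g.chromosome, g.rank) for g in read_gff3(outdir / f"{sp1}.gff3")}
        td = sorted(g for g, m in truth.dup_mode.items() if m == "TD")
        assert len(td) == 2 * cfg.dup_events["TD"]
        by_chrom: dict[str, list[int]] = {}
        for g in td:
            chrom, rank = ranks[g]
            by_chrom.setdefault(chrom, []).append(rank)
        pairs = 0
        for chrom_ranks in by_chrom.values():
            chrom_ranks.sort()
            pairs += sum(
                1 for a, b in zip(chrom_ranks, chrom_ranks[1:]) if b - a == 1
            )
        assert pairs == cfg.dup_events["TD"]

    def test_planted_blocks_reference_generated_genes(self, small_dataset):
        _cfg, _outdir, truth = small_dataset
        known = set(truth.ogg_membership)
        for blk in truth.planted_blocks:
            for a, b in blk["anchors"]:
                assert a in known
                assert b in known or b.startswith("outg")
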