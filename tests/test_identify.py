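import pytest
from hypothesis import given, strategies as st

from asterfam.identify import (
    IdentificationConfig,
    filter_candidates,
    longest_isoform,
    rename_by_position,
)
from asterfam.models import DomainHit, GeneModel, Transcript


def hit(pid, evalue=1e-20, mfrom=1, mto=265, mlen=265):
    return DomainHit(pid, "PF00069", evalue, mfrom, mto, 1, 300, mlen)


class TestFilterCandidates:
    @pytest.mark.parametrize(
        "evalue,length,mto,included",
        [
            (1e-5, 300, 265, False),  # fails the E-value cutoff
            (1e-20, 90, 265, False),  # protein below the length floor
            (1e-20, 300, 265, True),  # all filters passed
            (1e-20, 300, 130, False),  # incomplete domain (coverage < 0.8)
            (1e-10, 100, 265, True),  # both boundaries inclusive
        ],
    )
    def test_filter_rules(self, evalue, length, mto, included):
        got = filter_candidates([hit("p1", evalue, 1, mto)], {"p1": length})
        assert ("p1" in got) == included

    def test_unknown_protein_is_a_hard_error(self):
        with pytest.raises(KeyError, match="mystery"):
            filter_candidates([hit("mystery")], {"other": 300})

    def test_best_hit_decides_with_multiple_hits(self):
        hits = [hit("p1", 1e-3, 1, 265), hit("p1", 1e-30, 1, 265)]
        assert filter_candidates(hits, {"p1": 300}) == {"p1"}

    @given(
        cutoffs=st.tuples(
            st.floats(min_value=1e-30, max_value=1e-5),
            st.floats(min_value=1e-30, max_value=1e-5),
        ),
        evalues=st.lists(st.floats(min_value=1e-40, max_value=1.0), min_size=1, max_size=20),
    )
    def test_relaxing_the_cutoff_is_monotone(self, cutoffs, evalues):
        lo, hi = sorted(cutoffs)
        hits = [hit(f"p{i}", e) for i, e in enumerate(evalues)]
        proteins = {f"p{i}": 300 for i in range(len(evalues))}
        strict = filter_candidates(hits, proteins, IdentificationConfig(evalue_cutoff=lo))
        relaxed = filter_candidates(hits, proteins, IdentificationConfig(evalue_cutoff=hi))
        assert strict <= relaxed


def gene(gid, chrom="chr1", start=100, transcripts=()):
    return GeneModel(
        gene_id=gid, species="sp", chromosome=chrom, start=start, end=start + 999,
        strand="+", transcripts=tuple(transcripts),
    )


def tx(tid, cds_len, start=100):
    return Transcript(tid, ((start, start + cds_len - 1),), ((start, start + cds_len - 1),))


class TestLongestIsoform:
    def test_keeps_longest_cds(self):
        g = gene("g1", transcripts=[tx("t1", 300), tx("t2", 500)])
        (out,) = longest_isoform([g])
        assert out.transcripts[0].transcript_id == "t2"

    def test_tie_broken_lexicographically(self):
        g = gene("g1", transcripts=[tx("t2", 400), tx("t10", 400)])
        (out,) = longest_isoform([g])
        assert out.transcripts[0].transcript_id == "t10"  # "t10" < "t2"

    def test_single_isoform_unchanged(self):
        g = gene("g1", transcripts=[tx("t1", 300)])
        (out,) = longest_isoform([g])
        assert out.transcripts == g.transcripts

    def test_no_transcripts_is_an_error(self):
        with pytest.raises(ValueError):
            longest_isoform([gene("g1")])


class TestRenameByPosition:
    def test_orders_by_chromosome_then_start(self):
        genes = [
            gene("a", "chr2", 50), gene("b", "chr1", 900), gene("c", "chr1", 100),
        ]
        out = rename_by_position(genes, "Hann_MAPKKK")
        assert [(g.gene_id, g.family_name) for g in out] == [
            ("c", "Hann_MAPKKK1"), ("b", "Hann_MAPKKK2"), ("a", "Hann_MAPKKK3"),
        ]

    def test_natural_chromosome_order(self):
        out = rename_by_position([gene("a", "chr10"), gene("b", "chr2")], "X")
        assert [g.gene_id for g in out] == ["b", "a"]

    def test_empty_input(self):
        assert rename_by_position([], "X") == []

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            rename_by_position([gene("a"), gene("a")], "X")

    def test_names_are_a_bijection_and_idempotent(self):
        genes = [gene(f"g{i}", "chr1", 10 * i + 1) for i in range(12)]
        out = rename_by_position(genes, "F")
        names = [g.family_name for g in out]
        assert len(set(names)) == len(genes)
        again = rename_by_position(out, "F")
        assert [g.family_name for g in again] == names


def test_roster_recovery_matches_planted_family(small_pipeline):
    """Identification recovers exactly the planted family, per species."""
    _cfg, results, truth = small_pipeline
    for sp, expected in truth.family_roster.items():
        got = sorted(g.gene_id for g in results["roster"][sp])
        assert got == expected


def test_decoys_are_the_only_rejected_hits(small_dataset):
    """Each planted violator fails exactly its planted filter."""
    from asterfam.io import read_domain_table, read_fasta

    cfg, outdir, truth = small_dataset
    for sp in cfg.species:
        hits = read_domain_table(outdir / f"{sp}.domains.tsv")
        proteins = {k: len(v) for k, v in read_fasta(outdir / f"{sp}.protein.fa").items()}
        accepted = filter_candidates(hits, proteins)
        rejected = {h.protein_id for h in hits} - accepted
        assert accepted == set(truth.family_roster[sp])
        assert rejected == {g for g in truth.domain_decoys if g.startswith(sp)}
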