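import math

import pytest
from hypothesis import given, strategies as st

from asterfam.kaks import (
    CODON_TABLE,
    STOP_CODONS,
    aggregate,
    backtranslate,
    jukes_cantor,
    ng86,
    synonymous_sites,
    translate,
)
from asterfam.models import KaKsPair
from asterfam.synth import evolve_codon_pair


class TestBacktranslate:
    def test_gap_threading(self):
        rows = backtranslate(("M-F", "MKF"), "ATGTTT", "ATGAAATTC")
        assert rows == ("ATG---TTT", "ATGAAATTC")

    def test_identity(self):
        rows = backtranslate(("MF", "MF"), "ATGTTT", "ATGTTC")
        assert rows == ("ATGTTT", "ATGTTC")

    def test_terminal_stop_dropped(self):
        rows = backtranslate(("MF", "MF"), "ATGTTTTAA", "ATGTTCTGA")
        assert rows == ("ATGTTT", "ATGTTC")

    def test_translation_mismatch_names_the_column(self):
        with pytest.raises(ValueError, match="column 2"):
            backtranslate(("MF", "MF"), "ATGAAA", "ATGTTC")


class TestNg86:
    def test_identical_sequences(self):
        p = ng86(("ATGGCTTTT", "ATGGCTTTT"))
        assert p.Ka == 0 and p.Ks == 0 and p.omega is None

    def test_single_synonymous_change_worked_example(self):
        # per-codon synonymous sites: ATG 0, GCT 1, TTT 1/3, GGG 1
        p = ng86(("ATGGCTTTTGGG", "ATGGCTTTCGGG"))
        assert p.S == pytest.approx(7 / 3)
        assert p.N == pytest.approx(29 / 3)
        assert (p.Sd, p.Nd) == (1.0, 0.0)
        assert p.Ks == pytest.approx(0.6355, abs=1e-4)
        assert p.Ka == 0.0
        assert p.omega == 0.0

    def test_jukes_cantor_closed_form(self):
        assert jukes_cantor(0.3) == pytest.approx(-0.75 * math.log(0.6), abs=1e-12)
        assert jukes_cantor(0.3) == pytest.approx(0.3831, abs=1e-4)
        assert jukes_cantor(0.75) is None

    def test_sites_sum_to_three_per_codon_column(self):
        a, b = evolve_codon_pair(60, 4, 6, 3)
        p = ng86((a, b))
        assert p.S + p.N == pytest.approx(3 * 60, abs=1e-9)

    def test_symmetric_in_the_two_sequences(self):
        a, b = evolve_codon_pair(80, 5, 5, 9)
        pab, pba = ng86((a, b)), ng86((b, a))
        assert pab.S == pytest.approx(pba.S)
        assert pab.Sd == pytest.approx(pba.Sd)
        assert pab.Ks == pytest.approx(pba.Ks)
        assert pab.Ka == pytest.approx(pba.Ka)

    @given(st.integers(0, 10))
    def test_ks_monotone_in_synonymous_substitutions(self, extra):
        a, b = evolve_codon_pair(120, 5 + extra, 3, 21)
        base_a, base_b = evolve_codon_pair(120, 5, 3, 21)
        assert ng86((a, b)).Ks >= ng86((base_a, base_b)).Ks - 1e-12

    def test_gapped_columns_excluded(self):
        p = ng86(("ATG---TTT", "ATGAAATTT"))
        assert p.S + p.N == pytest.approx(6.0)

    def test_all_gapped_rejected(self):
        with pytest.raises(ValueError):
            ng86(("---", "---"))

    def test_agrees_with_biopython_on_single_step_differences(self):
        """Cross-check against Bio.codonalign's NG86 on codons whose one-step
        neighbourhoods contain no stop codons (where conventions coincide)."""
        import warnings

        import numpy as np

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        safe = [
            c for c in CODON_TABLE
            if not any(
                c[:i] + b + c[i + 1 :] in STOP_CODONS
                for i in range(3)
                for b in "ACGT"
            )
        ]
        rng = np.random.default_rng(17)
        for _ in range(5):
            codons_a = [safe[i] for i in rng.integers(0, len(safe), size=40)]
            codons_b = list(codons_a)
            for pos in rng.choice(40, size=8, replace=False):
                codon = codons_a[pos]
                neighbours = [
                    alt
                    for i in range(3)
                    for b in "ACGT"
                    if b != codon[i]
                    if (alt := codon[:i] + b + codon[i + 1 :]) in safe
                ]
                codons_b[pos] = neighbours[int(rng.integers(len(neighbours)))]
            a, b = "".join(codons_a), "".join(codons_b)
            ours = ng86((a, b))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            assert ours.Ka == pytest.approx(dn, abs=1e-9)
            assert ours.Ks == pytest.approx(ds, abs=1e-9)


class TestAggregate:
    def _pair(self, a, b, omega):
        return KaKsPair(a, b, 100, 200, 1, 1, 0.01, 0.005,
                        Ks=0.1, Ka=0.1 * omega, omega=omega)

    def test_ogg_mean(self):
        pairs = [self._pair("a", "b", 0.1), self._pair("a", "c", 0.3)]
        ogg_rows, _ = aggregate(pairs, {"a": "O1", "b": "O1", "c": "O1"})
        assert ogg_rows[0]["mean_omega"] == pytest.approx(0.2)

    def test_cluster_mean_is_unweighted(self):
        pairs = [
            self._pair("a", "b", 0.2),
            self._pair("c", "d", 0.3), self._pair("c", "e", 0.5),
        ]
        ogg_of = {"a": "O1", "b": "O1", "c": "O2", "d": "O2", "e": "O2"}
        ogg_rows, cluster_rows = aggregate(pairs, ogg_of, {"O1": "C1", "O2": "C1"})
        assert {r["ogg_id"]: r["mean_omega"] for r in ogg_rows} == pytest.approx(
            {"O1": 0.2, "O2": 0.4}
        )
        assert cluster_rows[0]["mean_omega"] == pytest.approx(0.3)

    def test_all_undefined_ogg_omitted_with_warning(self):
        undef = KaKsPair("a", "b", 100, 200, 0, 0, 0, 0, Ks=0.0, Ka=0.0, omega=None)
        with pytest.warns(UserWarning, match="omitted"):
            ogg_rows, _ = aggregate([undef], {"a": "O1", "b": "O1"})
        assert ogg_rows == []

    def test_pair_spanning_two_oggs_rejected(self):
        with pytest.raises(ValueError):
            aggregate([self._pair("a", "b", 0.1)], {"a": "O1", "b": "O2"})


def test_planted_counts_recovered_in_pipeline(small_pipeline):
    """Within-orthogroup pairs recover the planted substitution integers."""
    _cfg, results, truth = small_pipeline
    pairs = {}
    for p in results["kaks_pairs"]:
        pairs[(p.gene_a, p.gene_b)] = p
        pairs[(p.gene_b, p.gene_a)] = p
    checked = 0
    for (a, b), (sd, nd) in truth.planted_pair_counts.items():
        p = pairs.get((a, b))
        if p is None:  # copies can land outside the RBH orthogroup
            continue
        assert p.Sd == pytest.approx(sd, abs=1e-9)
        assert p.Nd == pytest.approx(nd, abs=1e-9)
        checked += 1
    # pairs involving duplicate copies can fall outside the RBH orthogroup
    # and are then not computed; the bulk of planted pairs must be covered
    assert checked >= len(truth.planted_pair_counts) * 0.7
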