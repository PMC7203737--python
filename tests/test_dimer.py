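"""Dimer composition, bridging windows, deviations and COB tables."""

import numpy as np
import pytest

from admotif import (
    BackgroundModel,
    COBTable,
    DimerSpec,
    PPM,
    assemble_cob,
    bridging_window,
    build_dimer,
    deviation,
    expected_bridging,
    expected_dimer,
    orient_pair,
    reverse_complement,
    seq_probability,
)
from admotif.alphabet import revcomp
from admotif.dimer import slice_blocks

from conftest import all_seqs


class TestOrientPair:
    def test_ht_unchanged(self, rand_adm):
        t1, t2 = rand_adm(3, 0), rand_adm(3, 1)
        a, b = orient_pair(t1, t2, "HT")
        assert a == t1 and b == t2

    def test_tt_reverse_complements_first(self, rand_adm):
        t1, t2 = rand_adm(3, 0), rand_adm(3, 1)
        a, b = orient_pair(t1, t2, "TT")
        np.testing.assert_allclose(
            a.matrix16(), reverse_complement(t1).matrix16()
        )
        assert b == t2

    def test_hh_with_palindromic_second_equals_ht(self):
        # a palindromic order-zero motif: rc(theta2) == theta2
        pal = PPM(np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.7]])).to_adm()
        other = PPM(np.array([[0.4, 0.3, 0.2, 0.1], [0.25, 0.25, 0.25, 0.25]])).to_adm()
        hh = orient_pair(other, pal, "HH")
        ht = orient_pair(other, pal, "HT")
        np.testing.assert_allclose(hh[1].matrix16(), ht[1].matrix16(), atol=1e-12)


class TestExpectedDimer:
    @pytest.mark.parametrize("o", ["HT", "HH", "TT", "TH"])
    def test_factorizes_at_independent_spacing(self, rand_adm, o):
        t1, t2 = rand_adm(2, 5), rand_adm(2, 6)
        bg = BackgroundModel()
        ed = expected_dimer(t1, t2, o, 4, bg)
        a, b = orient_pair(t1, t2, o)
        assert ed.length == 8
        for s in all_seqs(4):  # spot the factorization on a sub-grid
            full = s[:2] + "AC" + s[2:] + "GT"  # arbitrary but exhaustive-ish
        total = 0.0
        for s in all_seqs(8):
            p = seq_probability(ed, s)
            expect = (
                seq_probability(a, s[:2]) * 0.25**4 * seq_probability(b, s[6:])
            )
            assert p == pytest.approx(expect, abs=1e-12)
            total += p
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_gap_uses_second_initial_at_junction(self, rand_adm):
        t1, t2 = rand_adm(3, 2), rand_adm(3, 3)
        ed = expected_dimer(t1, t2, "HT", 0)
        np.testing.assert_allclose(ed.trans[2], np.tile(t2.initial, (4, 1)))

    def test_overlap_column_is_marginal_product(self):
        c1 = np.array([[0.25, 0.25, 0.25, 0.25], [1.0, 0.0, 0.0, 0.0]])
        c2 = np.array([[0.5, 0.5, 0.0, 0.0], [0.25, 0.25, 0.25, 0.25]])
        ed = expected_dimer(PPM(c1).to_adm(), PPM(c2).to_adm(), "HT", -1)
        assert ed.length == 3
        # shared column: (1,0,0,0) * (0.5,0.5,0,0) renormalized -> (1,0,0,0)
        np.testing.assert_allclose(ed.trans[0], np.tile([1.0, 0, 0, 0], (4, 1)))

    def test_overlap_as_long_as_monomer_rejected(self, rand_adm):
        with pytest.raises(ValueError, match="overlap"):
            expected_dimer(rand_adm(3, 0), rand_adm(3, 1), "HT", -3)

    def test_strand_coherence(self, rand_adm):
        """Scoring on the minus strand equals scoring the reverse
        complement against the reverse-complemented dimer."""
        tau = expected_dimer(rand_adm(2, 8), rand_adm(2, 9), "HH", -1)
        rc = reverse_complement(tau)
        for s in all_seqs(tau.length):
            assert seq_probability(rc, s) == pytest.approx(
                seq_probability(tau, revcomp(s)), abs=1e-12
            )


class TestBridging:
    def test_window_geometry(self):
        # gap d >= 0: d columns plus one flank column each side
        assert bridging_window(9, 2) == (8, 4)
        # overlap: |d| columns plus one flank column each side
        assert bridging_window(9, -2) == (6, 4)

    def test_independent_spacing_equals_expected(self, rand_adm):
        t1, t2 = rand_adm(3, 1), rand_adm(3, 2)
        spec = DimerSpec(0, 1, "HT", 4)
        built = build_dimer(t1, t2, spec, None, delta=4)
        np.testing.assert_allclose(
            built.adm.matrix16(), expected_dimer(t1, t2, "HT", 4).matrix16()
        )

    def test_close_spacing_window_width(self, rand_adm):
        t1, t2 = rand_adm(4, 1), rand_adm(4, 2)
        spec = DimerSpec(0, 1, "HT", -2)
        psi = expected_bridging(t1, t2, "HT", -2)
        assert psi.shape == (4, 4, 4)
        built = build_dimer(t1, t2, spec, psi, delta=4)
        assert built.adm.length == 4 + 4 - 2

    def test_expected_psi_gives_zero_deviation(self, rand_adm):
        t1, t2 = rand_adm(4, 3), rand_adm(4, 4)
        psi = expected_bridging(t1, t2, "HH", 2)
        kappa = deviation(psi, psi)
        np.testing.assert_allclose(kappa, 0.0)

    def test_psi_width_mismatch_rejected(self, rand_adm):
        t1, t2 = rand_adm(4, 3), rand_adm(4, 4)
        with pytest.raises(ValueError, match="shape"):
            build_dimer(t1, t2, DimerSpec(0, 1, "HT", 2), np.full((3, 4, 4), 0.25), 4)

    def test_psi_replaces_expected_middle(self, rand_adm):
        t1, t2 = rand_adm(4, 5), rand_adm(4, 6)
        spec = DimerSpec(0, 1, "TT", 1)
        psi = np.full((3, 4, 4), 0.25)
        built = build_dimer(t1, t2, spec, psi, delta=4)
        start, width = bridging_window(4, 1)
        got = slice_blocks(built.adm, start, width)
        np.testing.assert_allclose(got, psi)


class TestDeviation:
    def test_hand_subtraction(self):
        psi = np.tile([0.7, 0.1, 0.1, 0.1], (1, 4, 1)).reshape(1, 4, 4)
        exp = np.full((1, 4, 4), 0.25)
        kappa = deviation(psi, exp)
        np.testing.assert_allclose(kappa[0, 0], [0.45, -0.15, -0.15, -0.15])

    def test_conditional_blocks_sum_to_zero(self, rand_adm):
        t1, t2 = rand_adm(4, 7), rand_adm(4, 8)
        exp = expected_bridging(t1, t2, "HH", -1)
        rng = np.random.default_rng(0)
        psi = rng.dirichlet(np.ones(4), size=(3, 4))
        kappa = deviation(psi, exp)
        np.testing.assert_allclose(kappa.sum(axis=2), 0.0, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            deviation(np.full((2, 4, 4), 0.25), np.full((3, 4, 4), 0.25))


class TestCOBTable:
    def test_empty_when_all_pruned(self):
        specs = {DimerSpec(0, 0, "HT", d) for d in range(3)}
        cob = assemble_cob({}, (0, 0), pruned=specs, dmin=0, dmax=2)
        assert cob.to_frame().isna().all().all()
        assert cob.pruned == {("HT", d) for d in range(3)}

    def test_homodimer_has_no_th_row(self):
        cob = COBTable((0, 0), -2, 4)
        assert "TH" not in cob.to_frame().index
        hetero = COBTable((0, 1), -2, 4)
        assert "TH" in hetero.to_frame().index

    def test_display_units_round_half_up(self):
        cob = COBTable((0, 0), 0, 1, values={("HT", 0): 0.0614, ("HH", 1): 0.0615})
        disp = cob.display_frame()
        assert disp.loc["HT", 0] == "61"
        assert disp.loc["HH", 1] == "62"  # exact half rounds up

    def test_homodimer_th_spec_rejected(self):
        with pytest.raises(ValueError, match="homodimer"):
            DimerSpec(1, 1, "TH", 2)
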