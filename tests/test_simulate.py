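"""The ZOOPS read generator and the reference fixtures."""

import numpy as np
import pytest

from admotif import (
    BackgroundModel,
    MixtureModel,
    SimulationSpec,
    build_sanity_model,
    consensus,
    expected_bridging,
    generate_reads,
    hoxb13_standin,
    sanity_dimer_profile,
    seed_to_adm,
    two_motif_fixture,
)
from admotif.alphabet import encode_reads, revcomp
from admotif.simulate import example_bridging_deviation


class TestGenerateReads:
    def test_background_only_base_frequencies(self):
        model = MixtureModel(background=BackgroundModel(), monomers=[], pairs={})
        n, L = 20_000, 40
        reads, truth = generate_reads(SimulationSpec(model, n, L, seed=0))
        assert (truth["component"] == "background").all()
        enc = encode_reads(reads)
        freq = np.bincount(enc.ravel(), minlength=4)[:4] / (n * L)
        sigma = np.sqrt(0.25 * 0.75 / (n * L))
        assert np.all(np.abs(freq - 0.25) < 3 * sigma + 1e-12)

    def test_deterministic_monomer_lands_at_logged_positions(self):
        mono = seed_to_adm("TTAACC", match_weight=1.0)
        model = MixtureModel(
            background=BackgroundModel(),
            monomers=[mono],
            pairs={},
            lam_bg=0.0,
            lam_mono=np.array([1.0]),
        )
        reads, truth = generate_reads(SimulationSpec(model, 50, 20, seed=1))
        for r, row in zip(reads, truth.itertuples()):
            site = r[row.start : row.start + 6]
            assert site == ("TTAACC" if row.strand == "+" else revcomp("TTAACC"))

    def test_same_seed_reproduces_reads(self):
        model = two_motif_fixture(0.2)
        r1, t1 = generate_reads(SimulationSpec(model, 500, 30, seed=7))
        r2, t2 = generate_reads(SimulationSpec(model, 500, 30, seed=7))
        r3, _ = generate_reads(SimulationSpec(model, 500, 30, seed=8))
        assert r1 == r2 and t1.equals(t2)
        assert r1 != r3

    def test_motif_read_fraction_binomially_consistent(self):
        model = two_motif_fixture(0.45)
        n = 20_000
        reads, truth = generate_reads(SimulationSpec(model, n, 30, seed=3))
        frac = (truth["component"] != "background").mean()
        sigma = np.sqrt(0.9 * 0.1 / n)
        assert abs(frac - 0.90) < 3 * sigma

    def test_placement_dinucleotides_match_generating_chain(self):
        """Empirical dinucleotide frequencies at ground-truth placements
        converge to the generating ADM entries."""
        mono = seed_to_adm("TGACGTCA", 0.9)
        model = MixtureModel(
            background=BackgroundModel(),
            monomers=[mono],
            pairs={},
            lam_bg=0.2,
            lam_mono=np.array([0.8]),
        )
        n = 125_000
        reads, truth = generate_reads(SimulationSpec(model, n, 12, seed=5))
        enc = encode_reads(reads)
        hits = truth[truth["component"] != "background"]
        assert len(hits) > 99_000
        counts = np.zeros((7, 4, 4))
        init = np.zeros(4)
        for start, strand, row in zip(
            hits["start"], hits["strand"], enc[hits["read"].to_numpy()]
        ):
            win = row[start : start + 8]
            if strand == "-":
                win = (3 - win)[::-1]
            init[win[0]] += 1
            for h in range(1, 8):
                counts[h - 1, win[h - 1], win[h]] += 1
        est_init = init / init.sum()
        assert np.max(np.abs(est_init - mono.initial)) < 0.02
        rows = counts.sum(axis=2, keepdims=True)
        cond = np.divide(counts, rows, out=np.full_like(counts, 0.25), where=rows > 50)
        mask = (rows > 50).repeat(4, axis=2)
        assert np.max(np.abs(cond - mono.trans)[mask]) < 0.02

    def test_component_longer_than_read_rejected(self):
        model = two_motif_fixture(0.1)
        with pytest.raises(ValueError, match="exceeds read length"):
            generate_reads(SimulationSpec(model, 10, 6, seed=0))


class TestSanityModel:
    def test_reference_profile_weights(self):
        model = build_sanity_model(hoxb13_standin())
        assert model.lam_bg == pytest.approx(0.70)
        lam = {(s.o, s.d): v for s, v in model.lam_dimer.items()}
        assert lam == pytest.approx(
            {
                ("HT", 4): 0.061,
                ("HH", 4): 0.055,
                ("HH", 2): 0.068,
                ("TT", 2): 0.034,
                ("HH", 5): 0.082,
            }
        )

    @pytest.mark.parametrize("frac", [0.03, 0.90])
    def test_signal_fraction_rescaling(self, frac):
        model = build_sanity_model(hoxb13_standin(), total_signal=frac)
        assert model.total_signal() == pytest.approx(frac)
        assert model.lam_bg == pytest.approx(1 - frac)
        # relative shape of the weight profile is preserved
        profile = {(o, d): w for o, d, w in sanity_dimer_profile()}
        ratios = [
            model.lam_dimer[s] / profile[(s.o, s.d)] for s in model.lam_dimer
        ]
        np.testing.assert_allclose(ratios, frac / 0.30)

    def test_no_deviation_means_zero_kappa(self):
        model = build_sanity_model(hoxb13_standin())
        for spec in model.psi:
            np.testing.assert_allclose(model.deviation(spec), 0.0, atol=1e-12)

    def test_deviation_round_trip(self):
        mono = hoxb13_standin()
        kappa = example_bridging_deviation(4)
        model = build_sanity_model(mono, deviations={("HH", 2): kappa})
        from admotif.dimer import DimerSpec

        spec = DimerSpec(0, 0, "HH", 2)
        np.testing.assert_allclose(model.deviation(spec), kappa, atol=1e-12)
        back = model.psi[spec] - kappa
        np.testing.assert_allclose(
            back, expected_bridging(mono, mono, "HH", 2), atol=1e-12
        )

    def test_out_of_range_deviation_rejected(self):
        kappa = np.zeros((4, 4, 4))
        kappa[1] = np.tile([0.95, -0.95 / 3, -0.95 / 3, -0.95 / 3], (4, 1))
        with pytest.raises(ValueError, match="outside"):
            build_sanity_model(hoxb13_standin(), deviations={("HH", 2): kappa})

    def test_deviation_on_independent_cell_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            build_sanity_model(
                hoxb13_standin(),
                deviations={("HT", 4): example_bridging_deviation(6)},
            )

    def test_standin_is_first_order(self):
        """The stand-in monomer has genuine adjacent dependence (its
        conditionals differ across predecessors), unlike a plain PPM."""
        mono = hoxb13_standin()
        spread = np.max(mono.trans.max(axis=1) - mono.trans.min(axis=1))
        assert spread > 0.3
        assert consensus(mono).endswith("TAAAA")


class TestTwoMotifFixture:
    def test_background_weight(self):
        model = two_motif_fixture(0.45)
        assert model.lam_bg == pytest.approx(0.10)

    def test_consensus_sequences_are_close(self):
        model = two_motif_fixture(0.05)
        c1, c2 = (consensus(m) for m in model.monomers)
        dist = sum(a != b for a, b in zip(c1, c2))
        assert 1 <= dist <= 4

    def test_low_fraction_regime(self):
        model = two_motif_fixture(0.005)
        assert model.lam_bg == pytest.approx(0.99)
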