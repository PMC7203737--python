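"""The ZOOPS EM learner: likelihood, posteriors, updates, restriction,
pruning and the full driver."""

import numpy as np
import pytest

from admotif import (
    BackgroundModel,
    DimerSpec,
    MixtureModel,
    SimulationSpec,
    TrainingConfig,
    build_sanity_model,
    e_step,
    generate_reads,
    hamming_filter,
    log_likelihood,
    m_step,
    model_distance,
    prune_weak_dimers,
    run_em,
    seed_to_adm,
)
from admotif.em import ReadData

from conftest import brute_force_zoops_ll


def single_monomer_model(seed="TAATTA", lam=0.6, match=0.9):
    mono = seed_to_adm(seed, match)
    return MixtureModel(
        background=BackgroundModel(),
        monomers=[mono],
        pairs={},
        lam_bg=1.0 - lam,
        lam_mono=np.array([lam]),
    )


class TestLogLikelihood:
    def test_pure_background(self):
        model = MixtureModel(background=BackgroundModel(), monomers=[], pairs={})
        reads = ["ACGTACGTAC"] * 7
        assert log_likelihood(model, reads) == pytest.approx(
            7 * 10 * np.log(0.25)
        )

    def test_matches_enumeration_oracle(self, rng):
        model = single_monomer_model("TAA", lam=0.5, match=0.8)
        reads = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(3)]
        assert log_likelihood(model, reads) == pytest.approx(
            brute_force_zoops_ll(model, reads), abs=1e-9
        )

    def test_matches_oracle_with_dimers(self, rng):
        mono = seed_to_adm("TAA", 0.85)
        model = MixtureModel.initialize(
            [mono], pairs={(0, 0): (-1, 2)}, delta=2, lam_bg=0.4
        )
        reads = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(5)]
        assert log_likelihood(model, reads) == pytest.approx(
            brute_force_zoops_ll(model, reads), abs=1e-8
        )

    def test_component_longer_than_reads_rejected(self):
        model = single_monomer_model("TAATTAATTAAT")
        with pytest.raises(ValueError, match="length"):
            log_likelihood(model, ["ACGTACGT"])


class TestEStep:
    def test_background_only_when_lam_bg_is_one(self):
        model = MixtureModel(
            background=BackgroundModel(),
            monomers=[seed_to_adm("TAAT")],
            pairs={},
            lam_bg=1.0,
            lam_mono=np.array([0.0]),
        )
        post = e_step(model, ["ACGTTAATCG"] * 4)
        np.testing.assert_allclose(post.bg_mass, 1.0)
        pp, pm = post.resp[("mono", 0)]
        np.testing.assert_allclose(pp, 0.0)

    def test_high_contrast_site_takes_the_mass(self):
        model = single_monomer_model("GGGCCCGG", lam=0.5, match=0.97)
        read = "ATATATGGGCCCGGATATAT"
        post = e_step(model, [read])
        pp, pm = post.resp[("mono", 0)]
        assert pp[0, 6] > 0.99

    def test_palindromic_site_strand_symmetry(self):
        model = single_monomer_model("CACGTG", lam=0.5, match=0.95)
        post = e_step(model, ["ATCACGTGATAT"])
        pp, pm = post.resp[("mono", 0)]
        np.testing.assert_allclose(pp, pm, atol=1e-12)

    def test_per_read_masses_sum_to_one(self, rng):
        model = single_monomer_model()
        reads = ["".join(rng.choice(list("ACGT"), 15)) for _ in range(20)]
        post = e_step(model, reads)
        np.testing.assert_allclose(post.read_totals(), 1.0, atol=1e-9)


class TestMStep:
    def test_recovers_generating_monomer(self):
        gen = single_monomer_model("TGACGTCA", lam=0.6, match=0.9)
        reads, _ = generate_reads(SimulationSpec(gen, 50_000, 30, seed=4))
        post = e_step(gen, reads)
        new = m_step(post, TrainingConfig(pseudocount=0.01))
        err = np.max(
            np.abs(new.monomers[0].matrix16() - gen.monomers[0].matrix16())
        )
        assert err < 0.02

    def test_all_background_posterior_gives_lam_bg_one(self):
        model = MixtureModel(
            background=BackgroundModel(),
            monomers=[seed_to_adm("TAAT")],
            pairs={},
            lam_bg=1.0,
            lam_mono=np.array([0.0]),
        )
        post = e_step(model, ["ACGTACGTAC"] * 5)
        with pytest.warns(RuntimeWarning, match="no posterior mass"):
            new = m_step(post)
        assert new.lam_bg == pytest.approx(1.0)

    def test_close_dimers_contribute_no_monomer_counts(self):
        mono = seed_to_adm("TAATC", 0.9)
        gen = build_sanity_model(
            mono, dimers=[("HT", 2, 0.5)], delta=4, spacing=(0, 5)
        )
        reads, _ = generate_reads(SimulationSpec(gen, 300, 30, seed=1))
        learner = MixtureModel.initialize(
            [mono], pairs={(0, 0): (0, 5)}, delta=4, lam_bg=0.5
        )
        post = e_step(learner, reads)
        logbook: dict = {}
        m_step(post, monomer_count_log=logbook)
        close = {
            src
            for (src, _k) in logbook
            if isinstance(src, DimerSpec) and src.d < learner.delta
        }
        assert close == set()
        far = {
            src
            for (src, _k) in logbook
            if isinstance(src, DimerSpec) and src.d >= learner.delta
        }
        assert far  # far dimers do feed the monomer update

    def test_lambda_conservation(self, rng):
        model = single_monomer_model()
        reads = ["".join(rng.choice(list("ACGT"), 15)) for _ in range(50)]
        new = m_step(e_step(model, reads))
        total = new.lam_bg + new.lam_mono.sum() + sum(new.lam_dimer.values())
        assert total == pytest.approx(1.0, abs=1e-9)


class TestHammingFilter:
    def test_infinite_radius_is_noop(self, rng):
        model = single_monomer_model()
        post = e_step(model, ["".join(rng.choice(list("ACGT"), 15))])
        assert hamming_filter(post, None) is post

    def test_radius_zero_keeps_only_exact_consensus(self):
        model = single_monomer_model("GGGCCC", lam=0.5, match=0.9)
        read = "ATGGGCCCATGGGCCGAT"  # exact site at 2, 1-mismatch site at 10
        post = e_step(model, [read])
        filt = hamming_filter(post, 0)
        pp, pm = filt.resp[("mono", 0)]
        assert pp[0, 2] > 0
        assert pp[0, 10] == 0.0
        np.testing.assert_allclose(filt.read_totals(), 1.0, atol=1e-9)

    def test_unsurvived_reads_become_background_only(self):
        model = single_monomer_model("GGGGGG", lam=0.99, match=0.99)
        post = e_step(model, ["ATATATATATAT"])
        filt = hamming_filter(post, 0)
        assert filt.bg_mass[0] == pytest.approx(1.0)

    def test_excludes_nearby_decoy_motif_sites(self):
        """With two close consensus sequences, each motif's surviving
        placements exclude the other's exact sites beyond the radius."""
        a, b = "GGGGGGGG", "GGGGGTTT"  # Hamming distance 3
        model = MixtureModel(
            background=BackgroundModel(),
            monomers=[seed_to_adm(a, 0.95), seed_to_adm(b, 0.95)],
            pairs={},
            lam_bg=0.4,
            lam_mono=np.array([0.3, 0.3]),
        )
        read = "AT" + a + "AT" + b + "AT"
        post = e_step(model, [read])
        filt = hamming_filter(post, 2)
        pa = filt.resp[("mono", 0)][0]
        pb = filt.resp[("mono", 1)][0]
        assert pa[0, 2] > 0 and pb[0, 12] > 0
        assert pa[0, 12] == 0.0 and pb[0, 2] == 0.0


class TestPruning:
    def test_no_change_above_threshold(self):
        m = MixtureModel.initialize(
            [seed_to_adm("TAATC")], pairs=[(0, 0)], lam_bg=0.5
        )
        out = prune_weak_dimers(m, 1e-6)
        assert set(out.lam_dimer) == set(m.lam_dimer)

    def test_zero_weight_dimer_removed_monomers_kept(self):
        m = MixtureModel.initialize(
            [seed_to_adm("TAATC")], pairs=[(0, 0)], lam_bg=0.5
        )
        spec = m.dimer_specs()[0]
        freed = m.lam_dimer[spec]
        m.lam_dimer[spec] = 0.0
        m.lam_bg += freed
        out = prune_weak_dimers(m, 1e-4)
        assert spec not in out.lam_dimer and spec in out.pruned
        assert out.p == 1  # monomers never pruned
        out.validate()


class TestRunEM:
    def test_monotone_log_likelihood_without_heuristics(self):
        """Exact EM (rho infinite, pruning off): the likelihood trace is
        non-decreasing on random monomeric-mode fixtures."""
        for seed in range(5):
            gen = single_monomer_model("TGACGT", lam=0.4, match=0.85)
            reads, _ = generate_reads(SimulationSpec(gen, 250, 24, seed=seed))
            cfg = TrainingConfig(
                pairs=[], rho=None, pruning=False, maxiter=50, epsilon=0.0
            )
            res = run_em(reads, ["TGANGT"], cfg)
            diffs = np.diff(res.ll_trace)
            assert np.all(diffs >= -1e-7), f"seed {seed}: min diff {diffs.min()}"

    def test_fixed_point_converges_immediately(self):
        """Data sampled from (essentially) the initialization model is a
        near fixed point: convergence within the first few iterations."""
        init = MixtureModel(
            background=BackgroundModel(),
            monomers=[seed_to_adm("TGACGTCA", 0.8)],
            pairs={},
            lam_bg=0.5,
            lam_mono=np.array([0.5]),
        )
        reads, _ = generate_reads(SimulationSpec(init, 20_000, 30, seed=9))
        cfg = TrainingConfig(pairs=[], rho=None, maxiter=10, epsilon=0.01)
        res = run_em(reads, ["TGACGTCA"], cfg)
        assert res.converged and res.n_iter <= 3

    def test_noise_only_data_is_handled(self, rng):
        reads = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(400)]
        cfg = TrainingConfig(pairs=[], rho=3, maxiter=10)
        res = run_em(reads, ["TGACGTCA"], cfg)
        # the motif either collapses or stays weak; never crashes
        assert res.model.lam_mono[0] < 0.5
        res.model.validate()

    def test_deterministic_given_inputs(self):
        gen = single_monomer_model("TGACGTCA", lam=0.3)
        reads, _ = generate_reads(SimulationSpec(gen, 2000, 30, seed=5))
        cfg = TrainingConfig(pairs=[], rho=3, maxiter=5)
        r1 = run_em(reads, ["TGACGTCA"], cfg)
        r2 = run_em(reads, ["TGACGTCA"], cfg)
        assert np.array_equal(r1.model.lam_mono, r2.model.lam_mono)
        assert np.array_equal(
            r1.model.monomers[0].matrix16(), r2.model.monomers[0].matrix16()
        )
        assert r1.ll_trace == r2.ll_trace

    def test_seed_longer_than_reads_rejected(self):
        with pytest.raises(ValueError, match="length"):
            run_em(["ACGTAC"] * 3, ["ACGTACGTAC"], TrainingConfig(pairs=[]))


class TestReadData:
    def test_n_excludes_placements(self):
        data = ReadData(["ACGTNACGT"])
        # width-3 windows touching the N are inadmissible
        assert data.nvalid(3)[0] == 4

    def test_mixed_lengths_are_padded(self):
        data = ReadData(["ACGT", "ACGTACGT"])
        assert data.enc.shape == (2, 8)
        assert data.nvalid(4).tolist() == [1, 5]

    def test_flanks_excluded_from_core(self):
        data = ReadData(["ACGT"], flank_left="GG", flank_right="T")
        assert data.L == 7
        np.testing.assert_allclose(
            data.core[0], [0, 0, 1, 1, 1, 1, 0]
        )
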