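"""Generator/discriminator primitives against loop oracles; training contracts."""

import numpy as np
import pytest

from fcnets.autodiff import Tensor
from fcnets.gan import (GANConfig, DiscriminatorParams, GeneratorParams,
                        discriminator_forward, e2e_forward, e2n_forward,
                        generate_samples, generator_forward, n2g_forward,
                        train_brainnetcnn, train_gan)

from conftest import null_cohort


def small_cohort(seed=0, n_per_class=(8, 8), n_regions=8):
    return null_cohort(seed=seed, n_per_class=n_per_class, n_regions=n_regions,
                       n_timepoints=60)


def make_generator(n_regions=4, cfg=None, zero=False, seed=0):
    cfg = cfg or GANConfig()
    rng = np.random.default_rng(seed)
    gp = GeneratorParams(n_regions, cfg, n_classes=2, phen_len=3, rng=rng)
    if zero:
        for p in gp.parameters():
            p.data[...] = 0.0
    return gp


class TestGenerator:
    def latent(self, gp):
        rng = np.random.default_rng(1)
        noise = rng.uniform(-1, 1, size=gp.cfg.latent_total - 5)
        condition = rng.uniform(0, 1, size=5)
        return noise, condition

    def test_zero_embedding_gives_zero_matrix(self):
        gp = make_generator(zero=True)
        out = generator_forward(gp, *self.latent(gp))
        np.testing.assert_allclose(out, 0.0)

    def test_identity_embedding_gives_tanh_identity(self):
        cfg = GANConfig(embed_dim=2)
        gp = make_generator(n_regions=2, cfg=cfg, zero=True)
        gp.b2.data[...] = np.eye(2).ravel()  # X = I regardless of latent
        out = generator_forward(gp, *self.latent(gp))
        np.testing.assert_allclose(out, np.tanh(np.eye(2)), atol=1e-12)

    def test_output_exactly_symmetric_in_range(self):
        for seed in range(5):
            gp = make_generator(n_regions=6, seed=seed)
            out = generator_forward(gp, *self.latent(gp))
            assert np.array_equal(out, out.T)
            assert np.all(np.abs(out) < 1.0)

    def test_latent_length_mismatch_rejected(self):
        gp = make_generator()
        with pytest.raises(ValueError, match="latent"):
            generator_forward(gp, np.zeros(10), np.zeros(5))


class TestBrainNetCNNPrimitives:
    def test_e2e_all_ones_hand_example(self):
        M = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = e2e_forward(M, np.ones(2), np.ones(2), 0.0)
        np.testing.assert_allclose(out, np.full((2, 2), 2.0))

    def test_e2e_indicator_collapses_sum(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(4, 4))
        e1 = np.zeros(4)
        e1[1] = 1.0
        out = e2e_forward(M, e1, np.zeros(4), 0.0)
        for j in range(4):
            np.testing.assert_allclose(out[:, j], M[:, 1])

    def test_e2e_zero_input_gives_bias(self):
        out = e2e_forward(np.zeros((3, 3)), np.ones(3), np.ones(3), 0.7)
        np.testing.assert_allclose(out, 0.7)

    def test_e2n_row_sums_and_indicator(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(5, 5))
        np.testing.assert_allclose(e2n_forward(M, np.ones(5)), M.sum(axis=1))
        e2 = np.zeros(5)
        e2[2] = 1.0
        np.testing.assert_allclose(e2n_forward(M, e2), M[:, 2])

    def test_n2g_mean_filter_and_bias(self):
        v = np.array([1.0, 2.0, 3.0])
        assert n2g_forward(v, np.full(3, 1 / 3)) == pytest.approx(2.0)
        assert n2g_forward(np.zeros(3), np.ones(3), bias=1.5) == pytest.approx(1.5)

    def test_primitives_match_loop_oracles(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            M = rng.normal(size=(n, n))
            rw, cw, w = rng.normal(size=(3, n))
            b = float(rng.normal())
            e2e_oracle = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    e2e_oracle[i, j] = (sum(rw[k] * M[i, k] for k in range(n))
                                        + sum(cw[k] * M[k, j] for k in range(n)) + b)
            np.testing.assert_allclose(e2e_forward(M, rw, cw, b), e2e_oracle,
                                       atol=1e-10)
            e2n_oracle = np.array(
                [sum(w[j] * M[i, j] for j in range(n)) + b for i in range(n)])
            np.testing.assert_allclose(e2n_forward(M, w, b), e2n_oracle,
                                       atol=1e-10)
            v = rng.normal(size=n)
            assert n2g_forward(v, w, b) == pytest.approx(
                sum(w[i] * v[i] for i in range(n)) + b, abs=1e-10)


class TestDiscriminator:
    def make(self, seed=0, n_regions=6, phen_len=3, n_classes=3):
        return DiscriminatorParams(n_regions, phen_len, n_classes, GANConfig(),
                                   np.random.default_rng(seed))

    def test_eval_mode_deterministic(self):
        dp = self.make()
        rng = np.random.default_rng(2)
        M = rng.uniform(-1, 1, size=(6, 6))
        M = 0.5 * (M + M.T)
        phen = rng.uniform(0, 1, size=3)
        v1, p1 = discriminator_forward(dp, M, phen)
        v2, p2 = discriminator_forward(dp, M, phen)
        assert v1 == v2 and np.array_equal(p1, p2)

    def test_heads_well_formed(self):
        dp = self.make(seed=5)
        rng = np.random.default_rng(3)
        M = rng.uniform(-1, 1, size=(4, 6, 6))
        phen = rng.uniform(0, 1, size=(4, 3))
        validity, probs = discriminator_forward(dp, M, phen)
        assert np.all((validity > 0) & (validity < 1))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_n_mismatch_rejected(self):
        dp = self.make()
        with pytest.raises(ValueError, match="expects"):
            discriminator_forward(dp, np.eye(9), np.zeros(3))


class TestTraining:
    def test_same_seed_identical_loss_trajectory(self):
        cohort = small_cohort()
        cfg = GANConfig(epochs=3, seed=11)
        r1 = train_gan(cohort, cfg)
        r2 = train_gan(cohort, cfg)
        assert r1.history["d_loss"] == r2.history["d_loss"]
        assert r1.history["g_loss"] == r2.history["g_loss"]

    def test_brainnetcnn_same_seed_reproducible(self):
        cohort = small_cohort()
        cfg = GANConfig(epochs=3, seed=4)
        d1 = train_brainnetcnn(cohort, cfg)
        d2 = train_brainnetcnn(cohort, cfg)
        _, p1 = discriminator_forward(d1, cohort.matrices(),
                                      cohort.phenotype_matrix())
        _, p2 = discriminator_forward(d2, cohort.matrices(),
                                      cohort.phenotype_matrix())
        assert np.array_equal(p1, p2)

    def test_zero_epoch_brainnetcnn_near_chance(self):
        cohort = small_cohort()
        dp = train_brainnetcnn(cohort, GANConfig(epochs=0, seed=0))
        _, probs = discriminator_forward(dp, cohort.matrices(),
                                         cohort.phenotype_matrix())
        # untrained network: probabilities should not be confidently one-sided
        assert np.all(probs.max(axis=1) < 0.9)

    def test_single_class_rejected(self):
        cohort = small_cohort()
        with pytest.raises(ValueError, match="single class"):
            train_gan(cohort.subset(range(8)), GANConfig(epochs=1))


class TestGenerateSamples:
    def trained_generator(self):
        cohort = small_cohort()
        result = train_gan(cohort, GANConfig(epochs=2, seed=0))
        return result.generator, cohort

    def test_zero_request_gives_empty_list(self):
        gp, cohort = self.trained_generator()
        assert generate_samples(gp, 0, cohort, seed=0) == []

    def test_samples_are_valid_fc_shaped(self):
        gp, cohort = self.trained_generator()
        samples = generate_samples(gp, 5, cohort, seed=3)
        assert len(samples) == 5
        for fc, phen, y in samples:
            fc.validate()  # unit-diagonal rule waived via unit_diagonal=False
            assert np.array_equal(fc.values, fc.values.T)
            assert np.all(np.abs(fc.values) < 1.0)
            assert y in (0, 1)

    def test_fixed_seed_identical_samples(self):
        gp, cohort = self.trained_generator()
        a = generate_samples(gp, 3, cohort, seed=9)
        b = generate_samples(gp, 3, cohort, seed=9)
        for (fa, pa, ya), (fb, pb, yb) in zip(a, b):
            assert np.array_equal(fa.values, fb.values)
            assert ya == yb

    def test_gan_checkpoint_round_trip(self, tmp_path):
        from fcnets import persist
        cohort = small_cohort()
        result = train_gan(cohort, GANConfig(epochs=2, seed=1))
        persist.save_gan(result.generator, result.discriminator,
                         tmp_path / "g.npz")
        gen, disc = persist.load_gan(tmp_path / "g.npz")
        a = generate_samples(result.generator, 2, cohort, seed=5)
        b = generate_samples(gen, 2, cohort, seed=5)
        assert np.array_equal(a[0][0].values, b[0][0].values)
        _, p1 = discriminator_forward(result.discriminator, cohort.matrices(),
                                      cohort.phenotype_matrix())
        _, p2 = discriminator_forward(disc, cohort.matrices(),
                                      cohort.phenotype_matrix())
        np.testing.assert_array_equal(p1, p2)


class TestConditioningProbe:
    def test_generator_conditioning_no_mode_collapse(self):
        """A fully trained generator must produce diverse samples whose
        per-class means sit closer to the matching real class mean than to
        the other class's (in >= 4/5 seeds) — the probe that catches both
        mode collapse and ignored conditioning."""
        from fcnets.synthetic import SimSpec, generate_cohort

        n_pass = 0
        for seed in range(5):
            cohort, _ = generate_cohort(
                SimSpec(n_regions=20, n_per_class=(50, 50), effect_size=0.4,
                        effect_edges=0.05, seed=seed))
            train = cohort.subset(list(range(40)) + list(range(50, 90)))
            result = train_gan(train, GANConfig(epochs=300, seed=seed))
            samples = generate_samples(result.generator, 200, train,
                                       seed=seed + 77)
            y = train.labels()
            mats = train.matrices()
            by_class = {0: [], 1: []}
            for fc, _, label in samples:
                by_class[label].append(fc.values)
            g0 = by_class[0][:20]
            pairwise = np.mean([np.linalg.norm(a - b)
                                for i, a in enumerate(g0) for b in g0[i + 1:]])
            assert pairwise > 0  # distinct samples, not a collapsed point
            ok = True
            for c in (0, 1):
                gen_mean = np.mean(by_class[c], axis=0)
                d_own = np.linalg.norm(gen_mean - mats[y == c].mean(axis=0))
                d_other = np.linalg.norm(gen_mean - mats[y != c].mean(axis=0))
                ok = ok and (d_own < d_other)
            n_pass += ok
        assert n_pass >= 4, f"conditioning held in only {n_pass}/5 seeds"
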