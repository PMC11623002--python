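"""Conditional GAN: architecture conformance, objective, training loop."""

import numpy as np
import pytest

from splitfed import cgan, nn
from splitfed.cgan import (GanSpec, build_discriminator, build_generator,
                           gan_objective, generate_latent_points,
                           generator_loss, synthesize, train_cgan)
from splitfed.data import DatasetError
from splitfed.phantom import PhantomSpec, generate_phantom_dataset

# published per-layer trainable parameter counts for the default
# 256x256 / latent-100 / embed-50 / 3-class configuration; the label
# embedding is vocabulary-dependent and checked separately
GENERATOR_REFERENCE = {
    "dense_latent": 413_696,
    "dense_label": 208_896,
    "convtranspose_1": 2_112,
    "convtranspose_2": 1_025,
}
DISCRIMINATOR_REFERENCE = {
    "dense_label": 3_342_336,
    "conv_1": 2_432,
    "conv_2": 147_584,
    "conv_3": 147_584,
    "conv_4": 147_584,
    "conv_5": 147_584,
    "dense_out": 8_193,
}

SMALL = GanSpec(image_size=32, base_channels=8, latent_dim=16, embed_dim=5)


class TestArchitectureConformance:
    def test_generator_layer_counts_match_reference(self):
        table = cgan.generator_param_table(GanSpec())
        for layer, count in GENERATOR_REFERENCE.items():
            assert table[layer] == count, layer

    def test_discriminator_layer_counts_match_reference(self):
        table = cgan.discriminator_param_table(GanSpec())
        for layer, count in DISCRIMINATOR_REFERENCE.items():
            assert table[layer] == count, layer

    def test_built_models_realize_the_tables(self):
        # a reduced image size keeps construction cheap; every non-embedding
        # layer count is spec-derived and must match the built parameters
        spec = GanSpec(image_size=64)
        assert cgan.generator_actual_counts(build_generator(spec)) == \
            cgan.generator_param_table(spec)
        assert cgan.discriminator_actual_counts(build_discriminator(spec)) == \
            cgan.discriminator_param_table(spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(DatasetError):
            GanSpec(image_size=30)


class TestForwardContracts:
    def test_generator_output_shape_and_tanh_range(self):
        gen = build_generator(SMALL, seed=1)
        z, labels = generate_latent_points(SMALL.latent_dim, 4, 3, seed=0)
        out = gen(z, labels)
        assert out.shape == (4, 1, 32, 32)
        assert np.abs(out.data).max() <= 1.0

    def test_discriminator_output_in_unit_interval(self, rng):
        disc = build_discriminator(SMALL, seed=1)
        imgs = rng.standard_normal((4, 1, 32, 32))
        p = disc(imgs, np.array([0, 1, 2, 0]))
        assert p.shape == (4, 1)
        assert np.all((p.data >= 0) & (p.data <= 1))


class TestObjective:
    def test_perfect_discriminator_limit(self):
        eps = 1e-7
        v = gan_objective(np.array([1 - eps]), np.array([eps]))
        assert -1e-5 < v <= 0.0

    def test_uninformative_discriminator_value(self):
        v = gan_objective(np.array([0.5, 0.5]), np.array([0.5]))
        assert v == pytest.approx(2 * np.log(0.5), abs=1e-9)

    def test_equals_negative_bce_of_discriminator(self, rng):
        d_real = rng.uniform(0.05, 0.95, size=20)
        d_fake = rng.uniform(0.05, 0.95, size=20)
        bce_real = nn.binary_cross_entropy(
            nn.Tensor(d_real.reshape(-1, 1)), np.ones((20, 1))).item()
        bce_fake = nn.binary_cross_entropy(
            nn.Tensor(d_fake.reshape(-1, 1)), np.zeros((20, 1))).item()
        assert gan_objective(d_real, d_fake) == pytest.approx(
            -(bce_real + bce_fake), abs=1e-5)

    def test_monotonicity_on_probability_grids(self):
        grid = np.linspace(0.01, 0.99, 25)
        vals_real = [gan_objective(np.array([p]), np.array([0.5])) for p in grid]
        vals_fake = [gan_objective(np.array([0.5]), np.array([p])) for p in grid]
        assert np.all(np.diff(vals_real) > 0)     # maximized at d_real -> 1
        assert np.all(np.diff(vals_fake) < 0)     # maximized at d_fake -> 0

    def test_generator_loss_forms(self):
        d_fake = np.array([0.3, 0.7])
        assert generator_loss(d_fake) == pytest.approx(
            -np.mean(np.log(d_fake)))
        assert generator_loss(d_fake, saturating=True) == pytest.approx(
            np.mean(np.log(1 - d_fake)))

    def test_empty_inputs_error(self):
        with pytest.raises(DatasetError):
            gan_objective(np.array([]), np.array([0.5]))


class TestLatentPoints:
    def test_shapes_and_label_range(self):
        z, labels = generate_latent_points(100, 5, 3, seed=0)
        assert z.shape == (5, 100)
        assert labels.shape == (5,)
        assert set(labels) <= {0, 1, 2}

    def test_seeded_determinism_and_fixed_class(self):
        z1, l1 = generate_latent_points(8, 10, 3, seed=4)
        z2, l2 = generate_latent_points(8, 10, 3, seed=4)
        assert np.array_equal(z1, z2) and np.array_equal(l1, l2)
        _, lf = generate_latent_points(8, 10, 3, seed=4, fixed_class=2)
        assert np.all(lf == 2)


@pytest.fixture(scope="module")
def tiny_gan_run():
    ds = generate_phantom_dataset(
        PhantomSpec(image_size=32, n_per_class=(4, 4, 4), seed=5))
    spec = GanSpec(image_size=32, base_channels=8, latent_dim=16, embed_dim=5)
    weights, log = train_cgan(ds, spec, n_epochs=2, n_batch=8, seed=3)
    return ds, spec, weights, log


class TestTraining:
    def test_smoke_run_finite_losses_one_record_per_epoch(self, tiny_gan_run):
        _, _, _, log = tiny_gan_run
        assert len(log) == 2
        for series in (log.d_loss_real, log.d_loss_fake, log.g_loss):
            assert len(series) == 2 and all(np.isfinite(series))
        for series in (log.d_acc_real, log.d_acc_fake):
            assert all(0.0 <= a <= 1.0 for a in series)

    def test_discriminator_frozen_during_generator_step(self, rng):
        spec = SMALL
        gen = build_generator(spec, seed=1)
        disc = build_discriminator(spec, seed=2)
        opt_g = nn.Adam(gen.parameters(), lr=1e-3)
        before = disc.state_dict()
        z, labels = generate_latent_points(spec.latent_dim, 4, 3, seed=0)
        p = disc(gen(z, labels), labels)
        loss = nn.binary_cross_entropy(p, np.ones((4, 1)))
        gen.zero_grad()
        loss.backward()
        opt_g.step()           # only the generator optimizer steps
        after = disc.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)
        assert any(p.grad is not None and np.any(p.grad)
                   for p in gen.parameters())

    def test_training_determinism(self):
        ds = generate_phantom_dataset(
            PhantomSpec(image_size=32, n_per_class=(4, 4, 4), seed=5))
        spec = GanSpec(image_size=32, base_channels=8, latent_dim=16, embed_dim=5)
        _, log1 = train_cgan(ds, spec, n_epochs=1, n_batch=8, seed=9)
        _, log2 = train_cgan(ds, spec, n_epochs=1, n_batch=8, seed=9)
        assert log1.d_loss_real == log2.d_loss_real
        assert log1.g_loss == log2.g_loss

    def test_size_mismatch_rejected_before_training(self, small_phantom):
        with pytest.raises(DatasetError):
            train_cgan(small_phantom, GanSpec(image_size=64, base_channels=8),
                       n_epochs=1, n_batch=4, seed=0)


class TestSynthesize:
    def test_count_shape_range_and_provenance(self, tiny_gan_run):
        _, spec, weights, _ = tiny_gan_run
        out = synthesize(weights, class_label=1, n=10, seed=0)
        assert len(out) == 10
        assert all(im.shape == (32, 32) for im in out.images)
        assert all(im.min() >= 0 and im.max() <= 1 for im in out.images)
        assert np.all(out.labels == 1)
        assert all(p == "synthetic" for p in out.provenance)

    def test_rescale_maps_back_to_tanh_range(self, tiny_gan_run):
        _, _, weights, _ = tiny_gan_run
        out = synthesize(weights, class_label=0, n=3, seed=1)
        for im in out.images:
            assert np.abs(im * 2 - 1).max() <= 1.0 + 1e-6

    def test_label_out_of_range(self, tiny_gan_run):
        _, _, weights, _ = tiny_gan_run
        with pytest.raises(DatasetError):
            synthesize(weights, class_label=5, n=1, seed=0)


class TestPersistence:
    def test_checkpoint_roundtrip(self, tiny_gan_run, tmp_path):
        _, spec, weights, _ = tiny_gan_run
        path = tmp_path / "gan.npz"
        cgan.save_gan(weights, path)
        loaded = cgan.load_gan(path)
        assert loaded.spec == spec
        assert all(np.array_equal(loaded.generator[k], weights.generator[k])
                   for k in weights.generator)
        a = synthesize(weights, 0, 2, seed=5).images
        b = synthesize(loaded, 0, 2, seed=5).images
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
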