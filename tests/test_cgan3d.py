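"""3D pix2pix: architecture rules, losses, training contracts, inference."""

import numpy as np
import pytest

from airgap3d import cgan3d
from airgap3d.cgan3d import (
    CheckpointEntry,
    DiscriminatorSpec,
    GeneratorSpec,
    TrainConfig,
    build_discriminator,
    build_generator,
    denormalize_intensities,
    discriminator_loss,
    generate,
    generator_loss,
    load_generator,
    normalize_intensities,
    receptive_field,
    train,
)
from airgap3d.volume_io import Volume3D

from conftest import make_phantom_pairs


class TestSpecs:
    def test_depth_rule_truncates_default_filters(self):
        assert GeneratorSpec(cube_edge=32).encoder_filters == (64, 128, 256, 512, 512)
        spec256 = GeneratorSpec(cube_edge=256)
        assert spec256.encoder_filters == (64, 128, 256, 512, 512, 512, 512, 512)
        assert spec256.decoder_filters == (512, 512, 512, 512, 256, 128, 64)

    def test_non_power_of_two_edge_rejected(self):
        with pytest.raises(ValueError, match="power of two"):
            GeneratorSpec(cube_edge=48)

    def test_filter_count_must_match_depth(self):
        with pytest.raises(ValueError, match="encoder filters"):
            GeneratorSpec(cube_edge=32, encoder_filters=(8, 16))

    def test_discriminator_final_stride_must_be_one(self):
        with pytest.raises(ValueError, match="stride 1"):
            DiscriminatorSpec(strides=(2, 2, 2, 2))


class TestGenerator:
    def test_forward_preserves_shape(self):
        spec = GeneratorSpec(cube_edge=16, encoder_filters=(4, 8, 8, 8))
        model = build_generator(spec, seed=0)
        x = np.random.default_rng(0).standard_normal((1, 16, 16, 16)).astype(np.float32)
        y = model.net.forward(x, training=False)
        assert y.shape == (1, 16, 16, 16)
        assert (np.abs(y) <= 1.0).all()  # tanh head

    def test_parameter_count_matches_hand_computation(self):
        # edge 8, filters (8, 16, 8): hand-count conv + norm parameters
        spec = GeneratorSpec(cube_edge=8, encoder_filters=(8, 16, 8))
        model = build_generator(spec, seed=0)
        k3 = 4 ** 3

        def conv(cin, cout):
            return k3 * cin * cout + cout

        def bn(c):
            return 2 * c

        expected = (
            conv(1, 8)                      # enc1 (no norm)
            + conv(8, 16) + bn(16)          # enc2
            + conv(16, 8)                   # bottleneck (no norm)
            + conv(8, 16) + bn(16)          # dec1: T16
            + conv(16 + 16, 8) + bn(8)      # dec2: T8 on concat
            + conv(8 + 8, 1)                # output transpose conv
        )
        assert model.n_parameters() == expected

    def test_inference_is_deterministic_and_dropout_active_in_training(self):
        spec = GeneratorSpec(cube_edge=16, encoder_filters=(4, 8, 8, 8))
        model = build_generator(spec, seed=1)
        cube = Volume3D(np.random.default_rng(2).integers(0, 256, (16, 16, 16),
                                                          dtype=np.uint8))
        a = generate(model, cube)
        b = generate(model, cube)
        assert np.array_equal(a.data, b.data)
        x = normalize_intensities(cube.data)[None]
        t1 = model.net.forward(x, training=True)
        t2 = model.net.forward(x, training=True)
        assert not np.array_equal(t1, t2)  # dropout is a live noise source

    def test_generate_rejects_wrong_edge(self):
        model = build_generator(GeneratorSpec(cube_edge=16,
                                              encoder_filters=(4, 8, 8, 8)))
        with pytest.raises(ValueError, match="16"):
            generate(model, Volume3D(np.zeros((32, 32, 32), dtype=np.uint8)))

    def test_untrained_output_valid_shape_and_range(self):
        model = build_generator(GeneratorSpec(cube_edge=16,
                                              encoder_filters=(4, 8, 8, 8)))
        cube = Volume3D(np.full((16, 16, 16), 100, dtype=np.uint8), voxel_size_um=2.0)
        out = generate(model, cube)
        assert out.shape == cube.shape
        assert out.voxel_size_um == cube.voxel_size_um
        assert out.data.dtype == np.uint8


class TestDiscriminator:
    def test_score_map_shape_and_range(self):
        spec = DiscriminatorSpec(filters=(4, 8, 8, 8), strides=(2, 2, 2, 1))
        d = build_discriminator(spec, seed=0)
        rng = np.random.default_rng(0)
        s = d.score(rng.standard_normal((32,) * 3).astype(np.float32),
                    rng.standard_normal((32,) * 3).astype(np.float32))
        # 32 / 2^3 = 4 with two trailing stride-1 convs (same padding)
        assert s.shape == (1, 4, 4, 4)
        assert ((s > 0) & (s < 1)).all()


class TestReceptiveField:
    def test_default_patch_size_is_70(self):
        assert receptive_field(DiscriminatorSpec()) == 70

    def test_single_stride1_layer(self):
        assert receptive_field(DiscriminatorSpec(filters=(1,), strides=(1,))) == 7

    @pytest.mark.parametrize("strides", [(2, 2, 2, 1), (2, 2, 1, 1)])
    def test_recurrence_matches_gradient_footprint(self, strides):
        """Empirical oracle: extent of the nonzero input gradient of single
        scores.  Scores whose window lies fully inside the volume see exactly
        the receptive field; border scores see no more than it."""
        spec = DiscriminatorSpec(filters=(3, 3, 3, 3), strides=strides)
        rf = receptive_field(spec)
        d = build_discriminator(spec, seed=0, dtype=np.float64)
        # eval mode: batchnorm uses fixed running stats, so the input gradient
        # of one score is exactly its receptive-field window
        n = rf + 40
        x = np.random.default_rng(0).standard_normal((2, n, n, n)) * 0.1
        y = d.net.forward(x, training=False)
        best = 0
        for o in range(2, y.shape[1] - 1):
            if best == rf:
                break
            d.net.forward(x, training=False)
            gy = np.zeros_like(y)
            gy[0, o, o, o] = 1.0
            gx = d.net.backward(gy)
            footprint = np.abs(gx).sum(axis=0) > 0
            extents = []
            for ax in range(3):
                nz = np.flatnonzero(footprint.any(axis=tuple(a for a in range(3)
                                                             if a != ax)))
                extents.append(nz[-1] - nz[0] + 1)
            assert max(extents) <= rf       # never wider than the recurrence
            best = max(best, min(extents))
        assert best == rf                   # attained by interior scores


class TestLosses:
    def test_l1_term_zero_for_identical_volumes(self):
        scores = np.full((1, 2, 2, 2), 0.5)
        v = np.random.default_rng(0).standard_normal((1, 8, 8, 8))
        loss = generator_loss(scores, v, v.copy(), lambda_l1=100.0)
        assert loss == pytest.approx(-np.log(0.5))

    def test_lambda_scales_the_l1_term_linearly(self):
        scores = np.full((1, 2, 2, 2), 0.5)
        rng = np.random.default_rng(1)
        g, t = rng.standard_normal((1, 8, 8, 8)), rng.standard_normal((1, 8, 8, 8))
        adv = -np.log(0.5)
        l1 = generator_loss(scores, g, t, 100.0) - adv
        l2 = generator_loss(scores, g, t, 200.0) - adv
        assert l2 == pytest.approx(2 * l1)

    def test_generator_loss_shape_mismatch(self):
        with pytest.raises(ValueError):
            generator_loss(np.full((1, 1, 1, 1), 0.5), np.zeros((1, 4, 4, 4)),
                           np.zeros((1, 8, 8, 8)))

    def test_discriminator_loss_at_half_scores(self):
        half = np.full((1, 3, 3, 3), 0.5)
        assert discriminator_loss(half, half) == pytest.approx(-np.log(0.5))

    def test_perfect_discrimination_drives_loss_to_zero(self):
        eps = 1e-6
        real = np.full((1, 3, 3, 3), 1.0 - eps)
        fake = np.full((1, 3, 3, 3), eps)
        assert discriminator_loss(real, fake) < 1e-5

    def test_symmetry_under_real_fake_swap(self):
        rng = np.random.default_rng(2)
        real = rng.uniform(0.05, 0.95, (1, 3, 3, 3))
        fake = rng.uniform(0.05, 0.95, (1, 3, 3, 3))
        assert discriminator_loss(real, fake) == pytest.approx(
            discriminator_loss(1.0 - fake, 1.0 - real))


class TestNormalization:
    def test_round_trip_on_all_8bit_values(self):
        v = np.arange(256, dtype=np.uint8).reshape(4, 8, 8)
        assert np.array_equal(denormalize_intensities(normalize_intensities(v)), v)

    def test_range_mapping(self):
        v = np.array([0, 255], dtype=np.uint8).reshape(1, 1, 2)
        n = normalize_intensities(v)
        assert n.min() == -1.0 and n.max() == 1.0


class TestTraining:
    def test_checkpoint_cadence(self, tmp_path):
        pairs = make_phantom_pairs(2, 50)
        cfg = TrainConfig(epochs=4, checkpoint_interval_epochs=2, seed=0)
        spec = cgan3d.GeneratorSpec(cube_edge=16, encoder_filters=(4, 8, 8, 8))
        dspec = DiscriminatorSpec(filters=(4, 8, 8, 8), strides=(2, 2, 2, 1))
        series = train(pairs, cfg, checkpoint_dir=tmp_path, gen_spec=spec,
                       disc_spec=dspec)
        assert [e.epoch for e in series] == [2, 4]  # exactly epochs/interval saves
        assert (tmp_path / "generator_epoch2.npz").exists()
        assert (tmp_path / "generator_epoch4.npz").exists()
        assert (tmp_path / "losses.csv").exists()
        assert (tmp_path / "manifest.json").exists()

    def test_identical_seed_reproduces_loss_trace(self):
        pairs = make_phantom_pairs(2, 60)
        spec = cgan3d.GeneratorSpec(cube_edge=16, encoder_filters=(4, 8, 8, 8))
        dspec = DiscriminatorSpec(filters=(4, 8, 8, 8), strides=(2, 2, 2, 1))
        cfg = TrainConfig(epochs=2, checkpoint_interval_epochs=1, seed=3)
        t1 = train(pairs, cfg, None, spec, dspec).loss_trace
        t2 = train(pairs, cfg, None, spec, dspec).loss_trace
        assert t1 == t2

    def test_inconsistent_cube_sizes_rejected(self):
        pairs = make_phantom_pairs(1, 0, edge=16) + make_phantom_pairs(1, 0, edge=32)
        with pytest.raises(ValueError, match="inconsistent"):
            train(pairs, TrainConfig(epochs=1), None)

    def test_training_reduces_reconstruction_error(self, smoke_run):
        """After the smoke budget the generator beats the artifact-bearing source."""
        from airgap3d.model_eval import relative_error

        re_src = np.mean([relative_error(p.source, p.target)
                          for p in smoke_run["test_pairs"]])
        last = [r for r in smoke_run["reports"] if r.epoch == 30][0]
        first = [r for r in smoke_run["reports"] if r.epoch == 0][0]
        assert last.re_mean < re_src
        assert last.re_mean < first.re_mean

    def test_trained_generator_removes_intensity_extremes(self, smoke_run):
        model = smoke_run["series"].last.model
        n_in = n_out = 0
        for pair in smoke_run["test_pairs"]:
            out = generate(model, pair.source)
            n_in += int(((pair.source.data == 0) | (pair.source.data == 255)).sum())
            n_out += int(((out.data == 0) | (out.data == 255)).sum())
        assert n_in > 0
        assert n_out < n_in


class TestCheckpointIO:
    def test_save_load_round_trip(self, tmp_path):
        spec = GeneratorSpec(cube_edge=16, encoder_filters=(4, 8, 8, 8))
        model = build_generator(spec, seed=9)
        model.epoch = 7
        model.save(tmp_path / "g.npz")
        back = load_generator(tmp_path / "g.npz")
        assert back.epoch == 7
        assert back.spec == spec
        cube = Volume3D(np.random.default_rng(0).integers(0, 256, (16, 16, 16),
                                                          dtype=np.uint8))
        assert np.array_equal(generate(model, cube).data, generate(back, cube).data)
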