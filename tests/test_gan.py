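"""Adversarial training mechanics: updates, determinism, decoding, checkpoints."""

import numpy as np
import pytest

from channelsynth import (
    GanSpec,
    PairedRecord,
    build_discriminator,
    build_generator,
    decode_labels,
    generate,
    load_checkpoint,
    make_windows,
    robust_scale,
    save_checkpoint,
    snap_labels,
    train,
)
from channelsynth.gan import _sigmoid
from channelsynth.signal_io import ScalerParams, WindowBatch


@pytest.fixture(scope="module")
def tiny_spec():
    return GanSpec(window_length=64, batch_size=32, epochs=3, seed=0)


@pytest.fixture(scope="module")
def tiny_batch(demo_record):
    return make_windows(demo_record, 64, 64)


class TestArchitecture:
    def test_parameter_counts_are_functions_of_spec(self, tiny_spec, rng):
        # snapshot: hand-summed from the layer shapes for W=64, 16 base channels
        G = build_generator(tiny_spec, rng)
        D = build_discriminator(tiny_spec, rng, np.random.default_rng(0))
        assert G.n_params == 77586
        assert D.n_params == 10993

    def test_generator_output_shape_and_range(self, tiny_spec, rng):
        G = build_generator(tiny_spec, rng)
        out = G.forward(rng.standard_normal((16, tiny_spec.latent_size)), training=False)
        assert out.shape == (16, 2, 64)
        assert np.all(np.isfinite(out))
        assert np.all(np.abs(out) <= 1.0)

    def test_discriminator_probability_range(self, tiny_spec, rng):
        D = build_discriminator(tiny_spec, rng, np.random.default_rng(0))
        p = _sigmoid(D.forward(rng.standard_normal((8, 2, 64)), training=False))
        assert np.all((p > 0) & (p < 1))

    def test_window_length_must_be_multiple_of_eight(self):
        with pytest.raises(ValueError, match="divisible by 8"):
            GanSpec(window_length=100)

    def test_image_latent_option(self, rng):
        spec = GanSpec(window_length=64, latent_shape="image")
        assert spec.latent_size == 2 * 64
        G = build_generator(spec, rng)
        out = G.forward(rng.standard_normal((4, spec.latent_size)), training=False)
        assert out.shape == (4, 2, 64)


class TestUpdateIsolation:
    def test_generator_step_leaves_discriminator_untouched(self, tiny_spec, rng):
        from channelsynth import nn

        G = build_generator(tiny_spec, rng)
        D = build_discriminator(tiny_spec, rng, np.random.default_rng(1))
        d_before = [p.value.copy() for p in D.params()]
        opt_g = nn.Adam(G.params(), lr=1e-3)
        z = rng.standard_normal((8, tiny_spec.latent_size))
        G.zero_grad()
        fake = G.forward(z, training=True)
        D.zero_grad()
        p = _sigmoid(D.forward(fake, training=True))
        dfake = D.backward((p - 1.0) / len(p))
        D.zero_grad()
        G.backward(dfake)
        opt_g.step()
        for before, param in zip(d_before, D.params()):
            assert np.array_equal(before, param.value)

    def test_discriminator_step_leaves_generator_untouched(self, tiny_spec, rng):
        from channelsynth import nn

        G = build_generator(tiny_spec, rng)
        D = build_discriminator(tiny_spec, rng, np.random.default_rng(1))
        g_before = [p.value.copy() for p in G.params()]
        opt_d = nn.Adam(D.params(), lr=1e-3)
        real = rng.standard_normal((8, 2, 64))
        D.zero_grad()
        p = _sigmoid(D.forward(real, training=True))
        D.backward((p - 1.0) / len(p))
        opt_d.step()
        for before, param in zip(g_before, G.params()):
            assert np.array_equal(before, param.value)

    def test_descent_against_frozen_discriminator(self, tiny_spec, rng):
        """Plain gradient steps on a fixed latent batch against a frozen,
        confident discriminator reduce the generator loss monotonically."""
        from channelsynth.gan import generator_loss

        G = build_generator(tiny_spec, rng)
        D = build_discriminator(tiny_spec, rng, np.random.default_rng(2))
        z = rng.standard_normal((16, tiny_spec.latent_size))
        losses = []
        lr = 1e-3
        for _ in range(15):
            G.zero_grad()
            fake = G.forward(z, training=True)
            D.zero_grad()
            p = _sigmoid(D.forward(fake, training=False))
            dfake = D.backward((p - 1.0) / len(p))
            G.backward(dfake)
            losses.append(generator_loss(p.ravel()))
            for param in G.params():
                param.value -= lr * param.grad
        diffs = np.diff(losses)
        assert np.all(diffs <= 1e-10)


class TestTraining:
    def test_bookkeeping_and_finite_losses(self, tiny_batch, tiny_spec):
        log = train(tiny_batch, tiny_spec)
        assert len(log.d_loss) == tiny_spec.epochs
        assert len(log.g_loss) == tiny_spec.epochs
        assert np.all(np.isfinite(log.d_loss))
        assert np.all(np.isfinite(log.g_loss))
        assert not log.aborted

    def test_same_seed_gives_identical_loss_sequences(self, tiny_batch, tiny_spec):
        a = train(tiny_batch, tiny_spec)
        b = train(tiny_batch, tiny_spec)
        assert a.d_loss == b.d_loss
        assert a.g_loss == b.g_loss

    def test_too_few_windows_rejected(self, tiny_batch, tiny_spec):
        small = WindowBatch(
            tiny_batch.data[:10], 64, 64, tiny_batch.scaler
        )
        with pytest.raises(ValueError, match="batch_size"):
            train(small, tiny_spec)

    def test_checkpoint_roundtrip_and_resume(self, tiny_batch, tiny_spec, tmp_path):
        hold = tiny_batch.data[:16]
        log = train(tiny_batch, tiny_spec, out_dir=tmp_path / "run",
                    eval_windows=hold)
        assert "latest" in log.checkpoints
        G, D, spec, scaler = load_checkpoint(tmp_path / "run" / "latest")
        a = generate(tmp_path / "run" / "latest", 8, seed=3)
        b = generate(G, 8, seed=3, spec=spec, scaler=scaler)
        assert np.allclose(a.data, b.data)
        # resuming continues without error and logs more epochs
        log2 = train(tiny_batch, tiny_spec, resume_from=tmp_path / "run" / "latest")
        assert len(log2.d_loss) == tiny_spec.epochs

    def test_checkpoint_shape_mismatch_detected(self, tiny_spec, tiny_batch, tmp_path):
        import json

        log = train(tiny_batch, tiny_spec, out_dir=tmp_path / "run")
        spec_path = tmp_path / "run" / "latest" / "spec.json"
        d = json.loads(spec_path.read_text())
        d["base_channels"] = 8
        spec_path.write_text(json.dumps(d))
        with pytest.raises(ValueError, match="mismatch"):
            load_checkpoint(tmp_path / "run" / "latest")


class TestGenerate:
    def test_shape_range_determinism(self, tiny_spec, tiny_batch, rng):
        G = build_generator(tiny_spec, rng)
        a = generate(G, 16, seed=9, spec=tiny_spec, scaler=tiny_batch.scaler)
        b = generate(G, 16, seed=9, spec=tiny_spec, scaler=tiny_batch.scaler)
        assert a.data.shape == (16, 2, 64)
        assert a.source == "generated"
        assert np.all(np.abs(a.data) <= 1.0) and np.all(np.isfinite(a.data))
        assert np.array_equal(a.data, b.data)


class TestDecode:
    def test_nearest_level_and_lower_tie(self):
        scaler = ScalerParams(center=0.0, scale=1.0, label_levels=[0, 1])
        data = np.zeros((1, 2, 64))
        data[0, 1, :32] = 0.97   # near +1 -> level 1
        data[0, 1, 32:] = 0.0    # midpoint -> lower level 0
        batch = WindowBatch(data, 64, 64, scaler, source="generated")
        rec = decode_labels(batch, crop_fraction=0.0)[0]
        assert set(rec.label[:32]) == {1}
        assert set(rec.label[32:]) == {0}

    def test_encode_decode_roundtrip_on_noiseless_batch(self, demo_record):
        scaled, params = robust_scale(demo_record)
        batch = WindowBatch(
            scaled[None, :, :64], 64, 64, params, source="generated"
        )
        rec = decode_labels(batch, crop_fraction=0.0, sample_rate=5000.0)[0]
        assert np.array_equal(rec.label, demo_record.label[:64])
        assert np.allclose(rec.raw, demo_record.raw[:64])

    def test_crop_applied(self, tiny_batch):
        batch = WindowBatch(tiny_batch.data[:2], 64, 64, tiny_batch.scaler,
                            source="generated")
        recs = decode_labels(batch, crop_fraction=0.05)
        assert len(recs[0]) == 64 - 2 * int(0.05 * 64)
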