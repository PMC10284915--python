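"""Dual-encoder network: architecture, training machinery, inference."""

import numpy as np
import pytest

from hemomap.core import ConfigurationError, VolumeMap
from hemomap.grrs import GrrsOutputs
from hemomap.nn.model import DualEncoderDecoder, NetworkConfig, build_model
from hemomap.nn.training import (TrainingHyperparams, TrainingSample, augment,
                                 augment_cohort, flip_sample, kfold_split,
                                 l1_loss_and_grad, make_samples,
                                 predict_volume, train)
from hemomap.supplementary import CCStack


def tiny_config(**kw):
    defaults = dict(base_channels=4, supplementary_in_channels=6, seed=1)
    defaults.update(kw)
    return NetworkConfig(**defaults)


def expected_parameter_count(cfg: NetworkConfig) -> int:
    """Independent layer-by-layer arithmetic from the configuration."""

    def conv(cin, cout, k):
        return cout * cin * k * k + cout

    def bn(c):
        return 2 * c

    def conv_pair(cin, cout):
        return conv(cin, cout, 3) + bn(cout) + conv(cout, cout, 3) + bn(cout)

    base, depth = cfg.base_channels, cfg.depth
    total = 0
    widths = [base * 2 ** i for i in range(depth)]
    for in_ch, enabled in ((cfg.primary_in_channels, cfg.use_primary_encoder),
                           (cfg.supplementary_in_channels,
                            cfg.use_supplementary_encoder)):
        if not enabled:
            continue
        prev = in_ch
        for w in widths:
            total += conv_pair(prev, w)
            prev = w
    n_enc = cfg.n_encoders
    fused = widths[-1] * n_enc
    for _decoder in range(2):
        prev = fused
        for j in range(1, cfg.decoder_blocks + 1):
            w = base * 2 ** (cfg.decoder_blocks - j)
            total += prev * w * 4 + w          # 2x2 transpose conv
            total += conv_pair(2 * w, w)       # after skip concatenation
            prev = w
        total += conv(prev, 1, 1)              # 1x1 head
    return total


class TestArchitecture:
    def test_forward_shape_contract(self, rng):
        model = build_model(tiny_config())
        p = rng.normal(size=(1, 3, 96, 112)).astype(np.float32)
        s = rng.normal(size=(1, 6, 96, 112)).astype(np.float32)
        out = model.forward(p, s)
        assert out.shape == (1, 2, 96, 112)

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_outputs_bounded_by_tanh_head(self, seed):
        model = build_model(tiny_config(seed=seed))
        rng = np.random.default_rng(seed)
        p = (10 * rng.normal(size=(2, 3, 32, 32))).astype(np.float32)
        s = (10 * rng.normal(size=(2, 6, 32, 32))).astype(np.float32)
        out = model.forward(p, s)
        assert np.abs(out).max() <= 5.0

    @pytest.mark.parametrize("kw", [
        {},
        {"base_channels": 8, "supplementary_in_channels": 12},
        {"use_supplementary_encoder": False},
        {"use_primary_encoder": False},
        {"depth": 3, "decoder_blocks": 2},
    ])
    def test_parameter_count_matches_arithmetic_oracle(self, kw):
        cfg = tiny_config(**kw)
        model = build_model(cfg)
        assert model.n_parameters() == expected_parameter_count(cfg)

    def test_indivisible_dims_raise_with_pad_hint(self, rng):
        model = build_model(tiny_config())
        p = rng.normal(size=(1, 3, 30, 32)).astype(np.float32)
        s = rng.normal(size=(1, 6, 30, 32)).astype(np.float32)
        with pytest.raises(ConfigurationError, match="pad_volume"):
            model.forward(p, s)

    def test_both_encoders_disabled_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(use_primary_encoder=False,
                        use_supplementary_encoder=False)

    def test_save_load_roundtrip(self, rng, tmp_path):
        model = build_model(tiny_config())
        p = rng.normal(size=(1, 3, 16, 16)).astype(np.float32)
        s = rng.normal(size=(1, 6, 16, 16)).astype(np.float32)
        before = model.forward(p, s)
        model.save(tmp_path / "net.npz")
        loaded = DualEncoderDecoder.load(tmp_path / "net.npz")
        np.testing.assert_array_equal(loaded.forward(p, s), before)


def _toy_samples(n, rng, supp_ch=6, hw=(16, 16), cohort="healthy"):
    """Random inputs with smooth, bounded labels (like real Z-maps)."""
    from scipy.ndimage import gaussian_filter

    out = []
    for i in range(n):
        lab = np.stack([gaussian_filter(rng.normal(size=hw), 3.0)
                        for _ in range(2)])
        lab = np.clip(lab / np.abs(lab).max() * 3.0, -5, 5)
        out.append(TrainingSample(
            primary=rng.normal(size=(3,) + hw).astype(np.float32),
            supplementary=rng.normal(size=(supp_ch,) + hw).astype(np.float32),
            label=lab.astype(np.float32),
            subject_id=f"sub-{i:02d}", slice_index=0, cohort=cohort))
    return out


class TestSamplesAndAugment:
    def _grrs_stub(self, rng, shape=(20, 28, 6)):
        mk = lambda: VolumeMap(rng.normal(size=shape), units="zscore")
        return GrrsOutputs(beta0_z=mk(), beta1_z=mk(), cvr_z=mk(), bat_z=mk())

    def test_one_sample_per_nonempty_slice(self, rng):
        g = self._grrs_stub(rng)
        cc = CCStack(rng.normal(size=(4, 20, 28, 6)), np.arange(1, 5))
        labels = np.zeros((2, 32, 32, 6))
        brain = np.zeros((20, 28, 6), bool)
        brain[5:15, 5:20, 1:5] = True  # slices 1..4 populated
        samples = make_samples(g, cc, labels, brain)
        assert len(samples) == 4
        assert [s.slice_index for s in samples] == [1, 2, 3, 4]
        assert samples[0].primary.shape == (3, 32, 32)
        assert samples[0].supplementary.shape == (4, 32, 32)

    def test_channel_order_stable(self, rng):
        g = self._grrs_stub(rng)
        cc = CCStack(rng.normal(size=(4, 20, 28, 6)), np.arange(1, 5))
        labels = np.zeros((2, 32, 32, 6))
        brain = np.ones((20, 28, 6), bool)
        s = make_samples(g, cc, labels, brain)[2]
        from hemomap.preprocess import pad_volume

        np.testing.assert_allclose(
            s.primary[0], pad_volume(g.beta0_z).values[:, :, 2], atol=1e-6)
        np.testing.assert_allclose(
            s.primary[2], pad_volume(g.bat_z).values[:, :, 2], atol=1e-6)
        np.testing.assert_allclose(
            s.supplementary[3], pad_volume(VolumeMap(cc.maps[3])).values[:, :, 2],
            atol=1e-6)

    def test_double_flip_is_identity(self, rng):
        s = _toy_samples(1, rng)[0]
        twice = flip_sample(flip_sample(s, 1), 1)
        np.testing.assert_array_equal(twice.primary, s.primary)
        np.testing.assert_array_equal(twice.label, s.label)

    def test_flip_applies_jointly_to_inputs_and_labels(self, rng):
        s = _toy_samples(1, rng)[0]
        f = flip_sample(s, 1)
        np.testing.assert_array_equal(f.primary, s.primary[:, ::-1])
        np.testing.assert_array_equal(f.supplementary,
                                      s.supplementary[:, ::-1])
        np.testing.assert_array_equal(f.label, s.label[:, ::-1])

    def test_augmentation_only_for_flagged_cohorts(self, rng):
        healthy = _toy_samples(2, rng, cohort="healthy")
        patient = _toy_samples(3, rng, cohort="patient")
        hp = TrainingHyperparams(epochs=1)
        out = augment_cohort(healthy + patient, hp)
        assert len(out) == 2 + 3 * 3  # patients: original + h-flip + v-flip

    def test_augment_returns_requested_flips(self, rng):
        s = _toy_samples(1, rng)[0]
        assert len(augment(s, horizontal=True, vertical=True)) == 3
        assert len(augment(s, horizontal=False, vertical=False)) == 1


class TestKfold:
    def test_stratified_counts(self):
        ids = [f"s{i}" for i in range(10)]
        cohorts = ["healthy"] * 6 + ["patient"] * 4
        folds = kfold_split(ids, cohorts, k=5, seed=0)
        for f in range(5):
            members = [s for s, ff in folds.items() if ff == f]
            assert len(members) == 2
            n_pat = sum(1 for s in members if ids.index(s) >= 6)
            assert n_pat in (0, 1)

    def test_partition_is_disjoint_union(self):
        ids = [f"s{i}" for i in range(13)]
        cohorts = ["healthy"] * 7 + ["patient"] * 6
        folds = kfold_split(ids, cohorts, k=5, seed=3)
        assert set(folds) == set(ids)
        assert set(folds.values()) <= set(range(5))

    def test_seeded_reproducible(self):
        ids = [f"s{i}" for i in range(9)]
        cohorts = ["healthy"] * 9
        assert kfold_split(ids, cohorts, 3, seed=7) == kfold_split(
            ids, cohorts, 3, seed=7)

    def test_k_exceeding_n_raises(self):
        with pytest.raises(ConfigurationError):
            kfold_split(["a", "b"], ["healthy"] * 2, k=5)


class TestTraining:
    def test_same_seed_identical_histories(self, rng):
        samples = _toy_samples(6, rng)
        hp = TrainingHyperparams(epochs=3, batch_size=4, learning_rate=1e-3,
                                 seed=5)
        h1 = train(build_model(tiny_config(seed=2)), samples, hp)
        h2 = train(build_model(tiny_config(seed=2)), samples, hp)
        assert h1["train_l1"] == h2["train_l1"]

    def test_overfit_probe_converges(self, rng):
        """Four samples, 300 epochs on a small grid: the network memorizes
        them (final training L1 below 0.05)."""
        samples = _toy_samples(4, rng)
        hp = TrainingHyperparams(epochs=300, batch_size=4,
                                 learning_rate=1e-2, seed=0)
        model = build_model(tiny_config(seed=3))
        history = train(model, samples, hp)
        assert history["train_l1"][-1] < 0.05

    def test_ablated_model_trains(self, rng):
        samples = _toy_samples(4, rng)
        hp = TrainingHyperparams(epochs=2, batch_size=4, seed=0)
        model = build_model(tiny_config(use_supplementary_encoder=False))
        history = train(model, samples, hp)
        assert len(history["train_l1"]) == 2
        out = model.forward(np.stack([samples[0].primary]),
                            np.stack([samples[0].supplementary]))
        assert np.abs(out).max() <= 5.0 and np.all(np.isfinite(out))

    def test_empty_sample_list_raises(self):
        with pytest.raises(ConfigurationError):
            train(build_model(tiny_config()), [],
                  TrainingHyperparams(epochs=1))

    def test_flip_equivariance_after_symmetric_training(self, rng):
        """A model trained on samples plus their flips maps flipped inputs
        near the flipped outputs (up to border effects)."""
        base = _toy_samples(2, rng)
        samples = []
        for s in base:
            samples.extend(augment(s))
        hp = TrainingHyperparams(epochs=300, batch_size=6,
                                 learning_rate=5e-3, seed=0)
        model = build_model(tiny_config(seed=3))
        train(model, samples, hp)
        s = base[0]
        p = np.stack([s.primary])
        sp = np.stack([s.supplementary])
        out = model.predict(p, sp)
        out_flipped_in = model.predict(p[:, :, ::-1], sp[:, :, ::-1])
        cc = np.corrcoef(out[0].ravel(),
                         out_flipped_in[0, :, ::-1].ravel())[0, 1]
        assert cc > 0.9


class TestPredictVolume:
    def test_grid_roundtrip_and_bounds(self, rng):
        shape = (20, 28, 6)
        mk = lambda: VolumeMap(rng.normal(size=shape), units="zscore",
                               voxel_size_mm=(3.0, 3.0, 3.0))
        g = GrrsOutputs(beta0_z=mk(), beta1_z=mk(), cvr_z=mk(), bat_z=mk())
        cc = CCStack(rng.normal(size=(6, 20, 28, 6)), np.arange(1, 7))
        brain = rng.random(shape) > 0.4
        model = build_model(tiny_config())
        cvr, bat = predict_volume(model, g, cc, brain)
        assert cvr.shape == shape and bat.shape == shape
        assert cvr.voxel_size_mm == (3.0, 3.0, 3.0)
        assert np.abs(cvr.values).max() <= 5.0
        assert np.all(cvr.values[~brain] == 0.0)
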