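"""Network architecture, gradients, training mechanics, and prediction."""

import dataclasses

import numpy as np
import pytest

from rnfl_quant import (
    PhantomSpec,
    TrainConfig,
    UNetConfig,
    build_unet,
    expected_parameter_count,
    make_dataset,
    predict_mask,
    train_model,
)
from rnfl_quant.errors import ConfigurationError, ContractError, DataError
from rnfl_quant.images import BScanImage
from rnfl_quant.preprocess import denoise_morphological
from rnfl_quant.unet import SegmentationModel, bce_with_logits, split_scan_ids

TINY = UNetConfig(encoder_filters=(2, 4), input_size=8)
SMALL = UNetConfig(encoder_filters=(4, 8, 16), input_size=64)


class TestArchitecture:
    def test_forward_shape_and_probability_range(self):
        model = build_unet(SMALL, seed=0)
        x = np.random.default_rng(0).random((2, 64, 64), dtype=np.float32)
        proba = model.predict_proba(x)
        assert proba.shape == (2, 64, 64)
        assert np.all((proba > 0) & (proba < 1))

    def test_bottleneck_is_input_halved_per_level(self):
        # 5 levels halve the grid 4 times: 256 → 16 at the deepest encoder
        model = build_unet(UNetConfig(), seed=0)
        h = np.zeros((1, 256, 256, 1), dtype=np.float32)
        for lvl in range(len(model.enc) - 1):
            c1, c2 = model.enc[lvl]
            h = c2.forward(c1.forward(h, False), False)
            h = model.pools[lvl].forward(h, False)
        c1, c2 = model.enc[-1]
        bottleneck = c2.forward(c1.forward(h, False), False)
        assert bottleneck.shape == (1, 16, 16, 256)

    @pytest.mark.parametrize("config", [UNetConfig(), SMALL, TINY])
    def test_parameter_count_matches_closed_form(self, config):
        model = build_unet(config, seed=1)
        assert model.parameter_count() == expected_parameter_count(config)

    def test_default_filter_ladder(self):
        assert UNetConfig().encoder_filters == (16, 32, 64, 128, 256)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            UNetConfig(encoder_filters=(16, 16, 32))
        with pytest.raises(ConfigurationError):
            UNetConfig(encoder_filters=(8, 16, 32), input_size=250)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central finite differences."""
        rng = np.random.default_rng(7)
        model = build_unet(TINY, seed=7)
        x = rng.random((2, 8, 8), dtype=np.float32)
        y = (rng.random((2, 8, 8)) > 0.5).astype(np.float32)

        def loss_value():
            z = model.forward_logits(x.astype(np.float64), train=False)
            return bce_with_logits(z, y)[0]

        logits = model.forward_logits(x, train=True)
        _, dlogits = bce_with_logits(logits, y)
        model.backward(dlogits)
        grads = model.gradients()
        params = model.parameters()
        eps = 1e-3
        checked, agreeing = 0, 0
        for p, g in zip(params, grads):
            flat = p.ravel()
            gflat = np.asarray(g).ravel()
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_value()
                flat[idx] = orig - eps
                down = loss_value()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                # bias steps shift every activation in the layer, so the
                # difference quotient routinely crosses ReLU kinks; the
                # tolerance is loose enough for that but far below the
                # gradient scale a sign or indexing error would produce
                ok = abs(gflat[idx] - numeric) <= max(2e-3, 0.1 * abs(numeric))
                agreeing += ok
                checked += 1
        assert checked >= 30
        assert agreeing == checked, f"{agreeing}/{checked} gradients agree"


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    spec = PhantomSpec.for_group(
        "control", width_ascans=64, height_px=64, axial_spacing_um=5.0, ilm_depth_px=10
    )
    out = tmp_path_factory.mktemp("tiny_ds")
    return make_dataset(10, spec, seed=5, out_dir=out)


class TestTraining:
    def test_eighty_twenty_split_by_scan(self):
        train, val = split_scan_ids([f"s{i}" for i in range(10)], 0.8, seed=0)
        assert len(train) == 8 and len(val) == 2
        assert set(train).isdisjoint(val)

    def test_training_reduces_loss_on_repeated_phantom(self, tiny_dataset):
        # overfit sanity contract on a handful of 64×64 phantoms
        model = build_unet(SMALL, seed=3)
        tc = TrainConfig(epochs=8, batch_size=4, seed=3, learning_rate=3e-3)
        model, history = train_model(model, tiny_dataset, tc)
        assert history.train_loss.iloc[-1] < history.train_loss.iloc[0]
        assert np.isfinite(history[["train_loss", "val_loss"]].to_numpy()).all()

    def test_training_is_deterministic_given_seed(self, tiny_dataset):
        results = []
        for _ in range(2):
            model = build_unet(SMALL, seed=9)
            tc = TrainConfig(epochs=2, batch_size=4, seed=9)
            model, history = train_model(model, tiny_dataset, tc)
            results.append(history.val_loss.iloc[-1])
        assert results[0] == results[1]

    def test_empty_dataset_rejected(self, tiny_dataset):
        import pandas as pd

        from rnfl_quant.synthetic import DatasetManifest

        empty = DatasetManifest(frame=tiny_dataset.frame.iloc[:0], root=tiny_dataset.root)
        with pytest.raises(DataError):
            train_model(build_unet(SMALL, seed=0), empty, TrainConfig(epochs=1))


class TestPrediction:
    def test_output_strictly_binary_and_same_dims(self, tiny_dataset):
        from rnfl_quant.images import load_bscan

        model = build_unet(SMALL, seed=0)
        image = load_bscan(tiny_dataset.root / tiny_dataset.frame.image.iloc[0])
        mask = predict_mask(model, image)
        assert mask.pixels.dtype == bool
        assert mask.pixels.shape == image.pixels.shape

    def test_threshold_controls_binarisation(self):
        # raising the threshold can only shrink the predicted foreground
        model = build_unet(SMALL, seed=2)
        image = BScanImage(np.random.default_rng(4).random((64, 64)))
        lo = predict_mask(model, image, threshold=0.4)
        hi = predict_mask(model, image, threshold=0.6)
        assert np.all(hi.pixels <= lo.pixels)

    def test_large_scan_prediction_returns_original_dims(self):
        model = build_unet(SMALL, seed=0)
        small_model_cfg = dataclasses.replace(model.config, input_size=64)
        assert small_model_cfg.input_size == 64
        image = BScanImage(np.random.default_rng(1).random((96, 128)))
        mask = predict_mask(model, image)
        assert mask.pixels.shape == (96, 128)

    def test_inconsistent_scale_info_rejected(self):
        from rnfl_quant.preprocess import ScaleInfo

        model = build_unet(SMALL, seed=0)
        image = BScanImage(np.random.default_rng(1).random((64, 64)))
        wrong = ScaleInfo(
            scale_factor=1.0,
            pad_top=0,
            pad_left=0,
            original_height=50,
            original_width=50,
            target=64,
        )
        with pytest.raises(ContractError):
            predict_mask(model, image, scale=wrong)

    def test_checkpoint_round_trip(self, tmp_path):
        model = build_unet(SMALL, seed=6)
        model.save(tmp_path / "model")
        loaded = SegmentationModel.load(tmp_path / "model")
        x = np.random.default_rng(0).random((1, 64, 64), dtype=np.float32)
        np.testing.assert_array_equal(model.predict_proba(x), loaded.predict_proba(x))
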