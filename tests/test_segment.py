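import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import phasorflim as pf
from phasorflim.benchmarks import default_models, make_segmentation_dataset
from phasorflim.segment import MultimodalInput, postprocess_binary
from conftest import foreground_iou


class TestPreprocess:
    def test_constant_plane_becomes_ones(self):
        p = np.full((8, 8), 7.0)
        x = pf.preprocess(p, p, p, p)
        np.testing.assert_allclose(x.data, 1.0)

    def test_outlier_clipped_before_scaling(self):
        p = np.ones((20, 20))
        p[0, 0] = 1e6
        x = pf.preprocess(p, p, p, p)
        # the outlier is clipped to the 0.99-quantile value, so after
        # max-normalization the bulk of the image is at 1, not ~1e-6
        assert np.median(x.data[0]) == pytest.approx(1.0)

    def test_output_in_unit_interval_and_nan_free(self, rng):
        p = rng.exponential(50.0, size=(32, 32))
        t = np.where(rng.random((32, 32)) < 0.3, np.nan, rng.uniform(0, 4, (32, 32)))
        x = pf.preprocess(p, p, t, t)
        assert np.isfinite(x.data).all()
        assert x.data.min() >= 0 and x.data.max() <= 1.0

    def test_misaligned_planes_rejected(self):
        with pytest.raises(ValueError):
            pf.preprocess(np.ones((4, 4)), np.ones((5, 4)),
                          np.ones((4, 4)), np.ones((4, 4)))


class TestPostprocess:
    def test_diagonal_blobs_are_one_label(self):
        b = np.zeros((8, 8), dtype=bool)
        b[1:3, 1:3] = True
        b[3:5, 3:5] = True  # touches the first blob only diagonally
        mask = postprocess_binary(b, area_threshold=1)
        assert mask.n_labels == 1

    def test_small_labels_removed_at_threshold(self):
        b = np.zeros((12, 12), dtype=bool)
        b[1:4, 1:4] = True   # area 9
        b[8:10, 8:12] = True  # area 8
        mask = postprocess_binary(b, area_threshold=9)
        assert mask.n_labels == 1 and mask.areas.tolist() == [9]

    @given(hnp.arrays(bool, (24, 24)))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_idempotent_and_partition(self, b):
        m1 = postprocess_binary(b, area_threshold=4)
        m2 = postprocess_binary(m1.foreground, area_threshold=4)
        np.testing.assert_array_equal(m1.labels, m2.labels)
        assert m1.areas.sum() == m1.foreground.sum()
        if m1.n_labels:
            assert m1.areas.min() >= 4


class TestClassical:
    def test_recovers_planted_cell_count(self):
        scene = pf.SceneSpec(layer=pf.Layer.dermis, image_size=320, n_cells=20)
        stack, _, labels = pf.simulate_stack(scene, default_models(), seed=42)
        cals = pf.calibrate_channels(stack.meta)
        maps = pf.analyze_stack(stack, cals)
        x = pf.preprocess(maps["NADPH"].phasor.intensity,
                          maps["FAD"].phasor.intensity,
                          maps["NADPH"].tau_phi, maps["FAD"].tau_phi)
        mask = pf.classical_mask(x)
        assert 18 <= mask.n_labels <= 22
        assert foreground_iou(mask, labels) >= 0.7

    def test_blank_scene_empty(self):
        x = MultimodalInput(data=np.zeros((4, 32, 32)))
        assert pf.classical_mask(x).n_labels == 0


@pytest.fixture(scope="module")
def tiny_data():
    return make_segmentation_dataset(6, image_size=96, n_cells=3, seed=5)


class TestUNet:

    def test_training_deterministic_same_seed(self, tiny_data):
        X = [x for x, _ in tiny_data]
        y = [m for _, m in tiny_data]
        h = [pf.UNetSegmenter(epochs=2, random_state=3).fit(X, y).weights_hash()
             for _ in range(2)]
        assert h[0] == h[1]

    def test_dataset_smaller_than_batch_rejected(self, tiny_data):
        X = [tiny_data[0][0]]
        y = [tiny_data[0][1]]
        with pytest.raises(ValueError, match="batch"):
            pf.UNetSegmenter(batch_size=4).fit(X, y)

    def test_save_load_round_trip(self, tiny_data, tmp_path):
        X = [x for x, _ in tiny_data]
        y = [m for _, m in tiny_data]
        model = pf.UNetSegmenter(epochs=2, random_state=0).fit(X, y)
        model.save(tmp_path / "m")
        loaded = pf.UNetSegmenter.load(tmp_path / "m")
        assert loaded.weights_hash() == model.weights_hash()
        np.testing.assert_allclose(loaded.predict_proba(X[0]),
                                   model.predict_proba(X[0]))

    def test_predict_mask_shares_postprocessing_contract(self, tiny_data):
        X = [x for x, _ in tiny_data]
        y = [m for _, m in tiny_data]
        model = pf.UNetSegmenter(epochs=2, random_state=0).fit(X, y)
        prob = model.predict_proba(X[0])
        direct = postprocess_binary(prob >= 0.5, model.area_threshold)
        np.testing.assert_array_equal(model.predict(X[0]).labels, direct.labels)

    def test_augmented_training_robust_to_contrast_shift(self, tiny_data):
        """Training with gamma/log contrast augmentation stays non-inferior
        under in-family contrast perturbation of held-out scenes.  (The
        synthetic benchmark lacks the acquisition-to-acquisition contrast
        drift of real tissue data, so augmentation yields parity rather than
        a clear win here; the test pins non-inferiority and that the
        augmented model still segments perturbed scenes.)"""
        X = [x for x, _ in tiny_data]
        y = [m for _, m in tiny_data]
        held_out = make_segmentation_dataset(4, image_size=96, n_cells=3,
                                             seed=321)
        on = pf.UNetSegmenter(epochs=10, random_state=0, augment=True).fit(X, y)
        off = pf.UNetSegmenter(epochs=10, random_state=0, augment=False).fit(X, y)
        assert on.weights_hash() != off.weights_hash()

        def mean_iou(model):
            vals = []
            for x, truth in held_out:
                for gamma in (0.6, 1.8):
                    xp = MultimodalInput(data=np.clip(x.data, 0, 1) ** gamma)
                    vals.append(foreground_iou(model.predict(xp), truth))
            return float(np.mean(vals))

        iou_on, iou_off = mean_iou(on), mean_iou(off)
        assert iou_on >= iou_off - 0.02
        assert iou_on >= 0.5

    def test_low_probability_gives_empty_mask(self, tiny_data):
        X = [x for x, _ in tiny_data]
        y = [m for _, m in tiny_data]
        model = pf.UNetSegmenter(epochs=2, random_state=0).fit(X, y)
        mask = pf.predict_mask(model, X[0], prob_threshold=1.1)
        assert mask.n_labels == 0


class TestRoiStatistics:
    def _maps(self, f_values, meta, intensity=None):
        """Build metabolic maps whose pixels sit on the free-bound chord."""
        a = pf.monoexp_phasor(0.4, meta.omega)
        b = pf.monoexp_phasor(3.2, meta.omega)
        z = (1 - f_values) * a + f_values * b
        inten = np.full(f_values.shape, 100.0) if intensity is None else intensity
        ph = pf.PhasorImage(g=z.real, s=z.imag, intensity=inten, harmonic=1,
                            omega=meta.omega, calibrated=True, channel="NADPH")
        return pf.metabolic_maps(ph, anchor_taus=(0.4, 3.2),
                                 intensity_threshold=0.0)

    def test_uniform_map_roi_equals_pixel_value(self, meta):
        maps = self._maps(np.full((6, 6), 0.37), meta)
        rows = pf.roi_statistics(maps, unit="roi")
        assert rows.f_bound.iloc[0] == pytest.approx(0.37, abs=1e-12)

    def test_cells_never_pooled_in_cell_mode(self, meta):
        f = np.zeros((6, 6))
        labels = np.zeros((6, 6), dtype=int)
        f[1:3, 1:3], labels[1:3, 1:3] = 0.2, 1
        f[4:6, 4:6], labels[4:6, 4:6] = 0.4, 2
        rows = pf.roi_statistics(self._maps(f, meta), labels, unit="cell")
        assert sorted(rows.f_bound.round(6)) == [0.2, 0.4]
        assert (rows.unit_type == "cell").all()

    def test_mean_phasor_equals_mean_fraction_on_chord(self, meta, rng):
        """Aggregating the phasor then deriving fB equals averaging per-pixel
        fB, for pixels on the chord with equal weights (linearity)."""
        f = rng.uniform(0.1, 0.9, size=(10, 10))
        maps = self._maps(f, meta)
        rows = pf.roi_statistics(maps, unit="roi", intensity_weighted=False)
        assert rows.f_bound.iloc[0] == pytest.approx(f.mean(), abs=1e-9)

    def test_cell_mode_requires_mask(self, meta):
        with pytest.raises(ValueError):
            pf.roi_statistics(self._maps(np.full((4, 4), 0.5), meta),
                              unit="cell")
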