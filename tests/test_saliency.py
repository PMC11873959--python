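"""Localization: element-wise Grad-CAM, explainability gating, peak maps."""

import numpy as np
import pytest

import longchange as lc
from longchange.data import ImageRecord, LongitudinalPair
from longchange.model import ComparisonNetwork, ModelConfig
from longchange.saliency import (SaliencyResult, explainability_score,
                                 modified_gradcam, population_peak_map,
                                 upsample_nearest)

from conftest import occlusion_peak


def _pair(img1, img2):
    return LongitudinalPair(ImageRecord("s", 0.0, image=img1),
                            ImageRecord("s", 1.0, image=img2))


def _stub_net(seed=0, size=32):
    return ComparisonNetwork(ModelConfig(image_size=size, seed=seed))


def _restrict_head_to_cell(net, cell, image):
    """Make the head read one coarse-grid cell only, with a positive
    contribution for the given image (w aligned with its activations)."""
    from longchange.data import minmax_normalize

    C, h, w = net.extractor.coarse_shape
    net.features(minmax_normalize(image)[None])
    acts = net.extractor.last_activation[0]
    mask = np.zeros((C, h, w), np.float32)
    mask[:, cell[0], cell[1]] = 1.0
    net.head.params["w"] = (mask * acts).astype(np.float32).ravel()


class TestModifiedGradcam:
    def test_zero_head_gives_all_zero_map(self, rng):
        net = _stub_net()
        net.head.params["w"] = np.zeros_like(net.head.w)
        sal = modified_gradcam(net, _pair(*rng.random((2, 32, 32), np.float32)))
        assert np.all(sal.coarse_map == 0)
        assert np.all(sal.upsampled_map == 0)

    def test_map_nonnegative_and_peak_is_argmax(self, rng):
        net = _stub_net(seed=3)
        sal = modified_gradcam(net, _pair(*rng.random((2, 32, 32), np.float32)))
        assert (sal.coarse_map >= 0).all()
        assert sal.coarse_map[sal.peak] == sal.coarse_map.max()

    def test_single_cell_head_puts_peak_in_that_cell(self, rng):
        net = _stub_net(seed=4, size=64)
        cell = (1, 2)
        img = rng.random((64, 64), np.float32)
        _restrict_head_to_cell(net, cell, img)
        sal = modified_gradcam(net, _pair(img, rng.random((64, 64), np.float32)),
                               branch="first")
        assert sal.peak == cell

    def test_occlusion_oracle_agrees_on_stub_models(self, rng):
        """Independent oracle: occluding the image region the head reads
        must perturb r the most.  The oracle localizes at patch resolution
        with one cell of smear (coarse-cell receptive fields overlap
        neighbouring patches), so its region is the argmax patch plus its
        8-neighbourhood; the Grad-CAM peak must fall inside it."""
        agree = 0
        n_stubs = 12
        for k in range(n_stubs):
            net = _stub_net(seed=100 + k, size=64)
            cell = (int(rng.integers(0, 4)), int(rng.integers(0, 4)))
            img = (rng.random((64, 64), np.float32) * 0.5 + 0.25).astype(np.float32)
            other = (rng.random((64, 64), np.float32) * 0.5 + 0.25).astype(np.float32)
            _restrict_head_to_cell(net, cell, img)
            sal = modified_gradcam(net, _pair(img, other), branch="first")
            score_fn = lambda x: net.compare_arrays(x, other).logit
            oracle_cell = occlusion_peak(score_fn, img, patch=16)
            cheb = max(abs(a - b) for a, b in zip(sal.peak, oracle_cell))
            agree += (cheb <= 1)
        assert agree / n_stubs >= 0.9

    def test_negated_head_moves_peak_to_suppressed_signal(self, rng):
        net = _stub_net(seed=5)
        img_pair = _pair(*rng.random((2, 32, 32), np.float32))
        sal_pos = modified_gradcam(net, img_pair, branch="first")
        net.head.params["w"] = -net.head.params["w"]
        sal_neg = modified_gradcam(net, img_pair, branch="first")
        # maps are ReLUs of opposite-signed fields: they cannot co-peak
        # unless everything is zero
        assert sal_pos.coarse_map.max() > 0
        overlap = sal_pos.coarse_map * sal_neg.coarse_map
        assert np.all(overlap == 0)

    def test_branch_choice_flips_gradient_sign(self, rng):
        net = _stub_net(seed=6)
        img = rng.random((32, 32), np.float32)
        p = _pair(img, img.copy())
        first = modified_gradcam(net, p, branch="first")
        second = modified_gradcam(net, p, branch="second")
        # same activations, opposite gradient: their supports are disjoint
        assert np.all(first.coarse_map * second.coarse_map == 0)


class TestExplainabilityScore:
    @pytest.mark.parametrize("y,y_hat,y_bar,expected", [
        (2.0, 2.0, 0.0, 1.0),   # perfect prediction
        (2.0, 0.0, 0.0, 0.0),   # no better than the mean baseline
        (3.0, 2.0, 1.0, 0.75),  # 1 - 1/4
    ])
    def test_worked_values(self, y, y_hat, y_bar, expected):
        assert explainability_score(y, y_hat, y_bar) == pytest.approx(expected)

    def test_undefined_at_baseline_returns_nan_sentinel(self):
        assert np.isnan(explainability_score(1.0, 0.9, 1.0))


class TestPopulationPeakMap:
    def _result(self, peak, tau, grid=(4, 4), full=(16, 16)):
        coarse = np.zeros(grid)
        coarse[peak] = 1.0
        return SaliencyResult(coarse, upsample_nearest(coarse, full), peak,
                              logit=1.0, tau=tau)

    def test_single_case_is_upsampled_indicator(self):
        avg = population_peak_map([self._result((2, 3), 0.9)])
        expected = np.zeros((16, 16))
        expected[8:12, 12:16] = 1.0
        np.testing.assert_array_equal(avg, expected)

    def test_identical_peaks_average_to_one_indicator(self):
        results = [self._result((1, 1), 0.8) for _ in range(3)]
        np.testing.assert_array_equal(population_peak_map(results),
                                      results[0].upsampled_map)

    def test_distinct_peaks_conserve_total_mass(self):
        results = [self._result((i, i), 0.9) for i in range(4)]
        avg = population_peak_map(results)
        # each indicator has 16 pixels of mass; average preserves it
        assert avg.sum() == pytest.approx(16.0)

    def test_low_tau_cases_excluded_and_empty_set_raises(self):
        results = [self._result((0, 0), 0.9), self._result((3, 3), 0.2),
                   self._result((2, 2), float("nan"))]
        avg = population_peak_map(results, tau_threshold=0.7)
        assert avg[0, 0] == 1.0 and avg[12, 12] == 0.0
        with pytest.raises(ValueError, match="0.99"):
            population_peak_map(results, tau_threshold=0.99)


def test_peak_ties_resolved_to_lowest_linear_index():
    coarse = np.ones((3, 3))
    peak = tuple(int(i) for i in
                 np.unravel_index(np.argmax(coarse), coarse.shape))
    assert peak == (0, 0)
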