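"""T2 fitting: closed-form oracles, generative recovery, degenerate inputs."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from t2flux import (
    EchoStack,
    compute_t2_average,
    compute_t2_map,
    fit_pixel_decay,
    render_echo_stack,
)


def exp_decay(s0, t2, te):
    return s0 * np.exp(-np.asarray(te, float) / t2)


class TestFitPixelDecay:
    def test_noiseless_recovery_at_default_tes(self, te_list):
        fit = fit_pixel_decay(exp_decay(100.0, 68.0, te_list), te_list)
        assert fit.defined
        assert fit.s0 == pytest.approx(100.0, rel=1e-6)
        assert fit.t2_ms == pytest.approx(68.0, rel=1e-6)

    def test_two_point_closed_form(self, te_list):
        # S(12.5)=80, S(162.5)=20 on an exact exponential:
        # t2 = (162.5-12.5)/ln(80/20) = 150/ln 4 = 108.202...
        t2_true = 150.0 / math.log(4.0)
        s0_true = 80.0 / math.exp(-12.5 / t2_true)
        fit = fit_pixel_decay(exp_decay(s0_true, t2_true, te_list), te_list)
        assert fit.t2_ms == pytest.approx(t2_true, rel=1e-6)
        assert fit.t2_ms == pytest.approx(108.20, abs=5e-3)

    @pytest.mark.parametrize("i,j", [(0, 9), (2, 5), (1, 8), (4, 7)])
    def test_matches_pairwise_closed_form_oracle(self, te_list, i, j):
        """Any echo pair of a noiseless exponential gives the same T2 as the fit."""
        s = exp_decay(73.0, 91.0, te_list)
        oracle = (te_list[j] - te_list[i]) / math.log(s[i] / s[j])
        fit = fit_pixel_decay(s, te_list)
        assert fit.t2_ms == pytest.approx(oracle, rel=1e-6)

    def test_constant_signal_flagged_undefined(self, te_list):
        fit = fit_pixel_decay(np.full(10, 50.0), te_list)
        assert not fit.defined
        assert math.isnan(fit.t2_ms)

    def test_all_nonpositive_flagged_not_raised(self, te_list):
        fit = fit_pixel_decay(np.zeros(10), te_list)
        assert not fit.defined

    def test_fewer_than_three_echoes_raises(self):
        with pytest.raises(ValueError):
            fit_pixel_decay([10.0, 5.0], [10.0, 20.0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), t2=st.floats(20.0, 150.0))
    def test_scale_equivariance(self, scale, t2):
        """Scaling intensities scales s0 and leaves t2 unchanged."""
        te = np.array([12.5, 29.2, 45.8, 62.5, 79.2, 95.8, 112.5, 129.2, 145.8, 162.5])
        base = exp_decay(100.0, t2, te)
        f1 = fit_pixel_decay(base, te)
        f2 = fit_pixel_decay(scale * base, te)
        assert f2.s0 == pytest.approx(scale * f1.s0, rel=1e-5)
        assert f2.t2_ms == pytest.approx(f1.t2_ms, rel=1e-6)


class TestComputeT2Map:
    def test_noiseless_phantom_recovers_tissue_t2(self, noiseless_phantom):
        lm, stack = noiseless_phantom
        t2map = compute_t2_map(stack, mask=lm.labels > 0)
        for tissue, expected in (("brain", 47.0), ("tumor", 68.0), ("csf", 125.0)):
            sel = lm.tissue_mask(tissue)
            assert t2map.defined[sel].all()
            med = float(np.median(t2map.t2_ms[sel]))
            assert med == pytest.approx(expected, rel=1e-6)

    def test_background_pixels_undefined(self, noiseless_phantom):
        lm, stack = noiseless_phantom
        t2map = compute_t2_map(stack)
        background = lm.labels == 0
        assert not t2map.defined[background].any()
        assert np.isnan(t2map.t2_ms[background]).all()

    def test_single_pixel_mask(self, noiseless_phantom):
        lm, stack = noiseless_phantom
        mask = np.zeros(stack.spatial_shape, dtype=bool)
        pix = tuple(np.argwhere(lm.tissue_mask("tumor"))[0])
        mask[pix] = True
        t2map = compute_t2_map(stack, mask=mask)
        assert t2map.defined.sum() == 1
        assert t2map.defined[pix]

    def test_noise_robustness_one_percent(self, small_spec):
        """Per-tissue median within 2% of truth at noise_sd/S0 = 1%."""
        from t2flux import build_label_map

        spec = dataclasses.replace(small_spec, noise_sd=1.0, seed=42)
        lm = build_label_map(spec, session_week=6)
        stack = render_echo_stack(lm, spec)
        t2map = compute_t2_map(stack, mask=lm.labels > 0)
        for tissue, expected in (("brain", 47.0), ("tumor", 68.0)):
            sel = lm.tissue_mask(tissue) & t2map.defined
            med = float(np.median(t2map.t2_ms[sel]))
            assert med == pytest.approx(expected, rel=0.02)

    def test_display_clamp_leaves_values_untouched(self, noiseless_phantom):
        lm, stack = noiseless_phantom
        t2map = compute_t2_map(stack, mask=lm.tissue_mask("csf"))
        csf = lm.tissue_mask("csf") & t2map.defined
        # stored values stay at ~125 ms; only the rendering is capped at 120
        assert np.median(t2map.t2_ms[csf]) == pytest.approx(125.0, rel=1e-6)
        assert t2map.clamped_for_display().max() <= t2map.display_clamp_ms


class TestComputeT2Average:
    def test_pixelwise_mean_of_selected_echoes(self, te_list):
        data = np.zeros((1, 1, 1, 10))
        sel = [np.abs(te_list - t).argmin() for t in (45.8, 62.5, 79.2)]
        data[0, 0, 0, sel] = [60.0, 50.0, 40.0]
        stack = EchoStack(data, te_list)
        avg = compute_t2_average(stack)
        assert avg.values[0, 0, 0] == pytest.approx(50.0)

    def test_noiseless_tumor_pixel_closed_form(self, noiseless_phantom):
        lm, stack = noiseless_phantom
        avg = compute_t2_average(stack)
        expected = 100.0 * np.mean(np.exp(-np.array([45.8, 62.5, 79.2]) / 68.0))
        tumor_vals = avg.values[lm.tissue_mask("tumor")]
        assert tumor_vals == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(40.69, abs=5e-3)

    def test_identical_echoes_average_to_themselves(self, te_list):
        img = np.random.default_rng(0).uniform(size=(2, 4, 4))
        data = np.repeat(img[..., None], 10, axis=3)
        avg = compute_t2_average(EchoStack(data, te_list))
        assert np.allclose(avg.values, img)

    def test_absent_te_raises_listing_available(self, te_list):
        stack = EchoStack(np.ones((1, 2, 2, 10)), te_list)
        with pytest.raises(ValueError, match="not present"):
            compute_t2_average(stack, te_subset_ms=[50.0])

    def test_window_applies_only_at_render(self, te_list):
        stack = EchoStack(np.ones((1, 2, 2, 10)) * 80.0, te_list)
        avg = compute_t2_average(stack, window=(0.0, 50.0))
        assert avg.values.max() == pytest.approx(80.0)
        assert avg.windowed_for_display().max() == pytest.approx(50.0)


class TestEchoStackValidation:
    def test_te_count_mismatch(self, te_list):
        with pytest.raises(ValueError, match="echoes"):
            EchoStack(np.ones((1, 2, 2, 9)), te_list)

    def test_non_monotone_tes(self):
        with pytest.raises(ValueError, match="increasing"):
            EchoStack(np.ones((1, 2, 2, 3)), [30.0, 20.0, 40.0])

    def test_nan_voxel_named(self, te_list):
        data = np.ones((1, 2, 2, 10))
        data[0, 1, 0, 3] = np.nan
        with pytest.raises(ValueError, match=r"\(0, 1, 0, 3\)"):
            EchoStack(data, te_list)
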