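"""Model evaluation, goodness of fit, SNR-based component counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gammasf import model as gm


def comp(label="LG", **kw):
    base = dict(sigma=4.0, K0=35.0, K=-10.0, n=2.0, A1=10.0, sigma1=0.5, A2=0.0, sigma2=0.1)
    base.update(kw)
    return gm.ComponentParams(label=label, **base)


class TestBaseline:
    def test_direct_substitution(self):
        p = gm.BaselineParams(k=1000.0, a=2.0, b=0.0, c=1.0)
        assert gm.eval_baseline(p, 10.0) == pytest.approx(11.0)

    def test_monotone_decreasing(self):
        p = gm.BaselineParams(k=5e3, a=1.3, b=7.0, c=0.2)
        f = np.linspace(20, 120, 300)
        assert np.all(np.diff(gm.eval_baseline(p, f)) < 0)

    def test_floor_only(self):
        p = gm.BaselineParams(k=0.0, a=1.0, b=0.0, c=5.0)
        assert gm.eval_baseline(p, 77.0) == pytest.approx(5.0)

    def test_rejects_nonpositive_frequency(self):
        p = gm.BaselineParams(k=1.0, a=1.0)
        with pytest.raises(ValueError):
            gm.eval_baseline(p, 0.0)


class TestMu:
    def test_sigmoid_endpoints_and_half_saturation(self):
        c = comp(K0=35.0, K=-10.0, n=2.0)
        assert gm.eval_mu(c, 0.5, 0.0) == pytest.approx(35.0)
        assert gm.eval_mu(c, 0.5, 0.5) == pytest.approx(30.0)  # K0 + K/2 at sf0
        assert gm.eval_mu(c, 0.5, 500.0) == pytest.approx(25.0, rel=1e-3)


class TestWeight:
    def test_origin_value(self):
        c = comp(A1=10.0, A2=3.0)
        assert gm.eval_weight(c, 0.0) == pytest.approx(7.0)
        c2 = comp(A1=3.0, A2=10.0)
        assert gm.eval_weight(c2, 0.0) == 0.0  # floored

    def test_pure_gaussian_half_maximum(self):
        c = comp(A1=8.0, sigma1=0.5, A2=0.0)
        cutoff = 0.5 * np.sqrt(2 * np.log(2))
        assert gm.eval_weight(c, cutoff) == pytest.approx(4.0)

    def test_bandpass_argmax_positive(self):
        # DoG with a strong narrow subtractive lobe peaks away from sf=0
        c = comp(A1=10.0, sigma1=0.5, A2=8.0, sigma2=0.1)
        grid = np.linspace(0, 3, 30001)
        assert grid[np.argmax(gm.eval_weight(c, grid))] > 0

    def test_raw_value_can_be_negative(self):
        c = comp(A1=3.0, A2=10.0, sigma1=0.5, sigma2=0.5)
        assert gm.eval_weight(c, 0.0, floor=False) == pytest.approx(-7.0)


class TestEvalModel:
    def test_baseline_only(self, gt3):
        from gammasf import synthetic as syn

        p = syn.make_ground_truth("no_gamma", 0).model_params
        f = np.linspace(20, 120, 50)
        sfs = np.array([0.03, 0.1, 0.3, 1.0, 2.5])
        expected = np.broadcast_to(gm.eval_baseline(p.baseline, f), (5, 50))
        np.testing.assert_allclose(gm.eval_model(p, sfs, f), expected)

    def test_peak_value_is_baseline_plus_weight(self, gt3):
        p = gt3.model_params
        sf = 0.2
        for c in p.components:
            mu = gm.eval_mu(c, p.sf0, sf)
            single = gm.ModelParams(
                baseline=p.baseline,
                components=tuple(
                    cc if cc.label == c.label else
                    gm.ComponentParams(cc.label, cc.sigma, cc.K0, cc.K, cc.n, 0.0, cc.sigma1)
                    for cc in p.components
                ),
                sf0=p.sf0,
            )
            expected = gm.eval_baseline(p.baseline, mu) + gm.eval_weight(c, sf)
            assert gm.eval_model(single, sf, mu)[0, 0] == pytest.approx(expected)

    def test_nonnegative_everywhere(self, gt3):
        out = gm.eval_model(gt3.model_params, np.linspace(0, 2.5, 40), np.linspace(20, 120, 101))
        assert np.all(out >= 0)


class TestGoodnessOfFit:
    def test_perfect_and_null(self):
        data = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert gm.goodness_of_fit(data, data) == pytest.approx(1.0)
        assert gm.goodness_of_fit(data, np.full_like(data, data.mean())) == pytest.approx(0.0)

    def test_worked_example(self):
        # SS_res = 1, SS_tot about the mean (2) = 2
        assert gm.goodness_of_fit([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            gm.goodness_of_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestComponentCounting:
    def test_direct_ratio(self, gt3):
        p = gt3.model_params
        freqs = np.linspace(20, 120, 101)
        blank = gm.eval_baseline(p.baseline, freqs)
        snrs = gm.component_snr(p, freqs, blank, np.asarray([0.03, 0.1, 0.2, 0.33, 0.7, 1.5, 2.5]))
        # amplitudes were calibrated for SNR 6 on a dense SF grid; the
        # sampled grid can only underestimate the max weight
        assert np.all(snrs > 4.0) and np.all(snrs <= 6.0 + 1e-9)

    def test_zero_amplitude_component(self):
        from gammasf import synthetic as syn

        p = syn.make_ground_truth("lg_only", 0).model_params
        freqs = np.linspace(20, 120, 101)
        snrs = gm.component_snr(p, freqs, gm.eval_baseline(p.baseline, freqs), np.linspace(0.03, 2.5, 7))
        assert snrs[1] == 0.0 and snrs[2] == 0.0

    @pytest.mark.parametrize(
        "snrs,expected",
        [((5, 4, 3.5), 3), ((3, 3, 3), 0), ((10, 1, 0), 1), ((12 / 4.0, 0, 0), 0)],
    )
    def test_strict_threshold(self, snrs, expected):
        assert gm.count_components(snrs) == expected

    @given(st.tuples(*[st.floats(0, 20) for _ in range(3)]))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_threshold(self, snrs):
        counts = [gm.count_components(snrs, t) for t in (0.0, 1.0, 3.0, 6.0, 100.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSiteSnr:
    def test_direct_ratio(self):
        rng = np.random.default_rng(0)
        blank = rng.standard_normal(200)
        res = gm.site_snr(3.0 * blank, blank)
        assert res.value == pytest.approx(3.0)
        assert not res.included  # strictly-greater-than rule

    def test_null_case(self):
        rng = np.random.default_rng(1)
        res = gm.site_snr(rng.standard_normal(50), rng.standard_normal(50))
        assert res.value == pytest.approx(1.0, abs=0.3)

    def test_degenerate_blank(self):
        res = gm.site_snr([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])
        assert res.degenerate and not res.included


class TestFitModel:
    def test_roundtrip_noiseless(self, gt3, noiseless_grid):
        fit = gm.fit_model(noiseless_grid, seed=0, restarts=8)
        assert fit.gof >= 0.999
        sfs = noiseless_grid.sfs
        for ct, cf in zip(gt3.model_params.components, fit.params.components):
            mu_t = gm.eval_mu(ct, gt3.model_params.sf0, sfs)
            mu_f = gm.eval_mu(cf, fit.params.sf0, sfs)
            assert np.max(np.abs(mu_t - mu_f)) < 0.5

    def test_mu_ordering_enforced(self, noiseless_grid):
        fit = gm.fit_model(noiseless_grid, seed=0, restarts=4)
        sfs = noiseless_grid.sfs
        mus = np.array([gm.eval_mu(c, fit.params.sf0, sfs) for c in fit.params.components])
        assert np.all(mus[0] < mus[1]) and np.all(mus[1] < mus[2])

    def test_baseline_only_counts_zero(self):
        from gammasf import synthetic as syn

        p = syn.make_ground_truth("no_gamma", 0).model_params
        sfs = np.asarray(syn.DEFAULT_SFS)
        freqs = np.linspace(20, 120, 101)
        from gammasf import spectral as sp

        grid = sp.SpectrumGrid(
            frequencies=freqs, sfs=sfs,
            power=gm.eval_model(p, sfs, freqs),
            blank_power=gm.eval_baseline(p.baseline, freqs),
        )
        fit = gm.fit_model(grid, seed=0, restarts=6)
        assert fit.n_components == 0

    def test_rejects_bad_grids(self, noiseless_grid):
        from gammasf import spectral as sp

        with pytest.raises(ValueError):
            gm.fit_model(
                sp.SpectrumGrid(
                    frequencies=noiseless_grid.frequencies,
                    sfs=noiseless_grid.sfs[:3],
                    power=noiseless_grid.power[:3],
                ),
                restarts=1,
            )
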