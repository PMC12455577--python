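"""Multi-pool decomposition, AUC conventions and stack fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from cestpipe.b0 import FieldMap, QUALITY
from cestpipe.fitting import (
    FitConfig,
    PoolFitSpec,
    default_fit_config,
    fit_stack,
    fit_voxel,
    model_zspectrum,
    pool_auc,
)
from cestpipe.io import ZSpectrumStack
from cestpipe.spectra import PoolSpec, lorentzian_line
from cestpipe.synthetic import PhantomConfig, generate_phantom_study, simulate_zspectrum


class TestModelZspectrum:
    def test_all_zero_amplitudes_give_unity(self, cest_schedule):
        pools = [PoolSpec(n, c, 0.0, 1.0) for n, c in
                 [("water", 0.0), ("MT", -2.5), ("CR", 2.0), ("GLU", 3.0), ("NOE", -3.5)]]
        assert np.all(model_zspectrum(pools, cest_schedule.offsets_ppm) == 1.0)

    def test_single_pool_is_one_minus_lorentzian(self, cest_schedule):
        pool = PoolSpec("GLU", 3.0, 0.05, 1.2)
        z = model_zspectrum([pool], cest_schedule.offsets_ppm)
        np.testing.assert_allclose(
            z, 1.0 - lorentzian_line(cest_schedule.offsets_ppm, pool), atol=0)

    def test_duplicate_pool_names_rejected(self, cest_schedule):
        pools = [PoolSpec("GLU", 3.0, 0.05, 1.2)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            model_zspectrum(pools, cest_schedule.offsets_ppm)


class TestFitVoxel:
    def test_noiseless_recovery(self, pools, cest_schedule):
        z = simulate_zspectrum(pools, cest_schedule)
        res = fit_voxel(z, cest_schedule.offsets_ppm, default_fit_config())
        assert res.converged
        for p in pools:
            f = res.pools[p.name]
            assert abs(f.amplitude / p.amplitude - 1) < 0.01, p.name
            assert abs(f.fwhm_ppm / p.fwhm_ppm - 1) < 0.02, p.name
            assert abs(f.center_ppm - p.center_ppm) < 0.02, p.name

    def test_flat_spectrum_yields_zero_cest_amplitudes(self, cest_schedule):
        res = fit_voxel(np.ones(51), cest_schedule.offsets_ppm, default_fit_config())
        for name in ("CR", "GLU", "NOE"):
            assert res.pools[name].amplitude < 1e-3

    def test_water_only_spectrum(self, cest_schedule):
        water = PoolSpec("water", 0.0, 0.8, 1.4)
        z = simulate_zspectrum([water], cest_schedule)
        res = fit_voxel(z, cest_schedule.offsets_ppm, default_fit_config())
        for name in ("CR", "GLU", "NOE"):
            assert res.pools[name].amplitude < 1e-3
        assert abs(res.pools["water"].amplitude / 0.8 - 1) < 0.01

    def test_too_few_offsets_skipped(self, cest_schedule):
        z = np.full(51, np.nan)
        z[:10] = 1.0
        assert fit_voxel(z, cest_schedule.offsets_ppm, default_fit_config()) is None

    def test_residual_not_worse_than_initialization(self, pools, cest_schedule):
        """Optimizer contract: returned solution never exceeds the
        initialization's residual."""
        cfg = default_fit_config(multistart_count=1)
        rng = np.random.default_rng(5)
        for seed in range(5):
            z = simulate_zspectrum(pools, cest_schedule, noise_sd=0.01, seed=seed)
            res = fit_voxel(z, cest_schedule.offsets_ppm, cfg, rng=rng)
            init = [PoolSpec(p.name, p.center_ppm, p.amp_init, p.fwhm_init)
                    for p in cfg.pools]
            init_rms = np.sqrt(np.mean(
                (model_zspectrum(init, cest_schedule.offsets_ppm) - z) ** 2))
            assert res.residual_rms <= init_rms + 1e-12

    def test_grid_oracle_agrees_with_fitter(self, pools, cest_schedule):
        """Brute-force grid search over (A_GLU, G_GLU), other pools fixed
        at truth, attains its minimum within one grid cell of the fit."""
        truth = {p.name: p for p in pools}
        z = simulate_zspectrum(pools, cest_schedule)
        res = fit_voxel(z, cest_schedule.offsets_ppm, default_fit_config())
        amps = np.linspace(0.0, 0.1, 41)      # cell 0.0025
        widths = np.linspace(0.2, 3.0, 57)    # cell 0.05
        others = [p for p in pools if p.name != "GLU"]
        base = model_zspectrum(others, cest_schedule.offsets_ppm)
        best, best_cost = None, np.inf
        for a in amps:
            for g in widths:
                zi = base - lorentzian_line(cest_schedule.offsets_ppm,
                                            PoolSpec("GLU", 3.0, a, g))
                cost = np.sum((zi - z) ** 2)
                if cost < best_cost:
                    best, best_cost = (a, g), cost
        fitted = res.pools["GLU"]
        assert abs(fitted.amplitude - best[0]) <= 0.0025 + 1e-12
        assert abs(fitted.fwhm_ppm - best[1]) <= 0.05 + 1e-12

    def test_precision_near_cramer_rao_and_monotone_in_noise(self, pools,
                                                             cest_schedule):
        """Single-voxel GLU amplitude precision is information-limited:
        the median relative error stays within 1.5x the Cramer-Rao bound
        for an unbiased estimator of the full 15-parameter model, and
        errors shrink as the noise does."""
        from cestpipe.fitting import _model_and_jac, _pack

        cfg = default_fit_config(multistart_count=1)
        truth = {p.name: p for p in pools}
        _, jac = _model_and_jac(_pack(pools), cest_schedule.offsets_ppm)
        cov_unit = np.linalg.inv(jac.T @ jac)  # covariance per unit noise^2
        i_glu = 3 * [p.name for p in pools].index("GLU")
        med_errs = []
        for noise in (0.0, 0.005):
            errs = []
            for seed in range(200):
                z = simulate_zspectrum(pools, cest_schedule, noise_sd=noise, seed=seed)
                res = fit_voxel(z, cest_schedule.offsets_ppm, cfg)
                errs.append(abs(res.pools["GLU"].amplitude /
                                truth["GLU"].amplitude - 1))
            med_errs.append(np.median(errs))
            if noise > 0:
                # median |N(0, sd)| = 0.6745 sd
                crlb_median_rel = (0.6745 * noise * np.sqrt(cov_unit[i_glu, i_glu])
                                   / truth["GLU"].amplitude)
                assert med_errs[-1] < 1.5 * crlb_median_rel
        assert med_errs[0] <= med_errs[1]


class TestPoolAuc:
    def test_zero_amplitude_zero_auc(self):
        pool = PoolSpec("GLU", 3.0, 0.0, 1.0)
        assert pool_auc(pool) == 0.0
        assert pool_auc(pool, "numeric_window", (-5, 5)) == 0.0

    def test_full_line_closed_form(self):
        assert pool_auc(PoolSpec("GLU", 3.0, 0.1, 1.0)) == pytest.approx(
            0.05 * np.pi, rel=1e-12)

    def test_windowed_matches_quadrature(self):
        pool = PoolSpec("GLU", 3.0, 0.1, 1.0)
        auc = pool_auc(pool, "numeric_window", (-5.0, 5.0))
        oracle, _ = quad(lambda w: lorentzian_line(w, pool), -5.0, 5.0,
                         epsabs=1e-13, epsrel=1e-13)
        assert abs(auc / oracle - 1) < 1e-8

    def test_window_missing_center_warns(self):
        with pytest.warns(UserWarning, match="window"):
            pool_auc(PoolSpec("NOE", -3.5, 0.1, 1.0), "numeric_window", (0.0, 5.0))

    @settings(deadline=None, max_examples=50)
    @given(amp=st.floats(0, 1), scale=st.floats(0, 10),
           fwhm=st.floats(0.1, 30), center=st.floats(-4, 4))
    def test_auc_linear_in_amplitude(self, amp, scale, fwhm, center):
        pool = PoolSpec("p", center, amp, fwhm)
        scaled = pool.scaled(scale)
        for conv in ("analytic_full_line", "numeric_window"):
            assert pool_auc(scaled, conv, (-5, 5)) == pytest.approx(
                scale * pool_auc(pool, conv, (-5, 5)), rel=1e-12, abs=1e-300)


@pytest.fixture(scope="module")
def fitted(small_noiseless_bundle):
    bundle = small_noiseless_bundle
    subj = bundle.subjects[0]
    stack = ZSpectrumStack(subj.cest, bundle.config.schedule.offsets_ppm,
                           bundle.mask, normalized=True)
    cfg = default_fit_config(multistart_count=1)
    return bundle, stack, cfg, fit_stack(stack, None, cfg)


class TestFitStack:
    def test_noiseless_phantom_converges_and_recovers_auc(self, fitted):
        bundle, stack, cfg, (maps, contrasts) = fitted
        assert maps.converged[bundle.mask].mean() >= 0.99
        subj = bundle.subjects[0]
        truth_amp = subj.truth_amplitude["GLU"]
        glu_width = [p for p in bundle.config.baseline_pools if p.name == "GLU"][0].fwhm_ppm
        truth_auc = truth_amp * glu_width * np.pi / 2
        conv = maps.converged & bundle.mask
        rel = np.abs(contrasts.auc["GLU"][conv] / truth_auc[conv] - 1)
        assert np.max(rel) < 0.02

    def test_nan_exactly_at_nonconverged_or_unmasked(self, fitted):
        bundle, stack, cfg, (maps, contrasts) = fitted
        finite = np.isfinite(contrasts.auc["GLU"])
        np.testing.assert_array_equal(finite, maps.converged & bundle.mask)

    def test_zero_field_correction_is_noop(self, fitted):
        bundle, stack, cfg, (maps, contrasts) = fitted
        fm = FieldMap(np.zeros(bundle.mask.shape),
                      np.full(bundle.mask.shape, QUALITY["ok"], dtype=np.int8))
        _, contrasts2 = fit_stack(stack, fm, cfg)
        for pool in contrasts.auc:
            np.testing.assert_array_equal(contrasts.auc[pool], contrasts2.auc[pool])

    def test_effect_ratio_propagates_to_auc_maps(self, cest_schedule):
        config = PhantomConfig(grid_shape=(16, 16), noise_sd=0.0, b0_amplitude_ppm=0.0,
                               effects={("ART", "thalamus", "GLU"): 0.7})
        bundle = generate_phantom_study(config)
        cfg = default_fit_config(multistart_count=1)
        th = config.resolved_layout()["thalamus"]
        by_group = {}
        for (sid, g), subj in zip(bundle.design, bundle.subjects):
            if g in by_group or g not in ("ART", "vehicle"):
                continue
            stack = ZSpectrumStack(subj.cest, cest_schedule.offsets_ppm, bundle.mask,
                                   normalized=True)
            _, contrasts = fit_stack(stack, None, cfg)
            by_group[g] = np.nanmean(contrasts.auc["GLU"][th])
        ratio = by_group["ART"] / by_group["vehicle"]
        assert 0.65 <= ratio <= 0.75
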