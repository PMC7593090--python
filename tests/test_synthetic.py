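"""Generators and stochastic oracles: determinism, noise models,
telegraph statistics, multi-tau estimator correctness."""

import numpy as np
import pytest
import scipy.stats

from petfcs import (
    RateSet,
    build_scheme,
    fit_empirical_acf,
    generate_truth_presets,
    gillespie_intensity_trace,
    multitau_autocorrelate,
    simulate_dynamic_component,
    strip_static_components,
    synthesize_acf_dataset,
    synthesize_decay_panel,
    synthesize_fpa_bands,
)
from petfcs.fpa import build_force_profile, fraction_full_length
from petfcs.kinetics import without_trp_quenching
from petfcs.synthetic import (
    bright_dwell_times,
    direct_autocorrelation,
    expected_multitau_response,
    paper_like_force_profile_truth,
    TruthConfig,
)


class TestTruthPresets:
    def test_same_seed_same_config(self, tmp_path):
        a = generate_truth_presets("paper-like-5eH", seed=1)
        b = generate_truth_presets("paper-like-5eH", seed=1)
        assert a.rates.keys() == b.rates.keys()
        for c in a.rates:
            assert a.rates[c].values == b.rates[c].values
        # and the YAML round trip is lossless
        a.to_yaml(tmp_path / "truth.yaml")
        back = TruthConfig.from_yaml(tmp_path / "truth.yaml")
        for c in a.rates:
            assert back.rates[c].values == pytest.approx(a.rates[c].values)

    def test_rates_within_reported_regimes(self):
        t = generate_truth_presets("paper-like-5eH", seed=5)
        for rates in t.rates.values():
            assert 0.01e6 <= rates["kon_Wc"] <= 0.1e6
            assert 3e6 <= rates["kon_Wd"] <= 8e6
            assert 5e6 <= rates["kon_Rd"] <= 11e6
            assert rates["koff_Rd"] == pytest.approx(0.3e6)
            assert rates["koff_Wd"] == pytest.approx(2.2e6)

    def test_two_state_toy_and_unknown(self):
        t = generate_truth_presets("two-state-toy", seed=0)
        assert t.scheme_preset == "two-state"
        with pytest.raises(ValueError):
            generate_truth_presets("no-such-preset", seed=0)


class TestACFDataset:
    def test_noise_free_dataset_matches_model_composition(self):
        truth = generate_truth_presets("paper-like-5eH", seed=2)
        truth.noise_sd = 0.0
        curves = synthesize_acf_dataset(truth)
        assert len(curves) == len(truth.panel)
        scheme = truth.scheme()
        c0 = curves[0]
        rates = truth.rates[c0.construct]
        y = simulate_dynamic_component(scheme, rates, c0.lags).values
        env = truth.envelope
        trip = (1 - env.F + env.F * np.exp(-env.kf * c0.lags)) / (1 - env.F)
        diff = 1.0 / (env.N * (1 + env.kd * c0.lags))
        assert np.allclose(c0.amplitudes, (1 + y) * trip * diff, rtol=1e-12)

    @pytest.mark.parametrize("scaling", ["flat", "sqrt"])
    def test_noise_sd_follows_scaling_law(self, scaling):
        truth = generate_truth_presets("two-state-toy", seed=3)
        truth.noise_sd = 0.02
        truth.noise_scaling = scaling
        reps = []
        for s in range(100):
            truth.seed = s
            reps.append(synthesize_acf_dataset(truth)[0].amplitudes)
        stack = np.vstack(reps)
        lags = generate_truth_presets("two-state-toy", seed=3).lag_grid()
        if scaling == "flat":
            expected_rel = np.full_like(lags, 0.02)
        else:
            expected_rel = 0.02 * np.minimum(np.sqrt(lags / truth.lag_min), 10.0)
        mean = stack.mean(axis=0)
        rel_sd = stack.std(axis=0, ddof=1) / np.abs(mean)
        # compare where the signal is well above the noise floor and the
        # multiplicative model is not in its large-noise regime
        mask = (np.abs(mean) > 1e-3) & (expected_rel < 0.5)
        ratio = rel_sd[mask] / expected_rel[mask]
        assert np.all((ratio > 0.7) & (ratio < 1.4))

    def test_w6f_member_has_no_trp_signature(self):
        """The Trp-free control decay must equal the same network with its
        Trp-quenching edges removed."""
        truth = generate_truth_presets("paper-like-5eH", seed=4)
        truth.noise_sd = 0.0
        scheme = truth.scheme()
        curves = synthesize_acf_dataset(truth)
        w6f = next(c for c in curves if not c.trp_present)
        stripped = strip_static_components(w6f, truth.envelope, envelope_floor=0.0)
        rates_ref = without_trp_quenching(scheme, truth.rates[w6f.construct])
        y_ref = simulate_dynamic_component(scheme, rates_ref, stripped.lags).values
        assert np.allclose(stripped.values, y_ref, rtol=1e-9, atol=1e-12)

    def test_zero_noise_envelope_recovery_through_workflow(self):
        """The shared-envelope fit over a W6/W6F pair recovers the
        diffusion and molecule-number truth.  The triplet amplitude and
        rate are only loosely pinned (a triplet is one more exponential,
        partially degenerate with tens-of-µs kinetic modes even without
        noise); they must stay inside the physical box, and the barrier
        recovery test is the end-to-end check that the residual envelope
        error is inconsequential."""
        from petfcs.workflows import TRIPLET_BOUNDS, fit_and_strip

        truth = generate_truth_presets("paper-like-5eH", seed=6)
        truth.noise_sd = 0.0
        truth.panel = [m for m in truth.panel if m.construct == "hemk70_wt"]
        curves = synthesize_acf_dataset(truth)
        decays, fits = fit_and_strip(curves, seed=1, n_starts=8)
        fit = next(iter(fits.values()))[0]
        env = truth.envelope
        assert fit.kd == pytest.approx(env.kd, rel=0.1)
        assert fit.N == pytest.approx(env.N, rel=0.1)
        assert TRIPLET_BOUNDS["kf"][0] <= fit.kf <= TRIPLET_BOUNDS["kf"][1]
        assert fit.F <= TRIPLET_BOUNDS["F"][1]


class TestDecayPanel:
    def test_additive_noise_level(self):
        truth = generate_truth_presets("paper-like-5eH", seed=8)
        truth.noise_sd = 0.01
        noisy = synthesize_decay_panel(truth)
        truth.noise_sd = 0.0
        clean = synthesize_decay_panel(truth)
        resid = noisy[0].values - clean[0].values
        assert np.std(resid) == pytest.approx(noisy[0].sd[0], rel=0.35)
        assert noisy[0].sd[0] == pytest.approx(0.01 * abs(clean[0].values[0]), rel=1e-9)


class TestGillespie:
    def test_equal_rates_bright_fraction(self):
        s = build_scheme("two-state")
        r = RateSet(values={"kon": 1e6, "koff": 1e6})
        tr = gillespie_intensity_trace(s, r, duration=0.01, dt=1e-7, seed=9)
        # binomial-ish 3 sigma bound with ~duration*k independent switches
        n_eff = 0.01 * 5e5
        assert abs(tr.values.mean() - 0.5) < 3 * 0.5 / np.sqrt(n_eff)

    def test_determinism(self):
        s = build_scheme("two-state")
        r = RateSet(values={"kon": 3e6, "koff": 1e6})
        a = gillespie_intensity_trace(s, r, duration=1e-3, dt=1e-8, seed=12)
        b = gillespie_intensity_trace(s, r, duration=1e-3, dt=1e-8, seed=12)
        assert np.array_equal(a.values, b.values)

    def test_bright_dwells_are_exponential(self):
        """KS test of bright-state dwell times against Exp(1/k_quench)."""
        s = build_scheme("two-state")
        r = RateSet(values={"kon": 3e6, "koff": 1e6})
        tr = gillespie_intensity_trace(s, r, duration=0.02, dt=2e-9, seed=13)
        dwells = bright_dwell_times(tr)
        assert dwells.size > 1000
        # dt-quantization shifts dwells by up to one bin; add half a bin
        stat = scipy.stats.kstest(dwells + tr.dt / 2, "expon", args=(0, 1 / 3e6))
        assert stat.pvalue > 0.01

    def test_argument_validation(self):
        s = build_scheme("two-state")
        r = RateSet(values={"kon": 3e6, "koff": 1e6})
        with pytest.raises(ValueError):
            gillespie_intensity_trace(s, r, duration=1e-3, dt=0.0, seed=0)
        with pytest.raises(ValueError):
            gillespie_intensity_trace(s, r, duration=1e-9, dt=1e-8, seed=0)


class TestMultiTau:
    def test_constant_trace_is_flat_and_zero_trace_rejected(self):
        from petfcs.synthetic import IntensityTrace

        const = IntensityTrace(dt=1e-6, values=np.ones(20000, dtype=np.uint8), seed=0)
        res = multitau_autocorrelate(const, n_blocks=4)
        assert np.allclose(res.g, 0.0, atol=1e-12)
        zero = IntensityTrace(dt=1e-6, values=np.zeros(20000, dtype=np.uint8), seed=0)
        with pytest.raises(ValueError):
            multitau_autocorrelate(zero, n_blocks=4)

    def test_matches_direct_autocorrelation_at_finest_level(self):
        s = build_scheme("two-state")
        r = RateSet(values={"kon": 3e6, "koff": 1e6})
        tr = gillespie_intensity_trace(s, r, duration=3e-4, dt=2e-8, seed=14)
        res = multitau_autocorrelate(tr, m=16, n_blocks=1)
        lags_d, g_d = direct_autocorrelation(tr, 16)
        finest = res.levels == 0
        assert np.allclose(res.lags[finest], lags_d)
        assert np.max(np.abs(res.g[finest] - g_d)) < 1e-12

    def test_telegraph_estimate_matches_closed_form(self):
        """Quench 3 µs^-1 / dequench 1 µs^-1 telegraph: the correlator
        estimate agrees with amplitude 3, rate 4 µs^-1 within 3 SE."""
        s = build_scheme("two-state")
        r = RateSet(values={"kon": 3e6, "koff": 1e6})
        tr = gillespie_intensity_trace(s, r, duration=0.04, dt=2e-8, seed=15)
        res = multitau_autocorrelate(tr, m=16, n_blocks=32)
        ref = expected_multitau_response(s, r, res.lags, res.levels, tr.dt)
        window = res.lags < 5 / 4e6
        z = (res.g[window] - ref[window]) / res.se[window]
        assert np.max(np.abs(z)) < 3.0


class TestFPABands:
    def test_zero_noise_recovers_truth_exactly(self):
        truth = {30: 0.25, 40: 0.8}
        bands = synthesize_fpa_bands(truth.items(), noise_sd=0.0, replicates=2, seed=0)
        prof = build_force_profile(bands)
        assert prof.f_fl == pytest.approx([0.25, 0.8])
        assert len(bands) == 4

    def test_monte_carlo_unbiasedness(self):
        """Mean recovered f_FL over many seeds is unbiased within 3 SEM."""
        vals = []
        for seed in range(200):
            bands = synthesize_fpa_bands([(50, 0.3)], noise_sd=0.05, replicates=3,
                                         seed=seed)
            vals.append(build_force_profile(bands).f_fl[0])
        vals = np.asarray(vals)
        sem = vals.std(ddof=1) / np.sqrt(vals.size)
        # small convexity bias of the ratio is << SEM at 5% noise
        assert abs(vals.mean() - 0.3) < 3 * sem + 1e-3

    def test_single_replicate_and_validation(self):
        bands = synthesize_fpa_bands([(30, 0.5)], replicates=1, seed=1)
        assert len(bands) == 1
        with pytest.raises(ValueError):
            synthesize_fpa_bands([(30, 0.5)], noise_sd=-0.1)
        with pytest.raises(ValueError):
            synthesize_fpa_bands([(30, 1.5)])

    def test_paper_like_profile_has_early_tension_regions(self):
        from petfcs import call_high_tension_regions

        truth = paper_like_force_profile_truth()
        bands = synthesize_fpa_bands(truth, noise_sd=0.03, replicates=3, seed=2)
        prof = build_force_profile(bands)
        regions = call_high_tension_regions(prof, threshold=0.4, min_run=2)
        starts = [a for a, b in regions]
        assert any(a <= 25 for a in starts)  # tension already inside the tunnel
        assert len(regions) >= 3
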