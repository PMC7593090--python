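"""Global fitting: problem assembly, chi2 accounting, recovery,
profile-likelihood intervals, invariances."""

import dataclasses

import numpy as np
import pytest

from petfcs import (
    DynamicDecay,
    RateSet,
    assemble_problem,
    build_scheme,
    compute_chi2_dof,
    fit_global,
    scan_confidence,
    simulate_dynamic_component,
)
from petfcs.globalfit import LinkConfig, LinkError, paper_links


def two_state_decay(kon=3e6, koff=1e6, noise=0.0, seed=0, n=80, construct="toy"):
    rng = np.random.default_rng(seed)
    t = np.geomspace(1e-8, 5e-6, n)
    s = build_scheme("two-state")
    y = simulate_dynamic_component(s, RateSet(values={"kon": kon, "koff": koff}), t).values
    sd = max(noise * abs(y[0]), 1e-12)
    return DynamicDecay(
        lags=t, values=y + sd * rng.standard_normal(n) * (noise > 0),
        sd=np.full(n, sd) if noise > 0 else None, construct=construct,
        curve_id=construct,
    )


class TestAssembly:
    def test_published_preset_locks_dissociation(self):
        constructs = ["hemk70_wt", "hemk70_4xa", "hemk112_4xa"]
        links = paper_links("5e-H", constructs)
        assert links.lock == {"koff_Wc": 2.2e6, "koff_Wd": 2.2e6}
        # ribosome dequenching shared across the whole panel, incl. 112 4xA
        shared = dict(links.groups)
        assert set(shared["koff_Rc"]) == set(constructs)
        # the 112 4xA construct keeps its own on-rates
        for rate, members in links.groups:
            if rate.startswith("kon"):
                assert "hemk112_4xa" not in members
        assert paper_links("5e-O", constructs).lock["koff_Wc"] == 2.0e6

    def test_unknown_rate_and_absent_construct_rejected(self):
        d = two_state_decay()
        with pytest.raises(LinkError):
            assemble_problem([d], "two-state", links=LinkConfig(lock={"nope": 1.0}))
        with pytest.raises(LinkError):
            assemble_problem(
                [d], "two-state",
                links=LinkConfig(groups=(("kon", ("toy", "ghost")),)),
            )
        with pytest.raises(LinkError):
            assemble_problem([], "two-state", links=None)

    def test_single_decay_all_free_is_valid(self):
        problem = assemble_problem([two_state_decay()], "two-state", links=None)
        assert problem.free_parameter_names() == ["kon__toy", "koff__toy"]


class TestChi2:
    def test_zero_for_exact_model(self):
        problem = assemble_problem([two_state_decay()], "two-state", links=None)
        chi2, red = compute_chi2_dof(problem, {"kon__toy": 3e6, "koff__toy": 1e6})
        assert chi2 == pytest.approx(0.0, abs=1e-18)

    def test_dof_arithmetic(self):
        # 7 curves x 118 points with 14 free parameters -> DoF = 812
        decays = [
            two_state_decay(n=118, construct=f"c{i}") for i in range(7)
        ]
        links = LinkConfig()  # 7 constructs x 2 free rates = 14
        problem = assemble_problem(decays, "two-state", links=links)
        assert problem.n_points() - len(problem.free_parameter_names()) == 812

    def test_uniform_residual_closed_form(self):
        # residuals all equal 2 over n points, p free -> chi2/DoF = 4n/(n-p)
        d = two_state_decay(n=50)
        d = dataclasses.replace(d, values=d.values + 2.0, sd=None)
        problem = assemble_problem([d], "two-state", links=None,
                                   weighting="uniform")
        chi2, red = compute_chi2_dof(problem, {"kon__toy": 3e6, "koff__toy": 1e6})
        assert chi2 == pytest.approx(4 * 50, rel=1e-12)
        assert red == pytest.approx(4 * 50 / (50 - 2), rel=1e-12)


class TestFitRecovery:
    def test_two_state_rates_within_one_percent(self):
        d = two_state_decay(noise=0.001, seed=4)
        problem = assemble_problem([d], "two-state", links=None)
        fit = fit_global(problem, n_starts=6, seed=1)
        vals = fit.parameter_values()
        assert vals["kon__toy"] == pytest.approx(3e6, rel=0.01)
        assert vals["koff__toy"] == pytest.approx(1e6, rel=0.01)
        assert fit.chi2_dof < 2.0
        assert fit.success

    def test_linked_parameters_share_one_estimate(self):
        decays = [
            two_state_decay(noise=0.005, seed=5, construct="a"),
            two_state_decay(noise=0.005, seed=6, construct="b"),
        ]
        links = LinkConfig(groups=(("kon", ("a", "b")), ("koff", ("a", "b"))))
        problem = assemble_problem(decays, "two-state", links=links)
        assert len(problem.free_parameter_names()) == 2
        fit = fit_global(problem, n_starts=4, seed=2)
        table = fit.rates_table()
        kon_vals = table[table["rate"] == "kon"]["value"].to_numpy()
        assert kon_vals[0] == kon_vals[1]

    def test_freeing_a_locked_parameter_never_hurts(self):
        d = two_state_decay(noise=0.01, seed=7)
        locked = assemble_problem(
            [d], "two-state", links=LinkConfig(lock={"koff": 1.3e6})
        )
        fit_locked = fit_global(locked, n_starts=4, seed=3)
        free = assemble_problem([d], "two-state", links=None)
        fit_free = fit_global(
            free, n_starts=4, seed=3,
            init={**fit_locked.parameter_values(), "koff__toy": 1.3e6},
        )
        assert fit_free.chi2 <= fit_locked.chi2 * (1 + 1e-9)

    def test_time_rescaling_equivariance(self):
        d = two_state_decay(noise=0.01, seed=8)
        alpha = 10.0
        d_scaled = dataclasses.replace(d, lags=d.lags * alpha)
        p1 = assemble_problem([d], "two-state", links=None)
        p2 = assemble_problem([d_scaled], "two-state", links=None)
        chi1, _ = compute_chi2_dof(p1, {"kon__toy": 3e6, "koff__toy": 1e6})
        chi2_, _ = compute_chi2_dof(
            p2, {"kon__toy": 3e6 / alpha, "koff__toy": 1e6 / alpha}
        )
        assert chi1 == pytest.approx(chi2_, rel=1e-12)

    def test_curve_order_invariance(self):
        decays = [
            two_state_decay(noise=0.01, seed=9, construct="a"),
            two_state_decay(kon=2e6, koff=5e5, noise=0.01, seed=10, construct="b"),
        ]
        v = {"kon__a": 3e6, "koff__a": 1e6, "kon__b": 2e6, "koff__b": 5e5}
        chi_fwd, _ = compute_chi2_dof(assemble_problem(decays, "two-state", links=None), v)
        chi_rev, _ = compute_chi2_dof(
            assemble_problem(decays[::-1], "two-state", links=None), v
        )
        assert chi_fwd == pytest.approx(chi_rev, rel=1e-12)

    def test_titration_links_make_bimolecular_identifiable(self):
        """A Trp titration series with a shared bimolecular on-rate and a
        tied dissociation recovers both; with all concentrations zero the
        quenching constant is unidentifiable (flat residuals)."""
        s = build_scheme("two-state")
        k2 = 0.1e6  # s^-1 mM^-1
        koff = 2.2e6
        decays = []
        rng = np.random.default_rng(11)
        for trp in (1.8, 9.0, 45.0):
            t = np.geomspace(1e-8, 5e-6, 60)
            y = simulate_dynamic_component(
                s, RateSet(values={"kon": k2 * trp, "koff": koff}), t
            ).values
            sd = 0.005 * y[0]
            decays.append(
                DynamicDecay(lags=t, values=y + sd * rng.standard_normal(60),
                             sd=np.full(60, sd), construct="toy", trp_mM=trp,
                             curve_id=f"trp{trp}")
            )
        links = LinkConfig(bimolecular=("kon",))
        problem = assemble_problem(decays, "two-state", links=links)
        fit = fit_global(problem, n_starts=6, seed=4)
        vals = fit.parameter_values()
        assert vals["kon__toy"] == pytest.approx(k2, rel=0.05)
        assert vals["koff__toy"] == pytest.approx(koff, rel=0.05)
        # degenerate design: zero concentration everywhere
        flat = [dataclasses.replace(d, trp_mM=0.0) for d in decays[:1]]
        problem0 = assemble_problem(flat, "two-state", links=links)
        r_lo = problem0.residuals({"kon__toy": 1e3, "koff__toy": koff})
        r_hi = problem0.residuals({"kon__toy": 1e6, "koff__toy": koff})
        assert np.allclose(r_lo, r_hi)  # kon has no leverage at [Trp]=0


class TestConfidence:
    def test_profile_interval_matches_covariance_on_quadratic_surface(self):
        """At low noise the chi2 surface is quadratic, so the 0.833-contour
        profile interval must match the covariance prediction
        theta_hat +- SE * sqrt((1/0.833 - 1) * DoF)."""
        d = two_state_decay(noise=0.002, seed=12)
        problem = assemble_problem([d], "two-state", links=None)
        fit = fit_global(problem, n_starts=4, seed=5)
        lo, hi = scan_confidence(fit, "kon__toy", contour=0.833, span_decades=0.5,
                                 n_grid=40)
        k_hat = fit.parameter_values()["kon__toy"]
        se = fit.parameter_se()["kon__toy"]
        half_pred = se * np.sqrt((1 / 0.833 - 1) * fit.dof)
        assert lo is not None and hi is not None
        # compare in log space where the scan interpolates
        pred_lo, pred_hi = k_hat - half_pred, k_hat + half_pred
        assert lo == pytest.approx(pred_lo, rel=0.02 * half_pred / k_hat + 0.005)
        assert hi == pytest.approx(pred_hi, rel=0.02 * half_pred / k_hat + 0.005)

    def test_locked_parameter_rejected(self):
        d = two_state_decay()
        problem = assemble_problem(
            [d], "two-state", links=LinkConfig(lock={"koff": 1e6})
        )
        fit = fit_global(problem, n_starts=2, seed=6)
        with pytest.raises(ValueError):
            scan_confidence(fit, "koff__toy")

    def test_interval_covers_truth_across_replicates(self):
        """The 0.833-contour interval covers the generator truth in most
        of a small seeded replicate ensemble (coverage is high by design:
        the contour sits far out on a 78-point single-curve fit)."""
        hits = 0
        n_rep = 8
        for seed in range(n_rep):
            d = two_state_decay(noise=0.01, seed=100 + seed, n=60)
            problem = assemble_problem([d], "two-state", links=None)
            fit = fit_global(problem, n_starts=2, seed=7,
                             init={"kon__toy": 3e6, "koff__toy": 1e6})
            lo, hi = scan_confidence(fit, "kon__toy", span_decades=0.4, n_grid=15)
            if (lo is None or lo <= 3e6) and (hi is None or hi >= 3e6):
                hits += 1
        assert hits >= n_rep - 2
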