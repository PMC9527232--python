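"""Two-Gaussian EM fit and the density-crossing cut."""

import math

import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from oculochain.mixture import (
    DegenerateFitError,
    LatencyMixture,
    MixtureFit,
    NoCrossingError,
    assign_modes,
    fit_em,
    gaussian_intersection_cut,
    mixing_proportions,
)
from oculochain.simulate import default_params, generate_session
from oculochain.classify import label_states3
from conftest import table_from_states


def _sample(rng, n=1000, w=0.4, m1=250, s1=40, m2=900, s2=150):
    z = rng.random(n) < w
    return np.where(z, rng.normal(m1, s1, n), rng.normal(m2, s2, n))


class TestFitEM:
    def test_parameter_recovery(self, rng):
        x = _sample(rng)
        fit = fit_em(x, seed=0)
        assert fit.lambda1 == pytest.approx(0.4, abs=0.05)
        assert fit.mu1 == pytest.approx(250, abs=12)
        assert fit.mu2 == pytest.approx(900, abs=25)
        assert fit.converged
        assert fit.lambda1 + fit.lambda2 == pytest.approx(1.0, abs=1e-12)
        assert fit.mu1 < fit.mu2

    def test_agrees_with_independent_em(self, rng):
        """Cross-check against sklearn's EM on the same sample."""
        x = _sample(rng, n=2000)
        ours = fit_em(x, seed=0)
        ref = GaussianMixture(2, random_state=0, n_init=3, tol=1e-8).fit(x[:, None])
        order = np.argsort(ref.means_.ravel())
        assert ours.mu1 == pytest.approx(ref.means_.ravel()[order][0], abs=2.0)
        assert ours.mu2 == pytest.approx(ref.means_.ravel()[order][1], abs=5.0)
        assert ours.lambda1 == pytest.approx(ref.weights_[order][0], abs=0.02)

    def test_loglik_monotone_within_run(self, rng):
        """EM log-likelihood never decreases across iterations."""
        from scipy.special import logsumexp

        from oculochain.mixture import _em_once, _log_mixture

        x = _sample(rng, n=500)
        # rerun EM step by step from the same init and record the trajectory
        w = np.array([0.5, 0.5])
        mu = np.percentile(x, [25, 75]).astype(float)
        sd = np.array([np.std(x), np.std(x)])
        lls = []
        for _ in range(60):
            lls.append(float(logsumexp(_log_mixture(x, w, mu, sd), axis=1).sum()))
            out = _em_once(x, w, mu, sd, tol=0.0, max_iter=1, sd_floor=1.0)
            w, mu, sd = out[0], out[1], out[2]
        assert np.all(np.diff(lls) >= -1e-8)

    def test_small_sample_and_zero_variance_errors(self):
        with pytest.raises(ValueError, match="at least"):
            fit_em([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="zero-variance"):
            fit_em([300.0] * 100)

    def test_shift_equivariance(self, rng):
        x = _sample(rng)
        a = fit_em(x, seed=0)
        b = fit_em(x + 123.0, seed=0)
        assert b.mu1 == pytest.approx(a.mu1 + 123.0, abs=1e-6)
        assert b.mu2 == pytest.approx(a.mu2 + 123.0, abs=1e-6)
        assert b.cut_ms == pytest.approx(a.cut_ms + 123.0, abs=1e-6)

    def test_order_invariance(self, rng):
        x = _sample(rng)
        a = fit_em(x, seed=0)
        b = fit_em(x[::-1].copy(), seed=0)
        assert a.mu1 == pytest.approx(b.mu1, abs=1e-9)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-9)

    def test_weight_recovery_across_replicates(self):
        errs = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            fit = fit_em(_sample(rng), seed=0, restarts=3)
            errs.append(abs(fit.lambda1 - 0.4))
        assert np.mean(errs) < 0.03

    def test_estimator_api(self, rng):
        est = LatencyMixture(restarts=2).fit(_sample(rng))
        assert est.means_[0] < est.means_[1]
        labels = est.predict([est.means_[0], est.means_[1], est.cut_ms_])
        assert labels.tolist() == [0, 1, 0]  # tie at the cut goes first
        assert "restarts" in est.get_params()


class TestIntersectionCut:
    def test_symmetric_midpoint_exact(self):
        fit = MixtureFit(0.5, 0.5, 200, 800, 100, 100, 0, 0, True, 0)
        assert gaussian_intersection_cut(fit) == pytest.approx(500.0, abs=1e-9)

    def test_unequal_sigma_closed_form(self):
        # crossing of 0.5 N(0,1) and 0.5 N(4,4): positive root of
        # 3x^2 + 8x - (16 + 8 ln 2) = 0
        fit = MixtureFit(0.5, 0.5, 0.0, 4.0, 1.0, 2.0, 0, 0, True, 0)
        expected = (-8 + math.sqrt(64 + 12 * (16 + 8 * math.log(2)))) / 6
        got = gaussian_intersection_cut(fit)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(1.660, abs=1e-3)

    def test_dominated_component_no_crossing(self):
        fit = MixtureFit(0.999, 0.001, 300, 310, 50, 50, 0, 0, True, 0)
        with pytest.raises(NoCrossingError):
            gaussian_intersection_cut(fit)

    def test_matches_grid_oracle_over_random_parameters(self):
        """Analytic crossing within 0.5 ms of a 0.01 ms grid search."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            mu1 = rng.uniform(100, 600)
            mu2 = mu1 + rng.uniform(200, 1200)
            s1, s2 = rng.uniform(20, 150, 2)
            l1 = rng.uniform(0.2, 0.8)
            fit = MixtureFit(l1, 1 - l1, mu1, mu2, s1, s2, 0, 0, True, 0)
            try:
                cut = gaussian_intersection_cut(fit)
            except NoCrossingError:
                continue
            xs = np.arange(mu1, mu2, 0.01)
            d1 = l1 * np.exp(-0.5 * ((xs - mu1) / s1) ** 2) / s1
            d2 = (1 - l1) * np.exp(-0.5 * ((xs - mu2) / s2) ** 2) / s2
            flips = np.flatnonzero((d1[:-1] >= d2[:-1]) & (d1[1:] < d2[1:]))
            assert flips.size >= 1
            grid_cut = xs[flips[0]]
            assert abs(cut - grid_cut) <= 0.5
            checked += 1


class TestModeAssignment:
    def test_cut_comparison_and_tie_rule(self):
        table = table_from_states("ee", condition="explicit")
        table.data["fp_ms"] = [900.0, 900.0]
        table.data["cue_ms"] = [900.0, 900.0]
        table.data["lat_ws_ms"] = [400.0, 600.0]
        table.data["lat_is_ms"] = table.data["lat_ws_ms"] - 900.0
        out = assign_modes(table, {900.0: 600.0})
        assert out.data["state4"].tolist() == ["first", "first"]  # 600 ties to first
        out2 = assign_modes(table, {900.0: 500.0})
        assert out2.data["state4"].tolist() == ["first", "second"]

    def test_missing_cut_requires_fallback(self):
        table = table_from_states("e")
        with pytest.raises(KeyError):
            assign_modes(table, {})
        out = assign_modes(table, {}, pooled_cut=600.0)
        assert out.data["state4"].iloc[0] in ("first", "second")

    def test_mode_labels_match_latent_truth_when_separated(self):
        """With modes separated by >= 4 pooled sds the cut recovers the
        generating labels almost perfectly."""
        params = default_params(
            "iPD", "OFF", "explicit", n_trials=20000, seed=2,
            premature_sd_ms=25.0, antic_sd_ms=40.0,
        )
        truth = generate_session(params, "s")
        labeled = label_states3(truth, 170.0)
        cuts = {}
        for d, cell in labeled.data[labeled.data["state3"] == "e"].groupby("fp_ms"):
            cuts[float(d)] = fit_em(cell["lat_ws_ms"].to_numpy(), seed=0, restarts=2).cut_ms
        out = assign_modes(labeled, cuts)
        agree = (out.data["state4"] == truth.data["state4"]).mean()
        assert agree >= 0.95


class TestMixingProportions:
    def test_simple_counts(self):
        table = table_from_states("e" * 10, condition="explicit")
        table.data["fp_ms"] = 900.0
        table.data["cue_ms"] = 900.0
        table.data["state4"] = ["first"] * 3 + ["second"] * 7
        out = mixing_proportions(table)
        row = out[(out["duration_ms"] == 900.0)].iloc[0]
        assert row["proportion_first"] == pytest.approx(0.3)
        assert row["proportion_second"] == pytest.approx(0.7)
        empty = out[(out["duration_ms"] == 400.0)].iloc[0]
        assert np.isnan(empty["proportion_first"]) and empty["n"] == 0

    def test_second_mode_share_rises_with_duration(self):
        """With cue-increasing second-mode pressure the anticipatory share is
        non-decreasing in duration, as in the explicit-condition controls."""
        params = default_params(
            "CONT", "NA", "explicit", n_trials=40000, seed=8,
            second_mode_pressure=0.8, premature_sd_ms=25.0, antic_sd_ms=40.0,
        )
        labeled = label_states3(generate_session(params, "s"), 170.0)
        cuts = {}
        for d, cell in labeled.data[labeled.data["state3"] == "e"].groupby("fp_ms"):
            cuts[float(d)] = fit_em(cell["lat_ws_ms"].to_numpy(), seed=0, restarts=2).cut_ms
        mix = mixing_proportions(assign_modes(labeled, cuts)).sort_values("duration_ms")
        shares = mix["proportion_second"].to_numpy()
        assert np.all(np.diff(shares) >= -1e-12)
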