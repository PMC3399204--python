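"""Capture-history handling and Huggins conditional-likelihood fitting."""

import math

import numpy as np
import pytest
from scipy.special import logit

from islandgen.cmr import (
    CaptureHistory,
    CMRModelSpec,
    capture_probability,
    fit_all_models,
    fit_huggins,
    normalize_covariates,
    pool_occasions,
    read_capture_csv,
    select_model,
    write_capture_csv,
)
from islandgen.synth import generate_capture_histories


@pytest.fixture
def small_history():
    det = np.array([[1, 0, 1, 0], [0, 1, 0, 0], [1, 1, 1, 1]])
    return CaptureHistory(
        ["a", "b", "c"],
        ["t1", "t2", "t3", "t4"],
        det,
        covariates={"weight": np.array([1.0, 2.0, 3.0])},
    )


class TestCaptureIO:
    def test_events_build_matrix(self, tmp_path):
        f = tmp_path / "cap.csv"
        f.write_text(
            "individual,occasion,weight\n"
            "a,t1,1.1\na,t2,1.1\nb,t2,2.2\n"
        )
        ch = read_capture_csv(f)
        assert ch.individuals == ["a", "b"]
        assert ch.occasions == ["t1", "t2"]
        assert ch.detections.tolist() == [[1, 1], [0, 1]]
        assert ch.covariates["weight"].tolist() == [1.1, 2.2]

    def test_duplicate_events_collapse(self, tmp_path):
        f = tmp_path / "cap.csv"
        f.write_text("individual,occasion\na,t1\na,t1\n")
        ch = read_capture_csv(f)
        assert ch.detections.tolist() == [[1]]

    def test_round_trip(self, tmp_path, small_history):
        path = tmp_path / "rt.csv"
        write_capture_csv(small_history, path)
        back = read_capture_csv(path)
        assert sorted(back.individuals) == sorted(small_history.individuals)
        assert back.occasions == small_history.occasions
        # align rows by individual id (reader orders by first capture)
        order = [back.individuals.index(i) for i in small_history.individuals]
        assert np.array_equal(
            back.detections[order], small_history.detections
        )
        assert back.covariates["weight"][order] == pytest.approx(
            small_history.covariates["weight"]
        )

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="detection"):
            CaptureHistory(["a"], ["t1"], np.array([[0]]))


class TestPooling:
    def test_or_semantics(self, small_history):
        pooled = pool_occasions(
            small_history,
            {"t12": ["t1", "t2"], "t3": ["t3"], "t4": ["t4"]},
        )
        assert pooled.occasions == ["t12", "t3", "t4"]
        assert pooled.detections.tolist() == [[1, 1, 0], [1, 0, 0], [1, 1, 1]]

    def test_identity_grouping_is_noop(self, small_history):
        pooled = pool_occasions(
            small_history, {o: [o] for o in small_history.occasions}
        )
        assert np.array_equal(pooled.detections, small_history.detections)

    def test_non_partition_rejected(self, small_history):
        with pytest.raises(ValueError, match="partition"):
            pool_occasions(small_history, {"x": ["t1", "t2"]})

    @pytest.mark.parametrize("seed", range(3))
    def test_pooling_preserves_individuals(self, seed):
        ch, _ = generate_capture_histories(
            50, 8, CMRModelSpec(), np.array([-1.0]), seed=seed
        )
        grouping = {
            "p1": list(ch.occasions[:3]),
            "p2": list(ch.occasions[3:6]),
            "p3": list(ch.occasions[6:]),
        }
        assert pool_occasions(ch, grouping).n_individuals == ch.n_individuals


class TestNormalization:
    def test_z_scores_population_sd(self, small_history):
        out = normalize_covariates(small_history, ["weight"])
        sd = math.sqrt(2 / 3)  # sd of (1,2,3) with denominator n
        assert out.covariates["weight"] == pytest.approx(
            [-1 / sd, 0.0, 1 / sd]
        )
        assert out.covariate_norms["weight"] == pytest.approx((2.0, sd))

    def test_idempotent_on_standardized_input(self, small_history):
        once = normalize_covariates(small_history, ["weight"])
        twice = normalize_covariates(once, ["weight"])
        assert twice.covariates["weight"] == pytest.approx(
            once.covariates["weight"], abs=1e-12
        )

    def test_zero_variance_errors(self):
        ch = CaptureHistory(
            ["a", "b"], ["t1", "t2"], np.array([[1, 0], [0, 1]]),
            covariates={"w": np.array([2.0, 2.0])},
        )
        with pytest.raises(ValueError, match="w"):
            normalize_covariates(ch, ["w"])


class TestCaptureProbability:
    def test_zero_params_give_half(self):
        assert capture_probability(CMRModelSpec(), np.zeros(1), T=5) == 0.5

    def test_monotone_in_intercept(self):
        ps = [
            capture_probability(CMRModelSpec(), np.array([b]), T=5)
            for b in np.linspace(-8, 8, 17)
        ]
        assert all(b > a for a, b in zip(ps, ps[1:]))
        assert ps[0] < 1e-3

    def test_behavior_effect_raises_recapture(self):
        spec = CMRModelSpec(behavior_effect=True)
        params = np.array([-1.0, 1.0])
        naive = capture_probability(spec, params, T=5, previously_captured=False)
        recap = capture_probability(spec, params, T=5, previously_captured=True)
        assert naive == pytest.approx(1 / (1 + math.exp(1.0)))
        assert recap == pytest.approx(0.5)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="parameters"):
            capture_probability(
                CMRModelSpec(time_effect=True), np.zeros(2), T=5
            )


def m0_grid_oracle(D, T, C, resolution=1e-5):
    """Grid-search MLE of the M(0) conditional likelihood.

    L(p) proportional to p^C (1-p)^(DT-C) / (1 - (1-p)^T)^D.
    """
    p = np.arange(resolution, 1.0, resolution)
    ll = (
        C * np.log(p)
        + (D * T - C) * np.log1p(-p)
        - D * np.log1p(-((1 - p) ** T))
    )
    p_hat = p[np.argmax(ll)]
    n_hat = D / (1 - (1 - p_hat) ** T)
    return p_hat, n_hat


class TestHugginsFit:
    def test_m0_matches_grid_search_oracle(self):
        # D=10, T=5, C=20 constructed directly
        det = np.zeros((10, 5), dtype=np.int8)
        det[:, 0] = 1  # everyone caught once
        det[:5, 2] = 1
        det[:5, 4] = 1  # C = 20
        ch = CaptureHistory([f"a{k}" for k in range(10)], list("vwxyz"), det)
        fit = fit_huggins(ch, CMRModelSpec())
        p_hat = 1 / (1 + math.exp(-fit.coefficients[0]))
        p_star, n_star = m0_grid_oracle(10, 5, 20)
        assert p_hat == pytest.approx(p_star, abs=1e-4)
        assert fit.N_hat == pytest.approx(n_star, abs=1e-3)
        assert fit.converged

    def test_everyone_always_caught_hits_boundary(self):
        det = np.ones((6, 4), dtype=np.int8)
        ch = CaptureHistory([f"a{k}" for k in range(6)], list("abcd"), det)
        fit = fit_huggins(ch, CMRModelSpec())
        assert fit.boundary
        assert fit.N_hat == pytest.approx(6, abs=1e-3)

    def test_behavior_model_recovers_coefficients(self):
        spec = CMRModelSpec(behavior_effect=True)
        truth = np.array([logit(0.2), logit(0.5) - logit(0.2)])
        n_reps = 200
        within = np.zeros(2)
        for s in range(n_reps):
            ch, _ = generate_capture_histories(200, 10, spec, truth, seed=s)
            fit = fit_huggins(ch, spec, n_restarts=0)
            se = np.sqrt(np.diag(fit.coef_cov))
            within += np.abs(fit.coefficients - truth) <= 2 * se
        # ~95.4% expected per coefficient; 0.90 is >3 binomial SDs below
        assert (within / n_reps >= 0.90).all()

    def test_nested_models_order_loglik(self):
        ch, _ = generate_capture_histories(
            120, 8, CMRModelSpec(), np.array([-1.0]), seed=5
        )
        fits = {f.name: f for f in fit_all_models(ch)}
        assert fits["Mt"].log_lik >= fits["M0"].log_lik - 1e-6
        assert fits["Mtb"].log_lik >= fits["Mb"].log_lik - 1e-6

    def test_too_few_occasions_errors(self):
        ch = CaptureHistory(["a"], ["t1"], np.array([[1]]))
        with pytest.raises(ValueError, match="occasions"):
            fit_huggins(ch, CMRModelSpec())


class TestModelSweepAndSelection:
    def test_sweep_counts_models(self):
        ch, _ = generate_capture_histories(
            80, 6, CMRModelSpec(heterogeneity="linear", covariate="w"),
            np.array([-1.0, 0.3]), seed=2,
        )
        assert len(fit_all_models(ch)) == 4  # no covariate requested
        assert len(fit_all_models(ch, covariate="w")) == 8
        assert len(fit_all_models(ch, covariate="w", include_quadratic=True)) == 9

    def test_m0_selected_on_m0_data(self):
        wins = 0
        n_reps = 40
        for s in range(n_reps):
            ch, _ = generate_capture_histories(
                100, 10, CMRModelSpec(), np.array([logit(0.3)]), seed=200 + s
            )
            fits = fit_all_models(ch, seed=0)
            wins += select_model(fits).name == "M0"
        assert wins > n_reps / 2

    def test_exact_tie_prefers_fewer_parameters(self):
        from islandgen.cmr import CMRFit

        a = CMRFit(CMRModelSpec(), np.zeros(1), -100.0, 202.0, 50.0, 5.0, True)
        b = CMRFit(
            CMRModelSpec(behavior_effect=True), np.zeros(2), -99.0, 202.0,
            50.0, 5.0, True,
        )
        assert select_model([b, a]).name == "M0"

    def test_selection_invariant_to_order(self):
        ch, _ = generate_capture_histories(
            100, 8, CMRModelSpec(), np.array([-0.8]), seed=7
        )
        fits = fit_all_models(ch)
        chosen = {select_model(list(perm)).name
                  for perm in [fits, fits[::-1], fits[2:] + fits[:2]]}
        assert len(chosen) == 1

    def test_no_converged_fit_errors(self):
        with pytest.raises(ValueError, match="converged"):
            select_model([])
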