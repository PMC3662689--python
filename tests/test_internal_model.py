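"""Internal-model fitting, nested comparison and bootstrap machinery."""

import math

import numpy as np
import pytest
from scipy import stats

from motormodel.hit_probability import InternalModel, TargetShape, equivalent_radius
from motormodel.internal_model import (ScaledTable, bootstrap_cis, classify,
                                       fit_area_model, fit_gaussian_model,
                                       predict_log_r_eq)
from motormodel.pipeline import ExperimentDesign
from motormodel.psychometric import fit_psychometric
from motormodel.synthetic_subject import SubjectSpec, make_responder, simulate_endpoints
from motormodel.staircase import Staircase, run_staircases


@pytest.fixture(scope="module")
def rect_set():
    return ExperimentDesign.experiment_1().rectangles(4.88)


def area_radii(rects):
    return {k: math.sqrt(v.w * v.h / math.pi) for k, v in rects.items()}


class TestFitGaussianModel:
    def test_noiseless_identifiability(self, rect_set, unit_table_exp1):
        """Radii generated exactly from (σ̃², η̃) are recovered to tolerance."""
        model = InternalModel.gaussian(23.04, 1.2)
        r_meas = {k: equivalent_radius(v, model) for k, v in rect_set.items()}
        fit = fit_gaussian_model(r_meas, rect_set, sigma2_ref=23.04)
        assert fit.sigma2_tilde == pytest.approx(23.04, rel=1e-3)
        assert fit.eta_tilde == pytest.approx(1.2, rel=1e-3)
        assert fit.sigma_e <= 1e-4

    def test_scaled_table_matches_exact_predictions(self, rect_set, unit_table_exp1):
        pred = ScaledTable(unit_table_exp1, 4.88)
        ids = sorted(rect_set)
        exact = predict_log_r_eq([rect_set[i] for i in ids], 30.0, 1.3)
        assert np.abs(pred(30.0, 1.3) - exact).max() < 5e-4

    def test_area_generator_pushes_sigma2_to_cap(self, rect_set):
        """An area-matching generator drives σ̃² into the upper grid region
        and the Gaussian/area likelihood gap to ~0."""
        r_meas = area_radii(rect_set)
        fit = fit_gaussian_model(r_meas, rect_set, sigma2_ref=23.04)
        logL_area, _ = fit_area_model(r_meas, rect_set)
        assert fit.sigma2_tilde / 23.04 >= 999.0
        assert abs(fit.logL_gaussian - logL_area) < 1e-9

    def test_requires_three_rects_and_both_orientations(self):
        rects = {"h1": TargetShape.rectangle(4, 1), "h2": TargetShape.rectangle(8, 2),
                 "h3": TargetShape.rectangle(6, 1.5)}
        r = area_radii(rects)
        with pytest.raises(ValueError):
            fit_gaussian_model(r, rects)
        two = {k: rects[k] for k in ("h1", "h2")}
        with pytest.raises(ValueError):
            fit_gaussian_model(area_radii(two), two)


class TestFitAreaModel:
    def test_exact_area_radii_dominate(self, rect_set):
        logL, sigma_e = fit_area_model(area_radii(rect_set), rect_set)
        assert sigma_e == pytest.approx(1e-6)  # floored
        assert logL > 100.0  # enormous likelihood, dominates classification

    def test_constant_multiplicative_offset(self, rect_set):
        c = 1.17
        r_meas = {k: v * c for k, v in area_radii(rect_set).items()}
        _, sigma_e = fit_area_model(r_meas, rect_set)
        assert sigma_e == pytest.approx(abs(math.log(c)), rel=1e-9)

    def test_sigma_e_estimator_consistency(self, rect_set, rng):
        """σ̂_e tracks the generating 0.05 over 500 replicates."""
        base = area_radii(rect_set)
        n = len(base)
        est = []
        for _ in range(500):
            r_meas = {k: v * math.exp(0.05 * rng.standard_normal())
                      for k, v in base.items()}
            est.append(fit_area_model(r_meas, rect_set)[1])
        se = np.std(est) / math.sqrt(len(est))
        # MLE of sigma (n in the denominator) is biased low at n=10; compare
        # against its finite-sample expectation
        expected = 0.05 * math.sqrt(2 / n) * math.gamma((n + 1) / 2) / math.gamma(n / 2)
        assert abs(np.mean(est) - expected) < 3 * se


class TestClassify:
    def test_chi_square_criterion(self):
        crit = stats.chi2.ppf(0.95, 2)
        assert classify(1.0, 0.0)["type"] == "area_matching"   # λ = 2 < crit
        assert classify(10.0, 0.0)["type"] == "gaussian"       # λ = 20 > crit
        assert classify(0.0, 0.0)["lambda"] == 0.0
        assert classify(0.0, 0.0)["type"] == "area_matching"
        assert classify(10.0, 0.0)["criterion"] == pytest.approx(crit)

    def test_negative_lambda_raises(self):
        with pytest.raises(RuntimeError):
            classify(0.0, 5.0)

    def test_nesting_on_noisy_datasets(self, rect_set, unit_table_exp1, rng):
        """Maximized Gaussian logL ≥ area logL on arbitrary data."""
        pred = ScaledTable(unit_table_exp1, 4.88)
        for _ in range(25):
            r_meas = {k: v * math.exp(0.08 * rng.standard_normal())
                      for k, v in area_radii(rect_set).items()}
            g = fit_gaussian_model(r_meas, rect_set, sigma2_ref=23.04, predictor=pred)
            la, _ = fit_area_model(r_meas, rect_set)
            assert g.logL_gaussian >= la - 1e-6

    def test_classification_invariant_to_unit_rescaling(self, rect_set, rng):
        r_meas = {k: v * math.exp(0.05 * rng.standard_normal())
                  for k, v in area_radii(rect_set).items()}
        lam = []
        for c in (1.0, 0.1):
            rects_c = {k: TargetShape.rectangle(v.w * c, v.h * c)
                       for k, v in rect_set.items()}
            r_c = {k: v * c for k, v in r_meas.items()}
            g = fit_gaussian_model(r_c, rects_c, sigma2_ref=23.04 * c**2)
            la, _ = fit_area_model(r_c, rects_c)
            lam.append(classify(g.logL_gaussian, la)["lambda"])
        assert lam[0] == pytest.approx(lam[1], abs=5e-2)


class TestEtaIdentifiability:
    def test_eta_effect_shrinks_with_sigma2(self, rect_set):
        """The η̃ = 1 vs 1.44 prediction gap shrinks monotonically as σ̃² grows."""
        ids = sorted(rect_set)
        shapes = [rect_set[i] for i in ids]
        spreads = []
        for s2 in (5.0, 23.04, 100.0, 500.0):
            d = np.abs(predict_log_r_eq(shapes, s2, 1.44)
                       - predict_log_r_eq(shapes, s2, 1.0))
            spreads.append(float(d.max()))
        assert all(b < a for a, b in zip(spreads, spreads[1:]))


class TestBootstrap:
    def make_subject(self, seed, unit_table):
        design = ExperimentDesign.experiment_2()
        spec = SubjectSpec(seed=seed)
        endpoints = simulate_endpoints(spec, design.n_training)
        from motormodel.endpoint_analysis import fit_true_distribution
        motor = fit_true_distribution(endpoints)
        rects = design.rectangles(motor.sigma_bar)
        plan = design.staircase_plan(rects)
        scs = [Staircase(s, staircase_id=sid, rect=rect, rect_id=rid)
               for sid, rid, rect, s in plan]
        trials = run_staircases(scs, make_responder(spec), seed=spec.rng("choices"))
        fit = fit_psychometric(trials)
        return endpoints, fit, plan, ScaledTable(unit_table, motor.sigma_bar)

    def test_fixed_seed_reproducibility(self, unit_table_exp2):
        endpoints, fit, plan, pred = self.make_subject(77, unit_table_exp2)
        a = bootstrap_cis(endpoints, fit, plan, n_boot=12, seed=5, predictor=pred)
        b = bootstrap_cis(endpoints, fit, plan, n_boot=12, seed=5, predictor=pred)
        assert a["ci_sigma2_ratio"] == b["ci_sigma2_ratio"]
        assert a["ci_eta_ratio"] == b["ci_eta_ratio"]
        assert np.array_equal(a["sigma2_ratio"], b["sigma2_ratio"])

    def test_cis_bracket_generating_ratios(self, unit_table_exp2):
        """For a well-specified subject the CI surrounds the generating values."""
        endpoints, fit, plan, pred = self.make_subject(78, unit_table_exp2)
        out = bootstrap_cis(endpoints, fit, plan, n_boot=60, seed=3, predictor=pred)
        lo, hi = out["ci_sigma2_ratio"]
        assert lo < 1.0 < hi or (abs(math.log(lo)) < 0.7 and abs(math.log(hi)) < 0.7)
        assert lo < hi

    def test_invalid_n_boot(self, unit_table_exp2):
        endpoints, fit, plan, pred = self.make_subject(79, unit_table_exp2)
        with pytest.raises(ValueError):
            bootstrap_cis(endpoints, fit, plan, n_boot=1, predictor=pred)
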