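"""End-to-end experiment orchestration and cross-task statistics.

Ties the stages together for a full simulated subject: training reaches
→ motor-error fit → rectangle set scaled to the measured mean SD →
interleaved staircases against the subject's choice rule → psychometric
fit → equivalent radii → Gaussian vs area-matching comparison →
(optionally) bootstrap confidence intervals.  Also provides the
statistics used to compare the probability-choice and area-choice tasks:
a one-sample t-test on paired log equivalent-radius differences and
Fisher's exact test on type counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .endpoint_analysis import fit_true_distribution, isotropy_test
from .hit_probability import TargetShape
from .internal_model import (EquivalentRadiusTable, bootstrap_cis, classify,
                             fit_area_model, fit_gaussian_model)
from .psychometric import fit_psychometric
from .staircase import (EXP1_STEPS, EXP2_STEPS, Staircase, StaircaseSpec,
                        run_staircases)
from .synthetic_subject import SubjectSpec, make_responder, simulate_endpoints

__all__ = [
    "ExperimentDesign",
    "run_subject",
    "compare_tasks",
    "type_association",
]

# Geometric ladder of rectangle short sides, in units of the measured mean SD.
DEFAULT_MULTIPLIERS = (0.60, 0.90, 1.35, 2.025, 3.0375)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of one choice experiment.

    Rectangles come in 4:1 (horizontal) and 1:4 (vertical) orientations
    with short sides ``size_multipliers``×σ̄ (σ̄ measured from the
    subject's training reaches).  Each rectangle is paired with
    ``staircase_rules`` adaptive tracks of ``n_staircase_trials`` trials
    using ``step_schedule``.  Presets: :meth:`experiment_1` (5 sizes,
    1-up/2-down + 2-up/1-down × 50 trials, 300 training reaches) and
    :meth:`experiment_2` (4 sizes, one 1-up/1-down × 60 trials, 600
    training reaches).
    """

    size_multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS
    aspect: float = 4.0
    staircase_rules: tuple[tuple[int, int], ...] = ((1, 2), (2, 1))
    step_schedule: tuple[float, ...] = EXP1_STEPS
    n_staircase_trials: int = 50
    n_training: int = 300
    task: str = "probability"  # "probability" | "area" | "probability_with_feedback"
    # feedback phase only: per-block drift of the generator's internal model
    # toward truth (no fitted learning rule is claimed; 0 = no drift)
    feedback_drift: float = 0.0
    block_size: int = 100

    def __post_init__(self) -> None:
        m = self.size_multipliers
        if not m or any(x <= 0 for x in m):
            raise ValueError("size multipliers must be positive")
        if self.task not in ("probability", "area", "probability_with_feedback"):
            raise ValueError(f"unknown task {self.task!r}")
        if not 0.0 <= self.feedback_drift <= 1.0:
            raise ValueError("feedback_drift must lie in [0, 1]")

    @classmethod
    def experiment_1(cls) -> "ExperimentDesign":
        return cls()

    @classmethod
    def experiment_2(cls) -> "ExperimentDesign":
        return cls(size_multipliers=DEFAULT_MULTIPLIERS[:4],
                   staircase_rules=((1, 1),), step_schedule=EXP2_STEPS,
                   n_staircase_trials=60, n_training=600)

    def rectangles(self, sigma_bar: float) -> dict[str, TargetShape]:
        """Rectangle set scaled to a subject's measured mean SD (mm)."""
        if not sigma_bar > 0:
            raise ValueError("sigma_bar must be positive")
        rects: dict[str, TargetShape] = {}
        for m in self.size_multipliers:
            short = m * sigma_bar
            long = self.aspect * short
            rects[f"h{m:g}"] = TargetShape.rectangle(long, short)
            rects[f"v{m:g}"] = TargetShape.rectangle(short, long)
        return rects

    def staircase_plan(self, rects: dict[str, TargetShape]
                       ) -> list[tuple[str, str, TargetShape, StaircaseSpec]]:
        """(staircase_id, rect_id, rect, spec) for every track of a session.

        Start radius is the rectangle's area-equivalent radius — an
        anchor that favours neither the Gaussian nor the area-matching
        hypothesis.
        """
        plan = []
        for rid, rect in rects.items():
            start = math.sqrt(rect.w * rect.h / math.pi)
            for rule in self.staircase_rules:
                spec = StaircaseSpec(rule=rule, step_schedule=self.step_schedule,
                                     n_trials=self.n_staircase_trials,
                                     start_radius=start)
                plan.append((f"{rid}/{rule[0]}u{rule[1]}d", rid, rect, spec))
        return plan


def run_subject(spec: SubjectSpec, design: ExperimentDesign, seed: int | None = None,
                n_boot: int = 0, predictor=None, unit_table=None,
                keep_arrays: bool = False) -> dict:
    """Full simulate → fit → classify (→ bootstrap) pipeline for one subject.

    ``seed`` overrides the spec's master seed.  ``n_boot`` > 1 adds
    bootstrap CIs for σ̃²/σ̂² and η̃/η̂ (1000 replicates is the reference
    setting; smaller values trade CI smoothness for speed).  A
    ``predictor`` (:class:`~motormodel.internal_model.EquivalentRadiusTable`
    for this subject's rectangle set) or a ``unit_table`` (the same design
    tabulated at σ̄ = 1, rescaled here to the measured σ̄ and shareable
    across subjects) makes repeated fits much faster.  Deterministic: the
    same seed yields byte-identical reports.
    """
    if seed is not None:
        spec = SubjectSpec(**{**spec.to_dict(), "seed": seed,
                              "internal_model": spec.internal_model})
    endpoints = simulate_endpoints(spec, design.n_training)
    motor = fit_true_distribution(endpoints)
    rects = design.rectangles(motor.sigma_bar)
    plan = design.staircase_plan(rects)
    if predictor is None and unit_table is not None:
        from .internal_model import ScaledTable
        predictor = ScaledTable(unit_table, motor.sigma_bar)

    if design.task == "probability_with_feedback" and design.feedback_drift > 0:
        from .synthetic_subject import make_drifting_responder
        responder = make_drifting_responder(spec, design.feedback_drift,
                                            design.block_size)
    else:
        responder = make_responder(spec)
    scs = [Staircase(sc_spec, staircase_id=sid, rect=rect, rect_id=rid)
           for sid, rid, rect, sc_spec in plan]
    trials = run_staircases(scs, responder, interleave=True,
                            seed=spec.rng("choices"))

    psycho = fit_psychometric(trials)
    gauss = fit_gaussian_model(psycho.r_eq, rects, sigma2_ref=motor.sigma2,
                               predictor=predictor)
    logL_area, sigma_e_area = fit_area_model(psycho.r_eq, rects)
    test = classify(gauss.logL_gaussian, logL_area)

    report = {
        "seed": int(spec.seed),
        "task": design.task,
        "motor_error": {"sigma_h": motor.sigma_h, "sigma_v": motor.sigma_v,
                        "rho": motor.rho, "n_used": motor.n_used,
                        "sigma2": motor.sigma2, "eta": motor.eta,
                        "sigma_bar": motor.sigma_bar},
        "isotropy_test": isotropy_test(endpoints),
        "psychometric": {"a": psycho.a, "gamma": psycho.gamma,
                         "logL": psycho.logL, "r_eq": psycho.r_eq,
                         "separable": psycho.separable},
        "internal_model": {
            "sigma2_tilde": gauss.sigma2_tilde,
            "eta_tilde": gauss.eta_tilde,
            "sigma_e": gauss.sigma_e,
            "sigma2_ratio": gauss.sigma2_tilde / motor.sigma2,
            "eta_ratio": gauss.eta_tilde / motor.eta,
            "logL_gaussian": gauss.logL_gaussian,
            "logL_area": logL_area,
            "sigma_e_area": sigma_e_area,
            "lambda": test["lambda"],
            "type": test["type"],
        },
    }
    if n_boot > 1:
        boot = bootstrap_cis(endpoints, psycho, plan, n_boot=n_boot,
                             seed=spec.rng("bootstrap"), predictor=predictor)
        report["bootstrap"] = {
            "n_boot": n_boot,
            "ci_sigma2_ratio": [float(x) for x in boot["ci_sigma2_ratio"]],
            "ci_eta_ratio": [float(x) for x in boot["ci_eta_ratio"]],
        }
        if keep_arrays:
            report["bootstrap"]["sigma2_ratio"] = boot["sigma2_ratio"]
            report["bootstrap"]["eta_ratio"] = boot["eta_ratio"]
    return report


def compare_tasks(prob_radii: dict, area_radii: dict) -> dict:
    """Paired comparison of probability-task vs area-task equivalent radii.

    One-sample two-tailed t-test on log(r̂_prob / r̂_area) over the shared
    rectangles.  ``direction`` is the sign of the mean log difference
    (negative: probability radii smaller, the Gaussian-type signature).
    """
    keys = sorted(set(prob_radii) & set(area_radii))
    if len(keys) < 2:
        raise ValueError("need at least 2 paired rectangles")
    diffs = np.log([prob_radii[k] / area_radii[k] for k in keys])
    if np.allclose(diffs, diffs[0]):
        raise ValueError("zero variance in paired log differences")
    t, p = stats.ttest_1samp(diffs, 0.0)
    mean = float(np.mean(diffs))
    return {"t": float(t), "p": float(p), "df": len(keys) - 1,
            "mean_log_diff": mean,
            "direction": "negative" if mean < 0 else "positive"}


def type_association(counts) -> dict:
    """Fisher's exact test on a 2×2 table of subject-type counts.

    Rows: subject type in one task; columns: type in the other.  Returns
    hypergeometric exact p-values, one-sided ('greater') and two-sided.
    """
    table = np.asarray(counts, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("counts must be a nonnegative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("empty margin in 2x2 table")
    _, p_two = stats.fisher_exact(table, alternative="two-sided")
    _, p_one = stats.fisher_exact(table, alternative="greater")
    return {"p_one_sided": float(p_one), "p_two_sided": float(p_two)}
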