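"""Synthetic subjects: endpoint scatter and two-interval target choices.

A synthetic subject has a *true* motor error distribution (a vertically
elongated bivariate Gaussian, optionally correlated, with occasional
timeouts) and an *internal model* of that distribution which may be
wrong.  Endpoints are drawn from the true distribution; choices between
a rectangle and a circle are drawn from a Weibull-shaped decision rule
anchored at the internal model's own equivalent radius, the same family
used downstream for psychometric fitting, so that generation and fitting
are self-consistent and parameter recovery is a meaningful test.

Concretely, the probability of judging the circle easier to hit is

    P(circle | r) = 1 − exp(−(r/a)^γ),   a = r_eq* / (ln 2)^(1/γ),

where r_eq* is the radius at which the subject's internal model deems
the circle and the rectangle equally hittable.  The position parameter a
is chosen so that P = 0.5 exactly at r = r_eq*: the subject is
indifferent at her own equivalent radius, and inverting a fitted Weibull
at its 50% point recovers r_eq*.  γ (``gamma_choice``) controls decision
noise; γ → ∞ gives a deterministic chooser.

Randomness: one master seed spawns independent named substreams
(endpoints, choices) so modules can be exercised in isolation while the
full pipeline stays reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .hit_probability import InternalModel, TargetShape, equivalent_radius

__all__ = [
    "SubjectSpec",
    "EndpointSample",
    "simulate_endpoints",
    "choice_probability",
    "simulate_choice",
    "make_responder",
    "make_drifting_responder",
    "endpoints_to_frame",
    "write_endpoints_csv",
]

# Fixed substream labels: master seed + label -> independent generator.
_STREAMS = {"endpoints": 0, "choices": 1, "bootstrap": 2, "misc": 3}


@dataclass(frozen=True)
class SubjectSpec:
    """Generative description of one synthetic subject.

    ``sigma_h``/``sigma_v`` (mm) and ``rho`` define the true endpoint
    Gaussian; defaults give the anisotropy ratio 1.44 typical of upward
    reaching.  ``internal_model`` is what the subject *believes*;
    ``gamma_choice`` the steepness of her choice rule; ``timeout_rate``
    the probability a reach misses the movement-time limit.
    """

    sigma_h: float = 4.0
    sigma_v: float = 5.76
    rho: float = 0.0
    internal_model: InternalModel = field(
        default_factory=lambda: InternalModel.gaussian(4.0 * 5.76, 1.0))
    gamma_choice: float = 4.0
    timeout_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.sigma_h > 0 and self.sigma_v > 0):
            raise ValueError("sigma_h and sigma_v must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if not self.gamma_choice > 0:
            raise ValueError("gamma_choice must be positive")
        if not 0.0 <= self.timeout_rate < 1.0:
            raise ValueError("timeout_rate must lie in [0, 1)")

    def rng(self, stream: str = "misc") -> np.random.Generator:
        """Independent generator for a named substream of the master seed."""
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["internal_model"] = {k: v for k, v in asdict(self.internal_model).items()
                               if v is not None}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectSpec":
        d = dict(d)
        d["internal_model"] = InternalModel(**d["internal_model"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SubjectSpec":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class EndpointSample:
    """One reach endpoint (mm from target centroid, y up); timeouts carry
    no coordinates usable by the analysis."""

    x: float
    y: float
    timed_out: bool = False


def simulate_endpoints(spec: SubjectSpec, n: int,
                       rng: np.random.Generator | None = None,
                       ) -> list[EndpointSample]:
    """Draw ``n`` training reaches from the subject's true distribution.

    Non-timeout endpoints are bivariate Gaussian with mean 0 and
    covariance built from (sigma_h, sigma_v, rho); each trial times out
    independently with probability ``timeout_rate``, in which case the
    sample carries NaN coordinates and the ``timed_out`` flag.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = spec.rng("endpoints")
    cov = np.array([
        [spec.sigma_h**2, spec.rho * spec.sigma_h * spec.sigma_v],
        [spec.rho * spec.sigma_h * spec.sigma_v, spec.sigma_v**2],
    ])
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, 2))
    xy = z @ L.T
    timed_out = rng.random(n) < spec.timeout_rate
    out = []
    for i in range(n):
        if timed_out[i]:
            out.append(EndpointSample(x=math.nan, y=math.nan, timed_out=True))
        else:
            out.append(EndpointSample(x=float(xy[i, 0]), y=float(xy[i, 1])))
    return out


def choice_probability(rect: TargetShape, circle_radius: float,
                       spec: SubjectSpec, r_eq_star: float | None = None) -> float:
    """P(judge the circle easier than ``rect``) at the given radius."""
    if not circle_radius > 0:
        raise ValueError("circle radius must be positive")
    if r_eq_star is None:
        r_eq_star = equivalent_radius(rect, spec.internal_model)
    gamma = spec.gamma_choice
    # a = r_eq*/(ln2)^(1/gamma); for large gamma this tends to r_eq* and the
    # rule tends to a step at r_eq*.
    log_ratio = math.log(circle_radius / r_eq_star) + math.log(math.log(2.0)) / gamma
    t = gamma * log_ratio
    if t > 700.0 / math.log(10):
        return 1.0
    return float(-math.expm1(-math.exp(min(t, 700.0))))


def simulate_choice(trial: dict, spec: SubjectSpec,
                    rng: np.random.Generator | None = None) -> str:
    """One binary judgment between ``trial['rect']`` and ``trial['circle']``.

    Returns ``"circle"`` or ``"rectangle"``; the Bernoulli draw comes from
    the subject's ``choices`` substream unless an explicit generator is
    supplied (as the staircase runner does).
    """
    rect, circle = trial["rect"], trial["circle"]
    if rect.kind != "rectangle" or circle.kind != "circle":
        raise ValueError("trial must pair a rectangle with a circle")
    p = choice_probability(rect, circle.r, spec)
    if rng is None:
        rng = spec.rng("choices")
    return "circle" if rng.random() < p else "rectangle"


def make_responder(spec: SubjectSpec, rng: np.random.Generator | None = None,
                   ) -> Callable[[TargetShape, float], str]:
    """Stateful responder ``f(rect, radius) -> response`` for staircase runs.

    Caches each rectangle's internal equivalent radius so repeated trials
    on the same rectangle cost one Bernoulli draw.
    """
    if rng is None:
        rng = spec.rng("choices")
    cache: dict[TargetShape, float] = {}

    def respond(rect: TargetShape, radius: float) -> str:
        if rect not in cache:
            cache[rect] = equivalent_radius(rect, spec.internal_model)
        p = choice_probability(rect, radius, spec, r_eq_star=cache[rect])
        return "circle" if rng.random() < p else "rectangle"

    return respond


def make_drifting_responder(spec: SubjectSpec, drift_rate: float,
                            block_size: int,
                            rng: np.random.Generator | None = None,
                            ) -> Callable[[TargetShape, float], str]:
    """Responder whose Gaussian internal model drifts toward truth per block.

    Models a feedback phase: after each block of ``block_size`` trials the
    internal (log σ̃², log η̃) move a fraction ``drift_rate`` of the
    remaining distance toward the true (log σ², log η).  ``drift_rate=0``
    reproduces :func:`make_responder`.  No empirical learning rule is
    claimed — the rate is a knob, not a fitted model — and non-Gaussian
    internal models do not drift (there is no parameter path from the
    area-matching rule toward a specific Gaussian).
    """
    if not 0.0 <= drift_rate <= 1.0:
        raise ValueError("drift_rate must lie in [0, 1]")
    if block_size < 1:
        raise ValueError("block_size must be positive")
    if rng is None:
        rng = spec.rng("choices")
    if drift_rate == 0.0 or spec.internal_model.form != "gaussian":
        return make_responder(spec, rng)

    true_log_s2 = math.log(spec.sigma_h * spec.sigma_v)
    true_log_eta = math.log(spec.sigma_v / spec.sigma_h)
    state = {"n": 0, "block": 0,
             "log_s2": math.log(spec.internal_model.sigma2_tilde),
             "log_eta": math.log(spec.internal_model.eta_tilde),
             "cache": {}}

    def respond(rect: TargetShape, radius: float) -> str:
        block = state["n"] // block_size
        if block != state["block"]:
            frac = 1.0 - (1.0 - drift_rate) ** (block - state["block"])
            state["log_s2"] += frac * (true_log_s2 - state["log_s2"])
            state["log_eta"] += frac * (true_log_eta - state["log_eta"])
            state["block"] = block
            state["cache"] = {}
        state["n"] += 1
        model = InternalModel.gaussian(math.exp(state["log_s2"]),
                                       math.exp(state["log_eta"]))
        if rect not in state["cache"]:
            state["cache"][rect] = equivalent_radius(rect, model)
        # gamma is unchanged by drift; only the anchor moves
        p = choice_probability(rect, radius, spec,
                               r_eq_star=state["cache"][rect])
        return "circle" if rng.random() < p else "rectangle"

    return respond


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def endpoints_to_frame(endpoints: Sequence[EndpointSample]) -> pd.DataFrame:
    return pd.DataFrame({
        "x_mm": [e.x for e in endpoints],
        "y_mm": [e.y for e in endpoints],
        "timed_out": [bool(e.timed_out) for e in endpoints],
    })


def write_endpoints_csv(endpoints: Sequence[EndpointSample], path) -> None:
    endpoints_to_frame(endpoints).to_csv(path, index=False)
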