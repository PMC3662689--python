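"""Estimation and diagnostics of the true motor error distribution.

Speeded reaches toward a target leave a cloud of endpoints around the
aim point.  This module estimates the bivariate Gaussian describing that
cloud (per-axis SDs and correlation), derives the variance and
anisotropy parameterization used throughout the choice analysis, and
runs the distributional checks: a one-tailed F test for vertical
elongation, quantile–quantile linearity per axis, and the sensitivity of
rectangle hit probabilities to the (ignored) endpoint correlation.

Parameter convention: the variance parameter is the geometric-mean
variance σ² = σh·σv and the anisotropy is η = σv/σh, so σh² = σ²/η and
σv² = σ²·η, and η = 1 means isotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hit_probability import TargetShape, rect_hit_prob

__all__ = [
    "MotorError",
    "fit_true_distribution",
    "isotropy_test",
    "qq_linearity",
    "correlation_sensitivity",
    "read_endpoints_csv",
    "fit_report",
]


@dataclass(frozen=True)
class MotorError:
    """Fitted true endpoint distribution.

    ``sigma_h``/``sigma_v`` are the per-axis sample SDs in mm (timeouts
    excluded, n−1 denominator), ``rho`` the Pearson correlation and
    ``n_used`` the number of endpoints entering the fit.
    """

    sigma_h: float
    sigma_v: float
    rho: float
    n_used: int

    def __post_init__(self) -> None:
        if not (self.sigma_h > 0 and self.sigma_v > 0):
            raise ValueError("sigma_h and sigma_v must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")

    @property
    def sigma2(self) -> float:
        """Variance parameter σ² = σh·σv (mm²)."""
        return self.sigma_h * self.sigma_v

    @property
    def eta(self) -> float:
        """Anisotropy η = σv/σh (1 = isotropic)."""
        return self.sigma_v / self.sigma_h

    @property
    def sigma_bar(self) -> float:
        """Mean standard deviation σ̄ = (σh + σv)/2 (mm)."""
        return 0.5 * (self.sigma_h + self.sigma_v)


def _usable_xy(endpoints) -> np.ndarray:
    """(n, 2) array of non-timeout endpoint coordinates."""
    if isinstance(endpoints, pd.DataFrame):
        mask = ~endpoints["timed_out"].astype(bool).to_numpy()
        return endpoints.loc[mask, ["x_mm", "y_mm"]].to_numpy(dtype=float)
    rows = []
    for e in endpoints:
        if getattr(e, "timed_out", False):
            continue
        rows.append((e.x, e.y))
    return np.asarray(rows, dtype=float).reshape(-1, 2)


def fit_true_distribution(endpoints) -> MotorError:
    """Fit per-axis SDs and Pearson correlation of non-timeout endpoints.

    Accepts a sequence of endpoint samples (objects with ``x``, ``y`` and
    ``timed_out``) or a DataFrame with columns ``x_mm``, ``y_mm``,
    ``timed_out``.  Raises on fewer than 2 usable samples or degenerate
    (zero-variance) data.
    """
    xy = _usable_xy(endpoints)
    n = xy.shape[0]
    if n < 2:
        raise ValueError("need at least 2 non-timeout endpoints")
    sh = float(np.std(xy[:, 0], ddof=1))
    sv = float(np.std(xy[:, 1], ddof=1))
    if sh == 0.0 or sv == 0.0:
        raise ValueError("degenerate endpoint sample: zero variance on an axis")
    rho = float(np.corrcoef(xy[:, 0], xy[:, 1])[0, 1])
    return MotorError(sigma_h=sh, sigma_v=sv, rho=rho, n_used=n)


def isotropy_test(endpoints, alpha: float = 0.05) -> dict:
    """One-tailed F test of σv² > σh² on the endpoint sample.

    F = s_v²/s_h² with (n−1, n−1) degrees of freedom; the p-value is the
    upper tail, i.e. evidence for vertical elongation.
    """
    xy = _usable_xy(endpoints)
    n = xy.shape[0]
    if n < 2:
        raise ValueError("need at least 2 non-timeout endpoints")
    vh = float(np.var(xy[:, 0], ddof=1))
    vv = float(np.var(xy[:, 1], ddof=1))
    if vh == 0.0:
        raise ValueError("zero horizontal variance")
    F = vv / vh
    p = float(stats.f.sf(F, n - 1, n - 1))
    return {"F": F, "p": p, "vertical_elongated": bool(p < alpha)}


def qq_linearity(endpoints) -> dict:
    """Pearson correlation of sample quantiles vs standard normal quantiles.

    Operationalizes the visual Q-Q linearity check: values near 1 on both
    axes indicate a distribution close to bivariate Gaussian; heavy or
    truncated tails pull the correlation down.
    """
    xy = _usable_xy(endpoints)
    n = xy.shape[0]
    if n < 10:
        raise ValueError("need at least 10 non-timeout endpoints for Q-Q check")
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.norm.ppf(probs)
    out = {}
    for name, col in (("r_x", xy[:, 0]), ("r_y", xy[:, 1])):
        sample = np.sort(col)
        if np.ptp(sample) == 0.0:
            raise ValueError("degenerate endpoint sample: zero variance on an axis")
        out[name] = float(np.corrcoef(sample, theo)[0, 1])
    return out


def correlation_sensitivity(motor: MotorError, rects: Sequence[TargetShape]) -> float:
    """Max change (percentage points) in rectangle hit probability from ρ.

    For each axis-aligned, centered rectangle, compares the bivariate
    Gaussian hit probability with the fitted correlation against the
    uncorrelated approximation actually used by the analysis, and returns
    the largest absolute difference ×100.
    """
    worst = 0.0
    for rect in rects:
        if rect.kind != "rectangle":
            raise ValueError("correlation_sensitivity expects rectangles")
        p_rho = rect_hit_prob(rect, motor.sigma_h, motor.sigma_v, motor.rho)
        p_0 = rect_hit_prob(rect, motor.sigma_h, motor.sigma_v, 0.0)
        worst = max(worst, abs(p_rho - p_0) * 100.0)
    return worst


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_endpoints_csv(path) -> pd.DataFrame:
    """Read an endpoint table (columns x_mm, y_mm, timed_out)."""
    df = pd.read_csv(path)
    missing = {"x_mm", "y_mm", "timed_out"} - set(df.columns)
    if missing:
        raise ValueError(f"endpoint CSV missing columns: {sorted(missing)}")
    return df


def fit_report(endpoints, alpha: float = 0.05) -> dict:
    """JSON-serializable summary: fit, isotropy test and Q-Q linearity."""
    motor = fit_true_distribution(endpoints)
    report = {
        "motor_error": asdict(motor),
        "derived": {"sigma2": motor.sigma2, "eta": motor.eta,
                    "sigma_bar": motor.sigma_bar},
        "isotropy_test": isotropy_test(endpoints, alpha=alpha),
    }
    try:
        report["qq_linearity"] = qq_linearity(endpoints)
    except ValueError:
        report["qq_linearity"] = None
    return report
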