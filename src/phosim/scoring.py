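"""Reading-performance scoring: accuracy, speed, and acuity.

For each trial class (font condition f x viewing condition v) with N
observations of (n words, e misread, t seconds):

    accuracy   alpha_{f,v} = (1/N) sum_i (n_i - e_i) / n_i
    speed      beta_{f,v}  = (1/N) sum_i (n_i - e_i) / t_i   [per minute]

Reading acuity gamma_v interprets the summed accuracies as the
fractional number of size steps read down from the base size:

    gamma_v = Delta_0 + sum_f Delta_f * alpha_{f,v}

with Delta_0 the base (largest) size and Delta_f the (negative) size
step carried by each smaller font; the largest font carries no step
weight, so perfect reading yields exactly the smallest tested size.
With the uniform -0.1 logMAR steps and a single observation per class
these reduce to the classic MNREAD formulas.  A more robust acuity is
the midpoint of a logistic fit to alpha versus letter size with
asymptotes fixed at 0 and 1.

The acuity-surplus computation compares measured acuity differences
between density tiers against the expectation from two-dimensional
sampling density (0.5 * log10 of the count ratio).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .geometry import expected_acuity_gain
from .trial_engine import FONT_LADDER, VIEWING_CONDITIONS

__all__ = [
    "reading_accuracy",
    "reading_speed",
    "reading_acuity_mnread",
    "LogisticAcuityFit",
    "reading_acuity_logistic",
    "acuity_surplus",
    "ScoreTable",
    "score_log",
]


def _obs_arrays(observations, with_time: bool):
    obs = list(observations)
    if not obs:
        raise ValueError("need at least one observation")
    n = np.array([o[0] for o in obs], dtype=float)
    e = np.array([o[1] for o in obs], dtype=float)
    if np.any(n <= 0):
        raise ValueError("word counts must be positive")
    if np.any(e < 0) or np.any(e > n):
        raise ValueError("errors must satisfy 0 <= e <= n")
    if not with_time:
        return n, e
    t = np.array([o[2] for o in obs], dtype=float)
    if np.any(t <= 0):
        raise ValueError("reading times must be positive")
    return n, e, t


def reading_accuracy(observations) -> float:
    """Mean fraction of words read correctly over (n, e[, t]) observations."""
    n, e = _obs_arrays([(o[0], o[1]) for o in observations], with_time=False)
    return float(np.mean((n - e) / n))


def reading_speed(observations) -> float:
    """Correctly read words per minute over (n, e, t_seconds) observations."""
    n, e, t = _obs_arrays(observations, with_time=True)
    return float(np.mean((n - e) / t) * 60.0)


def reading_acuity_mnread(
    alphas,
    sizes=FONT_LADDER,
    include_largest: bool = False,
) -> float:
    """Acuity from accuracies across font sizes (largest first).

    ``alphas[i]`` is the accuracy at ``sizes[i]``; sizes must descend.
    Each font after the first carries its size step as weight.  With
    ``include_largest`` the classic base-plus-step parameterization is
    used instead: the base is one step above the largest size and the
    largest font's accuracy is weighted too (identical result for
    perfect reading on a uniform ladder extended by one line).
    """
    a = np.asarray(list(alphas), dtype=float)
    s = np.asarray(list(sizes), dtype=float)
    if a.shape != s.shape:
        raise ValueError("alphas and sizes must have matching lengths")
    if np.any((a < 0) | (a > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    steps = np.diff(s)
    if np.any(steps >= 0):
        raise ValueError("sizes must be strictly decreasing (largest first)")
    if include_largest:
        base = s[0] - steps[0]  # one step above the largest size
        weights = np.concatenate([[s[0] - base], steps])
        return float(base + np.sum(weights * a))
    return float(s[0] + np.sum(steps * a[1:]))


def clip_to_tested_range(gamma: float, sizes=FONT_LADDER) -> tuple[float, bool]:
    """Clip an acuity to the tested size range; the flag marks values
    that fell outside (the true value is then out of range)."""
    lo, hi = min(sizes), max(sizes)
    if gamma < lo:
        return lo, True
    if gamma > hi:
        return hi, True
    return gamma, False


@dataclass(frozen=True)
class LogisticAcuityFit:
    """Midpoint/slope of a logistic accuracy-versus-size fit.

    ``slope_pct_per_logmar`` is the curve's maximum derivative expressed
    in percentage points per logMAR (= 25 * k for asymptotes 0..100%).
    """

    midpoint_logmar: "float | None"
    k_per_logmar: "float | None"
    slope_pct_per_logmar: "float | None"
    converged: bool
    degenerate: bool

    @property
    def ok(self) -> bool:
        return self.converged and not self.degenerate


def reading_acuity_logistic(alphas, sizes=FONT_LADDER) -> LogisticAcuityFit:
    """Fit alpha(size) = 1 / (1 + exp(-k (size - m))) by least squares.

    Asymptotes are fixed at 0 and 1.  Data that never leave one
    asymptote (all ~0 or all ~1) carry no midpoint information and are
    flagged degenerate.  ``m`` is initialized at the 50% crossing of
    linear interpolation and ``k`` at 10 per logMAR.
    """
    a = np.asarray(list(alphas), dtype=float)
    s = np.asarray(list(sizes), dtype=float)
    if a.size != s.size or a.size < 3:
        raise ValueError("need accuracies at three or more sizes")
    if np.all(a > 0.999) or np.all(a < 0.001):
        return LogisticAcuityFit(None, None, None, False, True)

    order = np.argsort(s)
    ss, aa = s[order], a[order]
    m0 = ss[np.argmin(np.abs(aa - 0.5))]
    for i in range(len(ss) - 1):
        lo_a, hi_a = aa[i], aa[i + 1]
        if (lo_a - 0.5) * (hi_a - 0.5) <= 0 and lo_a != hi_a:
            m0 = ss[i] + (0.5 - lo_a) * (ss[i + 1] - ss[i]) / (hi_a - lo_a)
            break

    def resid(theta):
        m, k = theta
        return 1.0 / (1.0 + np.exp(-k * (s - m))) - a

    sol = optimize.least_squares(
        resid,
        [m0, 10.0],
        bounds=([s.min() - 1.0, 1e-2], [s.max() + 1.0, 1e4]),
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
    )
    m, k = sol.x
    return LogisticAcuityFit(
        float(m), float(k), float(25.0 * k), bool(sol.success), False
    )


def acuity_surplus(acuities, counts) -> tuple[np.ndarray, float]:
    """Observed-minus-expected acuity change between adjacent tiers.

    ``acuities`` are measured acuities ordered by decreasing phosphene
    count; ``counts`` are the matching totals.  For each adjacent pair
    the surplus is the observed acuity difference minus the expected
    two-dimensional sampling gain ``0.5 * log10(count_hi / count_lo)``.
    Returns the per-pair surpluses and their mean.
    """
    a = np.asarray(list(acuities), dtype=float)
    c = np.asarray(list(counts), dtype=float)
    if a.size != c.size:
        raise ValueError("acuities and counts must have matching lengths")
    if a.size < 2:
        raise ValueError("need at least two tiers")
    if np.any(np.diff(c) >= 0):
        raise ValueError("counts must be ordered decreasing")
    per_pair = np.array(
        [
            (a[i + 1] - a[i]) - expected_acuity_gain(c[i], c[i + 1])
            for i in range(a.size - 1)
        ]
    )
    return per_pair, float(np.mean(per_pair))


@dataclass
class ScoreTable:
    """Per-class accuracy and speed plus per-condition acuities."""

    by_class: pd.DataFrame  # font_condition, viewing_condition, alpha, beta_wpm
    by_condition: pd.DataFrame  # gamma, clipped gamma + flag, logistic fit
    sizes: tuple

    def to_json(self) -> str:
        return json.dumps(
            {
                "sizes": list(self.sizes),
                "by_class": self.by_class.to_dict(orient="records"),
                "by_condition": self.by_condition.to_dict(orient="records"),
            },
            indent=1,
            default=lambda o: None if o is None or (isinstance(o, float) and math.isnan(o)) else o,
        )


def score_log(log: pd.DataFrame, sizes=FONT_LADDER) -> ScoreTable:
    """Score a trial-log table (columns font_condition, viewing_condition,
    n_words, errors, t_reading_s; incomplete trials count as unread)."""
    df = log.copy()
    # a declared-unreadable or incomplete trial reads nothing
    df["errors"] = df["errors"].where(df.get("complete", True), df["n_words"])
    if df["errors"].isna().any():
        raise ValueError("trial log contains unscored trials (errors missing)")
    df["t_reading_s"] = df["t_reading_s"].fillna(np.inf)

    class_rows = []
    for (f, v), grp in df.groupby(["font_condition", "viewing_condition"]):
        obs = list(zip(grp["n_words"], grp["errors"], grp["t_reading_s"]))
        alpha = reading_accuracy(obs)
        finite = [(n, e, t) for n, e, t in obs if np.isfinite(t)]
        beta = reading_speed(finite) if finite else 0.0
        class_rows.append(
            {
                "font_condition": f,
                "font_logmar": sizes[f - 1],
                "viewing_condition": v,
                "viewing_name": VIEWING_CONDITIONS[v - 1],
                "n_obs": len(obs),
                "alpha": alpha,
                "beta_wpm": beta,
            }
        )
    by_class = pd.DataFrame(class_rows)

    cond_rows = []
    for v, grp in by_class.groupby("viewing_condition"):
        grp = grp.sort_values("font_condition")
        alphas = grp["alpha"].to_numpy()
        gamma = reading_acuity_mnread(alphas, sizes)
        gamma_clipped, out_of_range = clip_to_tested_range(gamma, sizes)
        fit = reading_acuity_logistic(alphas, sizes)
        cond_rows.append(
            {
                "viewing_condition": v,
                "viewing_name": VIEWING_CONDITIONS[v - 1],
                "gamma_logmar": gamma,
                "gamma_clipped_logmar": gamma_clipped,
                "gamma_out_of_range": out_of_range,
                "logistic_midpoint_logmar": fit.midpoint_logmar,
                "logistic_slope_pct_per_logmar": fit.slope_pct_per_logmar,
                "logistic_ok": fit.ok,
            }
        )
    by_condition = pd.DataFrame(cond_rows)
    return ScoreTable(by_class, by_condition, tuple(sizes))
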