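"""Statistical summaries of classifier validation accuracy.

Accuracies are treated as binomial proportions. Confidence intervals use
the Agresti-Coull adjustment: with ``z`` the normal quantile, the adjusted
count is ``x~ = x + z^2 / 2`` over ``n~ = n + z^2`` trials and the interval
is ``p~ +/- z * sqrt(p~ (1 - p~) / n~)``. A model is called significantly
better than chance when the whole interval lies strictly above 0.5.
Two accuracies on the same validation set are compared with an unpooled
Wald interval on the difference of proportions and with McNemar's test on
the discordant predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

#: two-sided 95% normal quantile
Z_95 = 1.959964


class StatsError(ValueError):
    pass


def _check_counts(x: int, n: int) -> None:
    if n <= 0:
        raise StatsError(f"n must be positive, got {n}")
    if not 0 <= x <= n:
        raise StatsError(f"successes ({x}) must be within [0, {n}]")


@dataclass(frozen=True)
class PropCI:
    """A binomial proportion with its confidence interval."""

    p_hat: float
    lo: float
    hi: float
    n: int

    def contains(self, p: float) -> bool:
        return self.lo <= p <= self.hi


def agresti_coull_ci(x: int, n: int, z: float = Z_95) -> PropCI:
    """Agresti-Coull interval for ``x`` successes in ``n`` trials,
    clipped to [0, 1]."""
    _check_counts(x, n)
    n_t = n + z * z
    p_t = (x + z * z / 2.0) / n_t
    half = z * np.sqrt(p_t * (1.0 - p_t) / n_t)
    return PropCI(
        p_hat=x / n,
        lo=float(max(0.0, p_t - half)),
        hi=float(min(1.0, p_t + half)),
        n=n,
    )


def significant_vs_chance(ci: PropCI, chance: float = 0.5) -> bool:
    """True iff the whole interval lies strictly above ``chance``."""
    return ci.lo > chance


def two_proportion_diff_ci(
    x1: int, n1: int, x2: int, n2: int, z: float = Z_95
) -> tuple[float, float, float]:
    """Unpooled Wald interval for ``p1 - p2``: returns
    ``(diff, lo, hi)``."""
    _check_counts(x1, n1)
    _check_counts(x2, n2)
    p1, p2 = x1 / n1, x2 / n2
    se = np.sqrt(p1 * (1.0 - p1) / n1 + p2 * (1.0 - p2) / n2)
    d = p1 - p2
    return float(d), float(d - z * se), float(d + z * se)


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float
    b: int
    c: int


def mcnemar(b: int, c: int, continuity: bool = False) -> McNemarResult:
    """McNemar's test from the discordant counts: ``b`` cases the first
    model got right and the second wrong, ``c`` the reverse.

    The plain (no continuity correction) statistic is
    ``(b - c)^2 / (b + c)``, chi-squared with 1 df.
    """
    if b < 0 or c < 0:
        raise StatsError("discordant counts must be non-negative")
    if b + c == 0:
        raise StatsError("McNemar's test is undefined with no discordant pairs")
    num = abs(b - c) - (1.0 if continuity else 0.0)
    stat = max(num, 0.0) ** 2 / (b + c)
    p = float(sps.chi2.sf(stat, df=1))
    return McNemarResult(float(stat), p, b, c)


def discordant_counts(
    y_true: np.ndarray, pred_a: np.ndarray, pred_b: np.ndarray
) -> tuple[int, int]:
    """Discordant pair counts (b, c) of two prediction vectors on the same
    validation labels: b = A right and B wrong, c = B right and A wrong."""
    y_true = np.asarray(y_true).ravel()
    pred_a = np.asarray(pred_a).ravel()
    pred_b = np.asarray(pred_b).ravel()
    if not (y_true.shape == pred_a.shape == pred_b.shape):
        raise StatsError("prediction vectors differ in length")
    a_ok = pred_a == y_true
    b_ok = pred_b == y_true
    return int(np.sum(a_ok & ~b_ok)), int(np.sum(b_ok & ~a_ok))


def round_half_up(x: float, digits: int = 2) -> float:
    """Display rounding with ties away from zero (0.005 -> 0.01), matching
    conventional reporting of proportions."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_ci(ci: PropCI, digits: int = 2) -> str:
    return (
        f"{round_half_up(ci.p_hat, digits):.{digits}f} "
        f"({round_half_up(ci.lo, digits):.{digits}f}, "
        f"{round_half_up(ci.hi, digits):.{digits}f})"
    )


def report_table(rows: list[dict]) -> pd.DataFrame:
    """Accuracy report: one row per (model, participant-or-pooled) with the
    Agresti-Coull interval and the strict above-chance call.

    Each input row needs ``model``, ``unit`` (participant id or "pooled"),
    ``correct`` and ``n``.
    """
    out = []
    for r in rows:
        ci = agresti_coull_ci(int(r["correct"]), int(r["n"]))
        out.append(
            dict(
                model=r["model"],
                unit=r["unit"],
                n=ci.n,
                accuracy=ci.p_hat,
                ci_lo=ci.lo,
                ci_hi=ci.hi,
                display=format_ci(ci),
                significant=significant_vs_chance(ci),
            )
        )
    return pd.DataFrame(out)
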