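"""Power-function fit of the older:premature ratio against 40q30.

Fits y = a * x^b where x is the premature probability of NCD death (40q30)
and y the older:premature ratio (20q70 / 40q30).  Two estimators:

* ``"nls"`` (default): nonlinear least squares on the original scale,
  initialised from the log-log ordinary-least-squares solution, so the
  optimisation is deterministic;
* ``"loglog"``: OLS of log y on log x, i.e. geometric-mean-relative errors.

Whatever the estimator, the goodness of fit r^2 is always computed on the
original (untransformed) scale as 1 - SS_res / SS_tot — a single
unambiguous definition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .lifetable import MetricInstance, metrics_to_frame

logger = logging.getLogger(__name__)

__all__ = ["ConvergenceError", "PowerFitResult", "fit_by_group", "fit_power", "predict"]

#: relative parameter tolerance for the nonlinear solver
XTOL = 1e-10
#: cap on solver function evaluations before declaring failure
MAX_NFEV = 400


class ConvergenceError(RuntimeError):
    """The nonlinear solver hit its evaluation budget without converging."""


@dataclass(frozen=True)
class PowerFitResult:
    """Fitted coefficients of ratio = a * (40q30)^b with original-scale r^2."""

    a: float
    b: float
    r2: float
    n: int
    group: str = "overall"
    method: str = "nls"

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("multiplicative coefficient a must be positive")
        if self.n < 3:
            raise ValueError("a power fit needs at least 3 points")


def _r2_original_scale(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    # flat response carries no explainable variance; the threshold guards
    # against SST that is pure floating-point summation residue
    if ss_tot <= 1e-20 * len(y) * float(np.mean(y**2)):
        return 0.0
    return 1.0 - ss_res / ss_tot


def fit_power(x, y, method: str = "nls", group: str = "overall") -> PowerFitResult:
    """Fit y = a * x^b to positive (x, y) pairs.

    Raises on nonpositive data (the log-log initialisation is undefined),
    on degenerate x (all equal) and on solver non-convergence — never a
    silent best-so-far.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.any(x <= 0) or np.any(y <= 0) or not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("all x and y must be positive and finite")
    if np.all(x == x[0]):
        raise ValueError("degenerate fit: all x values are equal")
    if method not in ("nls", "loglog"):
        raise ValueError("method must be 'nls' or 'loglog'")

    lx, ly = np.log(x), np.log(y)
    b0, la0 = np.polyfit(lx, ly, 1)
    a0 = float(np.exp(la0))

    if method == "loglog":
        a, b = a0, float(b0)
    else:
        res = least_squares(
            lambda p: p[0] * x ** p[1] - y,
            x0=[a0, float(b0)],
            bounds=([0.0, -np.inf], [np.inf, np.inf]),
            xtol=XTOL, ftol=None, gtol=None,
            max_nfev=MAX_NFEV,
        )
        if res.status == 0 or not res.success:
            raise ConvergenceError(
                f"power fit did not converge in {MAX_NFEV} evaluations (group={group})"
            )
        a, b = float(res.x[0]), float(res.x[1])

    r2 = _r2_original_scale(y, a * x ** b)
    return PowerFitResult(a=a, b=b, r2=r2, n=n, group=group, method=method)


def predict(fit: PowerFitResult, x):
    """Predicted ratio a * x^b; strictly decreasing in x when b < 0."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("x must be positive")
    out = fit.a * arr ** fit.b
    return out if np.ndim(x) else float(out)


def fit_by_group(
    instances: Iterable[MetricInstance] | pd.DataFrame,
    grouping: str | None = None,
    method: str = "nls",
    min_size: int = 3,
) -> list[PowerFitResult]:
    """Overall fit plus one fit per level of ``grouping`` (sex, year or unit).

    Instances with undefined ratio are excluded; groups smaller than
    ``min_size`` are skipped with a logged warning.
    """
    frame = instances if isinstance(instances, pd.DataFrame) else metrics_to_frame(instances)
    frame = frame[np.isfinite(frame["ratio"]) & (frame["q40_30"] > 0)]
    results = [fit_power(frame["q40_30"], frame["ratio"], method=method, group="overall")]
    if grouping is None:
        return results
    if grouping not in ("sex", "year", "unit"):
        raise ValueError("grouping must be 'sex', 'year' or 'unit'")
    for level, g in frame.groupby(grouping, sort=True):
        if len(g) < min_size:
            logger.warning("group %s=%s has %d < %d instances; skipped", grouping, level, len(g), min_size)
            continue
        results.append(fit_power(g["q40_30"], g["ratio"], method=method, group=str(level)))
    return results
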