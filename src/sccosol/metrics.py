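"""Fit-quality statistics and model ranking.

All residual-based statistics are computed in mole-fraction space (not log
space, not g/L), so SSE magnitudes for the study dataset land around 1e-8.
Model comparison uses the corrected Akaike information criterion

    AICc = n ln(sigma^2) + 2Q + 2Q(Q+1)/(n - Q - 1),  sigma^2 = SSE/n,

with Q the number of fitted constants; the maximum-likelihood variance
SSE/n (not SSE/(n-Q)) is the convention that makes the criterion consistent
with its derivation from the Gaussian log-likelihood. Lower is better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fitting import FitResult
from .models import get_model

__all__ = [
    "MetricsReport",
    "aard_percent",
    "aicc",
    "r_squared",
    "r_squared_adj",
    "sse",
    "rmse",
    "compute_metrics",
    "rank_models",
]


def _check_vectors(y_exp, y_calc):
    y_exp = np.asarray(y_exp, dtype=float)
    y_calc = np.asarray(y_calc, dtype=float)
    if y_exp.shape != y_calc.shape or y_exp.ndim != 1 or y_exp.size < 1:
        raise ValueError("y_exp and y_calc must be equal-length 1-D vectors")
    return y_exp, y_calc


def aard_percent(y_exp, y_calc) -> float:
    """Average absolute relative deviation, in percent:
    ``100/n * sum |y_calc - y_exp| / y_exp``."""
    y_exp, y_calc = _check_vectors(y_exp, y_calc)
    if np.any(y_exp <= 0):
        raise ValueError("aard requires strictly positive experimental values")
    return float(100.0 * np.mean(np.abs(y_calc - y_exp) / y_exp))


def sse(y_exp, y_calc) -> float:
    y_exp, y_calc = _check_vectors(y_exp, y_calc)
    return float(np.sum((y_calc - y_exp) ** 2))


def rmse(y_exp, y_calc) -> float:
    y_exp, y_calc = _check_vectors(y_exp, y_calc)
    return math.sqrt(sse(y_exp, y_calc) / y_exp.size)


def aicc(sse_value: float, n: int, q: int) -> float:
    """Corrected AIC from a sum of squared errors (sigma^2 = SSE/n)."""
    if sse_value <= 0:
        raise ValueError("sse must be > 0")
    if n <= q + 1:
        raise ValueError(f"AICc needs n > q + 1 (got n={n}, q={q})")
    sigma2 = sse_value / n
    return n * math.log(sigma2) + 2 * q + 2 * q * (q + 1) / (n - q - 1)


def r_squared(y_exp, y_calc) -> float:
    """Coefficient of determination about the experimental mean."""
    y_exp, y_calc = _check_vectors(y_exp, y_calc)
    sst = float(np.sum((y_exp - y_exp.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero variance in y_exp; R^2 undefined")
    return 1.0 - sse(y_exp, y_calc) / sst


def r_squared_adj(r2: float, n: int, q: int) -> float:
    if n <= q + 1:
        raise ValueError(f"adjusted R^2 needs n > q + 1 (got n={n}, q={q})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)


@dataclass(frozen=True)
class MetricsReport:
    model_id: str
    aard_percent: float
    sse: float
    rmse: float
    r2: float
    r2_adj: float
    aicc: float
    n: int
    q: int


def compute_metrics(y_exp, fit: FitResult) -> MetricsReport:
    """Full metrics report for one fit, on mole-fraction residuals."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_calc = np.asarray(fit.predictions)
    n = y_exp.size
    q = get_model(fit.parameter_set.model_id).parameter_count
    sse_v = sse(y_exp, y_calc)
    r2 = r_squared(y_exp, y_calc)
    return MetricsReport(
        model_id=fit.parameter_set.model_id,
        aard_percent=aard_percent(y_exp, y_calc),
        sse=sse_v,
        rmse=math.sqrt(sse_v / n),
        r2=r2,
        r2_adj=r_squared_adj(r2, n, q),
        aicc=aicc(sse_v, n, q),
        n=n,
        q=q,
    )


def rank_models(reports: list[MetricsReport]) -> list[MetricsReport]:
    """Sort ascending by AICc (best first); ties break on AARD then model id."""
    if not reports:
        raise ValueError("need at least one report to rank")
    return sorted(reports, key=lambda r: (r.aicc, r.aard_percent, r.model_id))
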