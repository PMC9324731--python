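"""Theoretical prediction of residual-PCA loadings under a serial-position
difficulty shift.

A shift ``ddelta`` in the perceived difficulty of an item moves its fit
residual by ``-K * ddelta``, where ``K = dP/d(delta) = -P(1-P)`` is the
response sensitivity. Averaged over a normally distributed cohort ability,
the loading of an explanatory variable ``x`` on a residual contrast is
proportional to ``a_x * ddelta * E[K]`` with ``a_x`` the variable's loading
from the explanatory-variable PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm

from .errors import ParameterError
from .rasch_core import sensitivity

__all__ = [
    "AbilityDistribution",
    "LoadingPrediction",
    "shifted_residual",
    "integrated_sensitivity",
    "predict_loadings",
]


@dataclass(frozen=True)
class AbilityDistribution:
    """Normal cohort ability distribution (mean and sd in logits)."""

    mean: float = -0.6
    sd: float = 1.0

    def __post_init__(self):
        if self.sd <= 0:
            raise ParameterError(f"ability sd must be > 0, got {self.sd}")

    def pdf(self, theta):
        return norm.pdf(theta, loc=self.mean, scale=self.sd)


def shifted_residual(y, theta, delta, ddelta):
    """Residual after a difficulty shift: ``y - K(theta, delta) * ddelta``."""
    return np.asarray(y, dtype=float) - sensitivity(theta, delta) * ddelta


def integrated_sensitivity(
    delta: float,
    dist: AbilityDistribution,
    abs_tol: float = 1e-8,
    span_sd: float = 8.0,
) -> float:
    """Cohort-averaged sensitivity ``E[K] = int p(theta) * K(theta, delta)
    dtheta`` over ``mean +/- span_sd * sd``.

    Always in (-0.25, 0); largest in magnitude when the item difficulty sits
    at the cohort mean, and an even function of ``delta - mean``.
    """
    lo = dist.mean - span_sd * dist.sd
    hi = dist.mean + span_sd * dist.sd
    val, err = integrate.quad(
        lambda th: dist.pdf(th) * sensitivity(th, delta),
        lo,
        hi,
        epsabs=abs_tol,
        limit=200,
    )
    if not np.isfinite(val) or err > max(abs_tol * 100, 1e-6):
        raise ArithmeticError(
            f"quadrature did not converge (value {val}, error estimate {err})"
        )
    return float(val)


@dataclass(frozen=True)
class LoadingPrediction:
    """Predicted residual-contrast loadings, item by explanatory variable.

    ``raw`` holds the proportional-scale predictions
    ``a_x * ddelta_x * E[K](delta_j)``; ``scaled`` is the optional
    least-squares rescaling against an empirical loading vector.
    """

    table: pd.DataFrame
    integrated: np.ndarray
    dist: AbilityDistribution
    ddelta: dict[str, float]
    scale_factor: Optional[float] = None

    @property
    def raw(self) -> pd.DataFrame:
        cols = [c for c in self.table.columns if c.startswith("pred_")]
        return self.table[cols]


def predict_loadings(
    coefficients: Mapping[str, float],
    ddelta: Union[float, Mapping[str, float]],
    delta: np.ndarray,
    dist: AbilityDistribution = AbilityDistribution(),
    rescale_to: Optional[np.ndarray] = None,
    rescale_variable: Optional[str] = None,
) -> LoadingPrediction:
    """Per-item loading predictions for each explanatory variable.

    ``coefficients`` maps variable name to its PCA1 loading ``a_{p,x}``;
    ``ddelta`` is a common or per-variable difficulty shift in logits;
    ``delta`` holds the empirical item difficulties at which the sensitivity
    integral is evaluated. When ``rescale_to`` is given, a single scale
    factor is fitted by least squares between the prediction column
    ``rescale_variable`` (default: first variable) and the empirical vector.
    """
    if not coefficients:
        raise ParameterError("coefficients mapping is empty (run the explanatory PCA first)")
    delta = np.asarray(delta, dtype=float)
    if isinstance(ddelta, Mapping):
        shifts = {v: float(ddelta.get(v, 0.0)) for v in coefficients}
    else:
        shifts = {v: float(ddelta) for v in coefficients}
    integ = np.array([integrated_sensitivity(d, dist) for d in delta])
    table = pd.DataFrame({"item": np.arange(1, delta.size + 1), "delta": delta, "E_K": integ})
    for var, a in coefficients.items():
        table[f"pred_{var}"] = a * shifts[var] * integ
    scale = None
    if rescale_to is not None:
        var = rescale_variable or next(iter(coefficients))
        pred = table[f"pred_{var}"].to_numpy()
        emp = np.asarray(rescale_to, dtype=float)
        if emp.shape != pred.shape:
            raise ParameterError("rescale_to must have one value per item")
        denom = float(pred @ pred)
        scale = float(emp @ pred / denom) if denom > 0 else np.nan
        for v in coefficients:
            table[f"scaled_{v}"] = scale * table[f"pred_{v}"]
    return LoadingPrediction(
        table=table, integrated=integ, dist=dist, ddelta=shifts, scale_factor=scale
    )
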