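"""Dichotomous Rasch model: probabilities, joint (JMLE) estimation,
standardized residuals, sensitivity, and back-conversion to the success
probability scale with asymmetric coverage intervals.

The log-odds of success for person ``i`` on item ``j`` is ``theta_i -
delta_j``. Joint maximum-likelihood estimation alternates damped Newton steps
over person and item parameters with items centered to mean zero for
identification. Standard uncertainties come from the observed information,
``u = 1/sqrt(sum P(1-P))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConvergenceError, DegenerateDataError, FormatError

__all__ = [
    "ResponseMatrix",
    "RaschConfig",
    "RaschEstimates",
    "PSuccessInterval",
    "success_probability",
    "sensitivity",
    "fit_rasch",
    "standardized_residuals",
    "to_psuccess",
]


@dataclass(frozen=True)
class ResponseMatrix:
    """Binary person x item scores; NaN marks missing responses."""

    data: np.ndarray
    person_ids: tuple[str, ...] = ()
    item_ids: tuple[str, ...] = ()
    groups: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", arr)
        if arr.ndim != 2:
            raise FormatError(f"response matrix must be 2-D, got shape {arr.shape}")
        finite = arr[~np.isnan(arr)]
        if not np.all(np.isin(finite, (0.0, 1.0))):
            bad = finite[~np.isin(finite, (0.0, 1.0))][0]
            raise FormatError(f"responses must be 0/1/missing, found {bad!r}")
        n, L = arr.shape
        if not self.person_ids:
            object.__setattr__(self, "person_ids", tuple(f"P{i+1}" for i in range(n)))
        if not self.item_ids:
            object.__setattr__(self, "item_ids", tuple(f"I{j+1}" for j in range(L)))
        if len(self.person_ids) != n:
            raise FormatError("person_ids length does not match row count")
        if len(self.item_ids) != L:
            raise FormatError("item_ids length does not match column count")
        if self.groups is not None and len(self.groups) != n:
            raise FormatError("groups length does not match row count")

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.data)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, index=list(self.person_ids), columns=list(self.item_ids))
        df.index.name = "person"
        if self.groups is not None:
            df.insert(0, "group", list(self.groups))
        return df


@dataclass(frozen=True)
class RaschConfig:
    """JMLE settings: convergence tolerance on the max parameter change
    (logits), iteration cap, optional (L-1)/L item-spread bias correction."""

    tol: float = 1e-4
    max_iter: int = 200
    bias_correction: bool = False
    max_step: float = 1.0


@dataclass(frozen=True)
class RaschEstimates:
    """Fitted person abilities and item difficulties with uncertainties.

    Extreme (all-correct / all-incorrect) persons and items carry NaN
    estimates and are flagged; item difficulties of non-extreme items are
    centered to mean zero.
    """

    theta: np.ndarray
    theta_se: np.ndarray
    delta: np.ndarray
    delta_se: np.ndarray
    extreme_persons: np.ndarray
    extreme_items: np.ndarray
    iterations: int
    max_change: float
    converged: bool

    @property
    def theta_mean(self) -> float:
        return float(np.nanmean(self.theta))

    @property
    def theta_sd(self) -> float:
        return float(np.nanstd(self.theta, ddof=1))

    def expanded_delta_uncertainty(self, k: float = 2.0) -> np.ndarray:
        return k * self.delta_se

    def item_frame(self, item_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "delta": self.delta,
                "delta_se": self.delta_se,
                "extreme": self.extreme_items,
            }
        )
        if item_ids is not None:
            df.index = list(item_ids)
        return df

    def person_frame(self, person_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "theta": self.theta,
                "theta_se": self.theta_se,
                "extreme": self.extreme_persons,
            }
        )
        if person_ids is not None:
            df.index = list(person_ids)
        return df


def success_probability(theta, delta):
    """P(correct) = logistic(theta - delta); elementwise on arrays."""
    return expit(np.asarray(theta, dtype=float) - np.asarray(delta, dtype=float))


def sensitivity(theta, delta):
    """dP/d(delta) = -P(1-P): always negative, peak magnitude 1/4 at
    theta == delta, symmetric in the sign of (theta - delta)."""
    p = success_probability(theta, delta)
    return -p * (1.0 - p)


def _flag_extremes(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively flag persons/items whose remaining responses are all 0 or
    all 1 (their ML estimates diverge)."""
    obs = ~np.isnan(data)
    ext_p = np.zeros(data.shape[0], dtype=bool)
    ext_i = np.zeros(data.shape[1], dtype=bool)
    while True:
        changed = False
        keep_i = ~ext_i
        for i in np.where(~ext_p)[0]:
            m = obs[i] & keep_i
            vals = data[i, m]
            if vals.size == 0 or vals.min() == vals.max():
                ext_p[i] = True
                changed = True
        keep_p = ~ext_p
        for j in np.where(~ext_i)[0]:
            m = obs[:, j] & keep_p
            vals = data[m, j]
            if vals.size == 0 or vals.min() == vals.max():
                ext_i[j] = True
                changed = True
        if not changed:
            return ext_p, ext_i


def fit_rasch(data: ResponseMatrix, config: RaschConfig = RaschConfig()) -> RaschEstimates:
    """Joint maximum-likelihood (JMLE) fit of the dichotomous Rasch model.

    Alternates Newton updates of all person abilities given item difficulties
    and vice versa, re-centering item difficulties to mean zero each sweep.
    Deterministic given data and config.
    """
    X = data.data
    n, L = X.shape
    if n < 2 or L < 2:
        raise DegenerateDataError(f"need at least 2 persons and 2 items, got {n}x{L}")
    ext_p, ext_i = _flag_extremes(X)
    keep_p, keep_i = ~ext_p, ~ext_i
    if keep_p.sum() == 0 or keep_i.sum() == 0:
        raise DegenerateDataError(
            "all persons or all items are extreme (responses carry no information)"
        )
    W = X[np.ix_(keep_p, keep_i)]
    obs = ~np.isnan(W)
    Wf = np.where(obs, W, 0.0)
    m, k = W.shape

    # logit-of-proportion start values
    p_person = Wf.sum(axis=1) / obs.sum(axis=1)
    p_item = Wf.sum(axis=0) / obs.sum(axis=0)
    theta = np.log(p_person / (1 - p_person))
    delta = -np.log(p_item / (1 - p_item))
    delta -= delta.mean()

    max_change = np.inf
    it = 0
    for it in range(1, config.max_iter + 1):
        P = expit(theta[:, None] - delta[None, :])
        info = P * (1 - P) * obs
        g_theta = (Wf - P * obs).sum(axis=1)
        step_t = np.clip(g_theta / info.sum(axis=1), -config.max_step, config.max_step)
        theta = theta + step_t

        P = expit(theta[:, None] - delta[None, :])
        info = P * (1 - P) * obs
        g_delta = (P * obs - Wf).sum(axis=0)
        step_d = np.clip(g_delta / info.sum(axis=0), -config.max_step, config.max_step)
        delta = delta + step_d
        shift = delta.mean()
        delta -= shift
        theta -= shift

        max_change = max(np.abs(step_t).max(), np.abs(step_d).max())
        if max_change < config.tol:
            break
    else:
        raise ConvergenceError(
            f"JMLE did not converge in {config.max_iter} iterations "
            f"(last max change {max_change:.3g} logits)",
            iterations=config.max_iter,
            max_change=max_change,
        )

    if config.bias_correction and k > 1:
        # classic JMLE spread correction: estimates are biased outward by
        # roughly k/(k-1); shrink both parameter sets
        delta = delta * (k - 1) / k
        theta = theta * (k - 1) / k

    P = expit(theta[:, None] - delta[None, :])
    info = P * (1 - P) * obs
    theta_se = 1.0 / np.sqrt(info.sum(axis=1))
    delta_se = 1.0 / np.sqrt(info.sum(axis=0))

    theta_full = np.full(n, np.nan)
    theta_se_full = np.full(n, np.nan)
    delta_full = np.full(L, np.nan)
    delta_se_full = np.full(L, np.nan)
    theta_full[keep_p] = theta
    theta_se_full[keep_p] = theta_se
    delta_full[keep_i] = delta
    delta_se_full[keep_i] = delta_se

    return RaschEstimates(
        theta=theta_full,
        theta_se=theta_se_full,
        delta=delta_full,
        delta_se=delta_se_full,
        extreme_persons=ext_p,
        extreme_items=ext_i,
        iterations=it,
        max_change=float(max_change),
        converged=True,
    )


def standardized_residuals(data: ResponseMatrix, est: RaschEstimates) -> np.ndarray:
    """Residual matrix ``(x - P) / sqrt(P(1-P))``; missing cells and cells of
    extreme persons/items propagate as NaN."""
    P = expit(est.theta[:, None] - est.delta[None, :])
    with np.errstate(invalid="ignore"):
        resid = (data.data - P) / np.sqrt(P * (1 - P))
    resid[est.extreme_persons, :] = np.nan
    resid[:, est.extreme_items] = np.nan
    return resid


@dataclass(frozen=True)
class PSuccessInterval:
    """Back-converted success probability with an asymmetric coverage
    interval obtained by converting the logit endpoints."""

    central: float
    low: float
    high: float
    k: float

    def __iter__(self):
        yield from (self.central, self.low, self.high)


def to_psuccess(measure: float, reference: float, U: float, k: float = 2.0) -> PSuccessInterval:
    """Convert a logit measure (relative to ``reference``) to the success
    probability scale; the interval endpoints are logistic transforms of
    ``measure -/+ k*U``, hence asymmetric away from P = 0.5."""
    if U < 0:
        raise ValueError(f"uncertainty must be >= 0, got {U}")
    central = float(success_probability(measure, reference))
    low = float(success_probability(measure - k * U, reference))
    high = float(success_probability(measure + k * U, reference))
    return PSuccessInterval(central=central, low=low, high=high, k=k)
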