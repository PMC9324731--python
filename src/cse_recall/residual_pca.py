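"""Principal contrasts of Rasch standardized residuals (PCA2) and
multidimensionality diagnostics.

The item-by-item Pearson correlation matrix of the standardized residuals
(pairwise-complete) is eigendecomposed; a component of that decomposition is
called a *contrast* and its eigenvalue is expressed in item units (the
eigenvalues of a correlation matrix sum to the number of items). A first
contrast with the strength of two or more items is the conventional warning
threshold for a secondary dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ParameterError
from .rasch_core import (
    RaschConfig,
    RaschEstimates,
    ResponseMatrix,
    fit_rasch,
    success_probability,
)

__all__ = [
    "ResidualContrast",
    "residual_contrasts",
    "variance_decomposition",
    "disattenuated_correlation",
    "DisattenuatedCorrelation",
    "linacre_checklist",
    "LinacreReport",
    "cluster_person_measures",
    "person_separation_reliability",
]

EIGENVALUE_THRESHOLD = 2.0


@dataclass(frozen=True)
class ResidualContrast:
    """Residual-PCA result: loadings per item and contrast, eigenvalues in
    item units, and a loading-based item clustering on contrast 1."""

    item_index: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    clusters: np.ndarray
    excluded_items: np.ndarray
    n_items: int

    @property
    def first_eigenvalue(self) -> float:
        return float(self.eigenvalues[0])

    def contrast(self, p: int) -> np.ndarray:
        """Loadings of contrast ``p`` (1-based) over the retained items."""
        return self.loadings[:, p - 1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"contrast{p+1}": self.loadings[:, p] for p in range(self.loadings.shape[1])}
        df = pd.DataFrame({"item": self.item_index + 1, **cols, "cluster": self.clusters})
        return df


def _cluster_by_loading(loadings: np.ndarray, n_clusters: int) -> np.ndarray:
    """Assign items to ``n_clusters`` ordered groups by contrast-1 loading
    quantiles (cluster 1 = highest loadings)."""
    ranks = pd.Series(loadings).rank(method="first", ascending=False).to_numpy()
    size = len(loadings) / n_clusters
    return np.minimum(((ranks - 1) // size).astype(int) + 1, n_clusters)


def residual_contrasts(
    residuals: np.ndarray,
    delta: Optional[np.ndarray] = None,
    n_clusters: int = 3,
) -> ResidualContrast:
    """Eigendecompose the item correlation matrix of standardized residuals.

    Items with zero residual variance (or no overlapping observations) are
    excluded with a warning. Loadings are signed so the highest-difficulty
    item (per ``delta``, else the first retained item) loads non-negatively
    on contrast 1.
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2:
        raise ParameterError("residuals must be a 2-D persons x items array")
    n, L = R.shape
    if L < 3:
        raise ParameterError(f"need >= 3 items for residual PCA, got {L}")
    df = pd.DataFrame(R)
    var = df.var(ddof=1)
    keep = (var > 1e-12) & (df.notna().sum() >= 2)
    if (~keep).any():
        warnings.warn(
            f"excluding {int((~keep).sum())} item(s) with zero residual variance "
            "from the residual PCA"
        )
    kept = np.where(keep.to_numpy())[0]
    if kept.size < 2:
        raise DegenerateDataError("fewer than 2 items with residual variance")
    corr = df.iloc[:, kept].corr(method="pearson").to_numpy()
    if np.isnan(corr).any():
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    if delta is not None:
        ref = int(np.nanargmax(np.asarray(delta, dtype=float)[kept]))
    else:
        ref = 0
    for p in range(eigvec.shape[1]):
        if eigvec[ref, p] < 0:
            eigvec[:, p] = -eigvec[:, p]
    clusters = _cluster_by_loading(eigvec[:, 0], n_clusters)
    return ResidualContrast(
        item_index=kept,
        loadings=eigvec,
        eigenvalues=eigval,
        clusters=clusters,
        excluded_items=np.where(~keep.to_numpy())[0],
        n_items=int(kept.size),
    )


def variance_decomposition(
    data: ResponseMatrix,
    est: RaschEstimates,
    contrast: Optional[ResidualContrast] = None,
) -> pd.DataFrame:
    """Decompose the observed response variance into parts explained by the
    person measures, by the item measures, and an unexplained remainder,
    attributing the latter to residual contrasts by eigenvalue share.

    Sums of squares are taken over observed, non-extreme cells: the explained
    part is the spread of the modeled probabilities (split via their row/
    column means), the unexplained part is the squared raw residual. All
    fractions sum to 1 by construction.
    """
    X = data.data
    P = success_probability(est.theta[:, None], est.delta[None, :])
    valid = ~np.isnan(X) & ~np.isnan(P)
    x = X[valid]
    p = P[valid]
    xbar = x.mean()
    ss_unexplained = float(((x - p) ** 2).sum())
    ss_model = float(((p - xbar) ** 2).sum())
    total = ss_model + ss_unexplained
    if total == 0:
        raise DegenerateDataError("no variance in responses")

    # split modeled variance into person and item directions via the means of
    # P over observed cells
    Pm = np.where(valid, P, np.nan)
    counts_p = valid.sum(axis=1)
    counts_i = valid.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-extreme rows/cols
        person_means = np.nanmean(Pm, axis=1)
        item_means = np.nanmean(Pm, axis=0)
    ss_persons = float(np.nansum(counts_p * (person_means - xbar) ** 2))
    ss_items = float(np.nansum(counts_i * (item_means - xbar) ** 2))
    scale = ss_model / (ss_persons + ss_items) if ss_persons + ss_items > 0 else 0.0
    ss_persons *= scale
    ss_items *= scale

    rows = [
        ("total", total, 1.0),
        ("explained_by_persons", ss_persons, ss_persons / total),
        ("explained_by_items", ss_items, ss_items / total),
        ("unexplained", ss_unexplained, ss_unexplained / total),
    ]
    if contrast is not None:
        unexp_frac = ss_unexplained / total
        for p_idx, ev in enumerate(contrast.eigenvalues, start=1):
            share = float(ev) / contrast.n_items
            rows.append(
                (
                    f"unexplained_contrast{p_idx}",
                    ss_unexplained * share,
                    unexp_frac * share,
                )
            )
    return pd.DataFrame(rows, columns=["component", "sum_of_squares", "fraction"])


@dataclass(frozen=True)
class DisattenuatedCorrelation:
    value: float
    raw: float
    clipped: bool

    def __float__(self):
        return self.value


def disattenuated_correlation(
    corr: float, reliability_a: float, reliability_b: float
) -> DisattenuatedCorrelation:
    """Correlation corrected for attenuation:
    ``corr / sqrt(R_a * R_b)``, clipped to [-1, 1] with a flag."""
    for name, r in (("reliability_a", reliability_a), ("reliability_b", reliability_b)):
        if not 0.0 < r <= 1.0:
            raise ParameterError(f"{name} must be in (0, 1], got {r}")
    raw = corr / np.sqrt(reliability_a * reliability_b)
    clipped = bool(abs(raw) > 1.0)
    return DisattenuatedCorrelation(
        value=float(np.clip(raw, -1.0, 1.0)), raw=float(raw), clipped=clipped
    )


def person_separation_reliability(measures: np.ndarray, ses: np.ndarray) -> float:
    """Rasch person-separation reliability: (observed variance - mean error
    variance) / observed variance, floored at 0."""
    m = np.asarray(measures, dtype=float)
    s = np.asarray(ses, dtype=float)
    ok = np.isfinite(m) & np.isfinite(s)
    if ok.sum() < 2:
        return 0.0
    var_obs = float(np.var(m[ok], ddof=1))
    if var_obs <= 0:
        return 0.0
    mean_err = float(np.mean(s[ok] ** 2))
    return max(0.0, (var_obs - mean_err) / var_obs)


def cluster_person_measures(
    data: ResponseMatrix,
    items: Sequence[int],
    config: RaschConfig = RaschConfig(),
) -> tuple[np.ndarray, float]:
    """Refit the Rasch model on a cluster of items (0-based indices) and
    return per-person measures with the cluster's person-separation
    reliability. Small clusters legitimately yield poor reliability; that is
    reported, not raised."""
    items = list(items)
    if len(items) < 2:
        raise ParameterError("need at least 2 items for a cluster fit")
    sub = ResponseMatrix(
        data=data.data[:, items],
        person_ids=data.person_ids,
        item_ids=tuple(data.item_ids[j] for j in items),
        groups=data.groups,
    )
    est = fit_rasch(sub, config)
    rel = person_separation_reliability(est.theta, est.theta_se)
    return est.theta, rel


@dataclass(frozen=True)
class LinacreCheck:
    name: str
    value: float
    threshold: Optional[float]
    status: str
    note: str


@dataclass(frozen=True)
class LinacreReport:
    """Structured multidimensionality checklist over a residual PCA."""

    checks: tuple[LinacreCheck, ...]

    @property
    def flagged(self) -> bool:
        return any(c.status == "flag" for c in self.checks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.checks])


def linacre_checklist(
    contrast: ResidualContrast, variance: pd.DataFrame
) -> LinacreReport:
    """Three-point decision checklist on residual-PCA evidence for a
    secondary dimension: variance-ratio size, first-contrast eigenvalue
    against the two-item chance threshold, and cluster separation."""
    v = variance.set_index("component")["fraction"]
    items_frac = float(v.get("explained_by_items", np.nan))
    c1_frac = float(v.get("unexplained_contrast1", np.nan))
    ratio = items_frac / c1_frac if c1_frac and np.isfinite(c1_frac) and c1_frac > 0 else np.inf
    checks = [
        LinacreCheck(
            name="items_vs_first_contrast_variance",
            value=ratio,
            threshold=2.0,
            status="pass" if ratio >= 2.0 else "flag",
            note=(
                f"raw variance explained by items {items_frac:.1%} vs unexplained "
                f"variance in first contrast {c1_frac:.1%}"
                if np.isfinite(c1_frac)
                else "contrast variance unavailable"
            ),
        )
    ]
    ev1 = contrast.first_eigenvalue
    checks.append(
        LinacreCheck(
            name="first_contrast_eigenvalue",
            value=ev1,
            threshold=EIGENVALUE_THRESHOLD,
            status="pass" if ev1 < EIGENVALUE_THRESHOLD else "flag",
            note=f"strength of ~{ev1:.1f} items; >=2 items is unlikely by chance",
        )
    )
    if contrast.n_items < 3:
        checks.append(
            LinacreCheck(
                name="cluster_separation",
                value=np.nan,
                threshold=None,
                status="insufficient",
                note="fewer than 3 items: a secondary dimension cannot be assessed",
            )
        )
    else:
        load1 = contrast.contrast(1)
        spread = float(load1.max() - load1.min())
        n_cl = len(np.unique(contrast.clusters))
        checks.append(
            LinacreCheck(
                name="cluster_separation",
                value=spread,
                threshold=None,
                status="flag" if spread > 1.0 and n_cl >= 2 else "pass",
                note=f"{n_cl} loading clusters, vertical spread {spread:.2f}",
            )
        )
    return LinacreReport(checks=tuple(checks))
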