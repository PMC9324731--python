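"""Classic-test-theory scoring and serial-position curves by region and
group, next to the Rasch-restituted success probabilities."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import warnings

import numpy as np
import pandas as pd

from .entropy_constructs import REGIONS, WordListDesign
from .errors import UndefinedScoreError
from .rasch_core import RaschEstimates, ResponseMatrix, to_psuccess

__all__ = ["SerialPositionSummary", "ctt_proportion", "spe_curves"]


def ctt_proportion(data: ResponseMatrix, j: int) -> float:
    """Classic proportion-correct for item ``j`` (1-based): mean of the
    column over non-missing responses."""
    if not 1 <= j <= data.n_items:
        raise IndexError(f"item {j} outside 1..{data.n_items}")
    col = data.data[:, j - 1]
    valid = ~np.isnan(col)
    if valid.sum() == 0:
        raise UndefinedScoreError(f"item {j} has no observed responses")
    return float(col[valid].mean())


@dataclass(frozen=True)
class SerialPositionSummary:
    """Per group x region summary: CTT proportion next to the Rasch route
    (group mean ability vs mean region difficulty, back-converted with an
    asymmetric k=2 interval). CTT carries no interval by design."""

    table: pd.DataFrame
    k: float
    aggregation: str

    def row(self, group: str, region: str) -> pd.Series:
        t = self.table
        hit = t[(t["group"] == group) & (t["region"] == region)]
        if hit.empty:
            raise KeyError(f"no summary row for group={group!r}, region={region!r}")
        return hit.iloc[0]


def _group_theta_uncertainty(theta: np.ndarray, theta_se: np.ndarray) -> float:
    """Standard uncertainty of the group mean ability: SEM of the measures
    combined in quadrature with the mean individual measurement SE."""
    n = theta.size
    sem = float(np.std(theta, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    mean_se = float(np.mean(theta_se))
    return float(np.hypot(sem, mean_se))


def spe_curves(
    data: ResponseMatrix,
    est: RaschEstimates,
    design: WordListDesign,
    grouping: Optional[np.ndarray] = None,
    k: float = 2.0,
    per_item: bool = False,
) -> SerialPositionSummary:
    """Serial-position summary per clinical group and region.

    The CTT route averages raw proportions over the region's items. The Rasch
    route converts the group mean ability against the mean region difficulty
    (default), or averages per-item conversions when ``per_item`` is set.
    """
    if grouping is None:
        grouping = np.asarray(data.groups) if data.groups is not None else np.array(["all"] * data.n_persons)
    grouping = np.asarray(grouping)
    if grouping.size != data.n_persons:
        raise ValueError("grouping must label every person")

    rows = []
    for group in pd.unique(grouping):
        sel = grouping == group
        members = np.where(sel & ~est.extreme_persons)[0]
        if sel.sum() == 0:
            warnings.warn(f"group {group!r} is empty; skipped")
            continue
        theta_g = est.theta[members]
        theta_se_g = est.theta_se[members]
        theta_bar = float(np.mean(theta_g)) if members.size else np.nan
        U_theta = _group_theta_uncertainty(theta_g, theta_se_g) if members.size else np.nan
        for region in REGIONS:
            items = design.region_items(region)
            cols = [j - 1 for j in items]
            sub = data.data[np.ix_(sel, cols)]
            valid = ~np.isnan(sub)
            ctt = float(sub[valid].mean()) if valid.any() else np.nan
            delta_r = est.delta[cols]
            delta_bar = float(np.nanmean(delta_r))
            if members.size == 0:
                central = low = high = np.nan
            elif per_item:
                ivals = [to_psuccess(theta_bar, d, U_theta, k=k) for d in delta_r if np.isfinite(d)]
                central = float(np.mean([v.central for v in ivals]))
                low = float(np.mean([v.low for v in ivals]))
                high = float(np.mean([v.high for v in ivals]))
            else:
                iv = to_psuccess(theta_bar, delta_bar, U_theta, k=k)
                central, low, high = iv.central, iv.low, iv.high
            rows.append(
                {
                    "group": group,
                    "region": region,
                    "n": int(sel.sum()),
                    "ctt_proportion": ctt,
                    "rasch_p": central,
                    "rasch_low": low,
                    "rasch_high": high,
                    "theta_mean": theta_bar,
                    "theta_U": U_theta,
                    "delta_mean": delta_bar,
                }
            )
    return SerialPositionSummary(
        table=pd.DataFrame(rows),
        k=k,
        aggregation="per_item" if per_item else "mean_measure",
    )
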