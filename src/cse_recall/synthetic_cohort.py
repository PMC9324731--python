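"""Simulated recall cohorts: Rasch-generated binary response matrices with
group-specific ability distributions and region-wise difficulty shifts.

Every downstream module is testable against these fixtures: the generative
model is exactly the dichotomous Rasch model, with each group's effective
item difficulty equal to the base difficulty plus an overall group shift plus
a per-region shift (the mechanism assumed by the loading-shift theory).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .entropy_constructs import REGIONS, WordListDesign, default_regions
from .errors import ParameterError
from .rasch_core import ResponseMatrix, success_probability

__all__ = ["GroupSpec", "CohortSpec", "TrueParameters", "simulate_cohort", "neuromet_like_preset"]


@dataclass(frozen=True)
class GroupSpec:
    """One clinical group: size, ability distribution, difficulty modifiers."""

    label: str
    n: int
    theta_mean: float
    theta_sd: float = 1.0
    overall_shift: float = 0.0
    region_shifts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 1:
            raise ParameterError(f"group {self.label!r}: n must be >= 1, got {self.n}")
        if self.theta_sd <= 0:
            raise ParameterError(
                f"group {self.label!r}: theta_sd must be > 0, got {self.theta_sd}"
            )
        bad = set(self.region_shifts) - set(REGIONS)
        if bad:
            raise ParameterError(f"group {self.label!r}: unknown regions {sorted(bad)}")


@dataclass(frozen=True)
class CohortSpec:
    """Full simulation recipe; identical spec + seed reproduce the matrix
    bitwise."""

    groups: tuple[GroupSpec, ...]
    base_difficulties: np.ndarray
    regions: tuple[str, ...]
    seed: int = 0

    def __post_init__(self):
        base = np.asarray(self.base_difficulties, dtype=float)
        object.__setattr__(self, "base_difficulties", base)
        if base.ndim != 1 or base.size < 2:
            raise ParameterError("base_difficulties must be a 1-D vector of length >= 2")
        if len(self.regions) != base.size:
            raise ParameterError("regions must tag every item")
        if not self.groups:
            raise ParameterError("need at least one group")

    @property
    def L(self) -> int:
        return self.base_difficulties.size

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)

    def effective_difficulties(self, group: GroupSpec) -> np.ndarray:
        """Base difficulty + overall group shift + that group's region shift."""
        d = self.base_difficulties + group.overall_shift
        for region, shift in group.region_shifts.items():
            mask = np.array([r == region for r in self.regions])
            d = d + np.where(mask, shift, 0.0)
        return d

    @classmethod
    def from_design(
        cls,
        groups: Sequence[GroupSpec],
        design: WordListDesign,
        base_difficulties: Optional[Sequence[float]] = None,
        seed: int = 0,
    ) -> "CohortSpec":
        from .entropy_constructs import theoretical_difficulty

        if base_difficulties is None:
            base = np.array([theoretical_difficulty(j, design) for j in range(1, design.L + 1)])
            base = base - base.mean()
        else:
            base = np.asarray(base_difficulties, dtype=float)
        return cls(
            groups=tuple(groups),
            base_difficulties=base,
            regions=tuple(design.region_tags),
            seed=seed,
        )


@dataclass(frozen=True)
class TrueParameters:
    """Generative ground truth kept alongside a simulated matrix."""

    theta: np.ndarray
    effective_delta: dict[str, np.ndarray]
    base_delta: np.ndarray
    groups: np.ndarray


def simulate_cohort(spec: CohortSpec) -> tuple[ResponseMatrix, TrueParameters]:
    """Draw a binary response matrix from the Rasch model under ``spec``.

    Abilities are drawn per group from Normal(theta_mean, theta_sd); each
    response is Bernoulli with probability logistic(theta_i - delta_eff_j).
    """
    rng = np.random.default_rng(spec.seed)
    thetas = []
    labels = []
    rows = []
    eff = {}
    for g in spec.groups:
        d_eff = spec.effective_difficulties(g)
        eff[g.label] = d_eff
        th = rng.normal(g.theta_mean, g.theta_sd, size=g.n)
        P = success_probability(th[:, None], d_eff[None, :])
        rows.append((rng.random((g.n, spec.L)) < P).astype(float))
        thetas.append(th)
        labels.extend([g.label] * g.n)
    data = np.vstack(rows)
    theta = np.concatenate(thetas)
    matrix = ResponseMatrix(
        data=data,
        person_ids=tuple(f"{lab}_{i+1}" for i, lab in enumerate(labels)),
        item_ids=tuple(f"I{j+1}" for j in range(spec.L)),
        groups=tuple(labels),
    )
    truth = TrueParameters(
        theta=theta,
        effective_delta=eff,
        base_delta=spec.base_difficulties.copy(),
        groups=np.array(labels),
    )
    return matrix, truth


# Invented group-mean offsets (ordered healthy > impaired); they average to
# zero with the group sizes below so the cohort mean ability is exactly the
# configured overall mean.
_PRESET_GROUPS = (
    ("HC", 66, +0.50),
    ("SCD", 99, +0.05),
    ("MCI", 27, -0.55),
    ("AD", 33, -0.70),
)


def neuromet_like_preset(
    impaired_primacy_penalty: float = 0.0,
    overall_mean: float = -0.6,
    sd: float = 1.0,
    seed: int = 0,
    base_difficulties: Optional[Sequence[float]] = None,
) -> CohortSpec:
    """Four-group, 225-person cohort spec shaped like the reference study
    (66 healthy controls, 99 subjective decline, 27 mild impairment, 33
    dementia; overall mean ability -0.6, sd 1.0).

    Group-mean offsets around the overall mean are invented, documented
    defaults (not estimated from any cohort). ``impaired_primacy_penalty``
    adds that many logits to primacy-region item difficulty for the MCI and
    AD groups, removing their primacy benefit.
    """
    if base_difficulties is None:
        from .io_cli import load_table1_fixture

        base_difficulties = load_table1_fixture().delta
    base = np.asarray(base_difficulties, dtype=float)
    regions = tuple(default_regions(base.size))
    groups = []
    for label, n, offset in _PRESET_GROUPS:
        shifts = {}
        if label in ("MCI", "AD") and impaired_primacy_penalty != 0.0:
            shifts["Pr"] = float(impaired_primacy_penalty)
        groups.append(
            GroupSpec(
                label=label,
                n=n,
                theta_mean=overall_mean + offset,
                theta_sd=sd,
                region_shifts=shifts,
            )
        )
    return CohortSpec(
        groups=tuple(groups), base_difficulties=base, regions=regions, seed=seed
    )
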