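"""Combinatorial-entropy explanatory variables for serial word-list recall.

Task difficulty of recalling item ``j`` from an ordered list of ``L`` words is
decomposed into additive information terms on the logit scale, all carrying the
common scale constant ``M = 1/ln(L)``:

* primacy:    ``-M * ln(j!)`` — zero for the first word, decreasing with order;
* mid-range:  ``+M * ln(floor(L/2)!)`` — a constant, entering the total twice;
* recency:    ``-M * ln((L-1-j)!)`` with the factorial argument clipped at 0 —
  zero for the final words;
* frequency:  ``-M * ln(p_rel)`` for a relative corpus frequency ``p_rel``,
  or a tabulated per-item value passed through unchanged.

The per-item total is ``delta_j = primacy + 2*midrange + recency + frequency``.

Factorials are evaluated through ``lgamma`` so large ``L`` cannot overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidDesignError, InvalidFrequencyError, ItemIndexError

__all__ = [
    "ItemRecord",
    "WordListDesign",
    "ExplanatoryMatrix",
    "scale_constant",
    "primacy_difficulty",
    "recency_difficulty",
    "midrange_difficulty",
    "frequency_difficulty",
    "theoretical_difficulty",
    "explanatory_matrix",
    "default_regions",
]

REGIONS = ("Pr", "Mr", "Rr")


def default_regions(L: int) -> list[str]:
    """Region tags for an ``L``-word list: first/last four words are the
    primacy/recency regions when the list is long enough (the convention for
    the canonical 15-word list), shrinking proportionally for short lists."""
    if L < 3:
        raise InvalidDesignError(f"need at least 3 items to define regions, got L={L}")
    edge = 4 if L >= 12 else max(1, L // 4)
    tags = ["Mr"] * L
    for j in range(edge):
        tags[j] = "Pr"
        tags[L - 1 - j] = "Rr"
    return tags


@dataclass(frozen=True)
class ItemRecord:
    """One word of the list.

    ``rel_freq`` is a relative corpus frequency in (0, 1]; ``freq_logit`` is a
    pre-tabulated frequency difficulty in logits (takes precedence when set).
    """

    order: int
    word: str = ""
    rel_freq: Optional[float] = None
    freq_logit: Optional[float] = None
    region: Optional[str] = None


@dataclass(frozen=True)
class WordListDesign:
    """Ordered word list with region partition and per-item frequencies."""

    items: tuple[ItemRecord, ...]

    def __post_init__(self):
        L = len(self.items)
        if L < 3:
            raise InvalidDesignError(f"list length must be >= 3, got {L}")
        orders = [it.order for it in self.items]
        if orders != list(range(1, L + 1)):
            raise InvalidDesignError(
                f"item orders must be exactly 1..{L} in sequence, got {orders}"
            )
        regions = [it.region for it in self.items]
        if any(r is None for r in regions):
            filled = default_regions(L)
            object.__setattr__(
                self,
                "items",
                tuple(
                    ItemRecord(it.order, it.word, it.rel_freq, it.freq_logit, tag)
                    for it, tag in zip(self.items, filled)
                ),
            )
        else:
            bad = sorted({r for r in regions if r not in REGIONS})
            if bad:
                raise InvalidDesignError(f"unknown region tags {bad}; expected {REGIONS}")
        for it in self.items:
            if it.rel_freq is not None and not (0.0 < it.rel_freq <= 1.0):
                raise InvalidFrequencyError(
                    f"item {it.order}: rel_freq must be in (0, 1], got {it.rel_freq}"
                )

    @property
    def L(self) -> int:
        return len(self.items)

    @property
    def region_tags(self) -> list[str]:
        return [it.region for it in self.items]

    def region_items(self, region: str) -> list[int]:
        """1-based order indices belonging to ``region``."""
        if region not in REGIONS:
            raise InvalidDesignError(f"unknown region {region!r}")
        return [it.order for it in self.items if it.region == region]

    @classmethod
    def from_lengths(
        cls,
        L: int,
        rel_freqs: Optional[Sequence[float]] = None,
        freq_logits: Optional[Sequence[float]] = None,
        words: Optional[Sequence[str]] = None,
        regions: Optional[Sequence[str]] = None,
    ) -> "WordListDesign":
        items = []
        for j in range(1, L + 1):
            items.append(
                ItemRecord(
                    order=j,
                    word=words[j - 1] if words is not None else f"item{j}",
                    rel_freq=rel_freqs[j - 1] if rel_freqs is not None else None,
                    freq_logit=freq_logits[j - 1] if freq_logits is not None else None,
                    region=regions[j - 1] if regions is not None else None,
                )
            )
        return cls(items=tuple(items))


def scale_constant(L: float) -> float:
    """Entropy scale constant ``M = 1/ln(L)``; dimensionless.

    ``L`` may be any real > some lower bound for testing closed forms, but a
    physical list needs an integer length of at least 2.
    """
    if L < 2 and not math.isclose(L, math.e):
        # L = e is admitted purely so that M = 1 is exercisable in tests.
        raise InvalidDesignError(f"list length must be >= 2, got {L}")
    return 1.0 / math.log(L)


def _check_index(j: int, L: int) -> None:
    if not 1 <= j <= L:
        raise ItemIndexError(f"item order {j} outside 1..{L}")


def primacy_difficulty(j: int, L: int) -> float:
    """Primacy term ``-ln(j!)/ln(L)``: 0 at the first word, strictly
    decreasing with list position."""
    _check_index(j, L)
    return -math.lgamma(j + 1) / math.log(L)


def recency_difficulty(j: int, L: int) -> float:
    """Recency term ``-ln((L-1-j)!)/ln(L)`` with the factorial argument
    clipped at zero, so the last words of the list contribute 0."""
    _check_index(j, L)
    n = max(L - 1 - j, 0)
    return -math.lgamma(n + 1) / math.log(L)


def midrange_difficulty(L: int) -> float:
    """Single mid-range term ``M * ln(floor(L/2)!)``.

    The total difficulty counts this term twice; the doubled value is what a
    per-item explanatory table shows in its constant middle column.
    """
    if L < 3:
        raise InvalidDesignError(f"list length must be >= 3, got {L}")
    return math.lgamma(L // 2 + 1) / math.log(L)


def frequency_difficulty(p_rel: float, L: int) -> float:
    """Frequency term ``-ln(p_rel)/ln(L)`` >= 0 for ``p_rel`` in (0, 1].

    This closed form is a modelling convenience: published explanatory tables
    list the frequency variable directly in logits, and those tabulated values
    should be passed through unchanged when available (see
    :func:`explanatory_matrix`).
    """
    if not 0.0 < p_rel <= 1.0:
        raise InvalidFrequencyError(f"relative frequency must be in (0, 1], got {p_rel}")
    return -math.log(p_rel) / math.log(L)


def _item_frequency(item: ItemRecord, L: int) -> float:
    if item.freq_logit is not None:
        return float(item.freq_logit)
    if item.rel_freq is not None:
        return frequency_difficulty(item.rel_freq, L)
    return 0.0


def theoretical_difficulty(j: int, design: WordListDesign) -> float:
    """Four-term additive difficulty
    ``primacy + 2*midrange + recency + frequency`` for item ``j``."""
    L = design.L
    _check_index(j, L)
    item = design.items[j - 1]
    return (
        primacy_difficulty(j, L)
        + 2.0 * midrange_difficulty(L)
        + recency_difficulty(j, L)
        + _item_frequency(item, L)
    )


@dataclass(frozen=True)
class ExplanatoryMatrix:
    """Per-item explanatory variables (logits) plus the scale constant M.

    ``midrange`` holds the doubled constant term as it enters the additive
    total, matching the layout of published explanatory tables.
    """

    item: np.ndarray
    primacy: np.ndarray
    midrange: np.ndarray
    recency: np.ndarray
    frequency: np.ndarray
    M: float
    region: tuple[str, ...] = field(default=())

    VARIABLES = ("primacy", "recency", "frequency")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "item": self.item,
                "primacy": self.primacy,
                "midrange": self.midrange,
                "recency": self.recency,
                "frequency": self.frequency,
            }
        )
        if self.region:
            df["region"] = list(self.region)
        return df

    def variable_matrix(self) -> np.ndarray:
        """Items x (primacy, recency, frequency) — the non-constant columns."""
        return np.column_stack([self.primacy, self.recency, self.frequency])

    @property
    def total(self) -> np.ndarray:
        """Theoretical per-item difficulty: sum of the four columns."""
        return self.primacy + self.midrange + self.recency + self.frequency


def explanatory_matrix(design: WordListDesign) -> ExplanatoryMatrix:
    """Tabulate the four explanatory variables for every item of ``design``.

    Pure function: the same design always yields the same table. Tabulated
    frequency logits, when present on the items, are passed through verbatim.
    """
    L = design.L
    js = np.arange(1, L + 1)
    mid2 = 2.0 * midrange_difficulty(L)
    return ExplanatoryMatrix(
        item=js,
        primacy=np.array([primacy_difficulty(j, L) for j in js]),
        midrange=np.full(L, mid2),
        recency=np.array([recency_difficulty(j, L) for j in js]),
        frequency=np.array([_item_frequency(it, L) for it in design.items]),
        M=scale_constant(L),
        region=tuple(design.region_tags),
    )
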