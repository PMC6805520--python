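"""Rank-sum-ratio grading of weighted indicators.

Indicators are ranked ascending by weight; mean ranks are converted to
cumulative percentages, the top entry's percentage is replaced by
``(1 - 1/(4m)) * 100`` so it stays below 100, and the percentages are
mapped to probit values ``Phi^-1(P/100) + 5``.  Grades are assigned
from half-open probit intervals.

Two probit modes are offered.  ``exact`` transforms the cumulative
percentage as-is.  ``legacy_percent_table`` first truncates it to a
whole percent, reproducing results computed from classical printed
probit lookup tables.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import ComputationError, ConfigurationError, ValidationError
from .weights import WeightVector

PROBIT_OFFSET = 5.0
MODES = ("exact", "legacy_percent_table")


@dataclasses.dataclass(frozen=True)
class GradeScheme:
    """Half-open probit intervals; grade g covers [t_{g-1}, t_g)."""

    thresholds: tuple[float, ...] = (4.0, 6.0)

    def __post_init__(self) -> None:
        thresholds = tuple(float(t) for t in self.thresholds)
        if len(thresholds) < 1 or any(
            a >= b for a, b in zip(thresholds, thresholds[1:])
        ):
            raise ValidationError("grade thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", thresholds)

    @property
    def n_grades(self) -> int:
        return len(self.thresholds) + 1

    def grade(self, y: float) -> int:
        return int(np.searchsorted(self.thresholds, y, side="right")) + 1


@dataclasses.dataclass(frozen=True)
class RsrTable:
    """Per-indicator rank bookkeeping, ascending by the ranking statistic.

    Columns: ``indicator, rsr, f, f_cum, rank, mean_rank, p, p_used, y``
    and, once grades are assigned, ``grade``.
    """

    frame: pd.DataFrame
    mode: str

    def row(self, indicator: str) -> pd.Series:
        match = self.frame[self.frame["indicator"] == indicator]
        if match.empty:
            raise KeyError(indicator)
        return match.iloc[0]

    def grade_partition(self) -> dict[int, tuple[str, ...]]:
        if "grade" not in self.frame.columns:
            raise ConfigurationError("grades not yet assigned")
        out: dict[int, tuple[str, ...]] = {}
        for g, group in self.frame.groupby("grade"):
            out[int(g)] = tuple(group["indicator"])
        return out

    def to_markdown(self) -> str:
        frame = self.frame.copy()
        frame["rsr"] = frame["rsr"].map(lambda v: f"{v:.4f}")
        frame["p"] = frame["p"].map(lambda v: f"{v:.2f}%")
        frame["p_used"] = frame["p_used"].map(lambda v: f"{v:.2f}%")
        frame["y"] = frame["y"].map(lambda v: f"{v:.4f}")
        return frame.to_markdown(index=False)


def build_rsr_table(w: WeightVector, *, mode: str = "exact") -> RsrTable:
    """Rank indicators by weight and compute percentages and probits.

    Ties receive their average rank; the entry (or entries) holding the
    maximum mean rank m would map to P = 100%, so its percentage is
    replaced by ``(1 - 1/(4m)) * 100``.
    """
    if mode not in MODES:
        raise ConfigurationError(f"probit mode must be one of {MODES}")
    m = len(w)
    if m < 2:
        raise ValidationError("ranking needs at least two indicators")
    values = w.values
    order = np.lexsort((np.asarray(w.labels), values))
    sorted_vals = values[order]
    sorted_labels = [w.labels[i] for i in order]
    # average ranks over ties of the ascending sequence
    from scipy.stats import rankdata

    mean_rank = rankdata(sorted_vals, method="average")
    rank = np.arange(1, m + 1)
    uniq, counts = np.unique(sorted_vals, return_counts=True)
    f = counts[np.searchsorted(uniq, sorted_vals)]
    f_cum = np.searchsorted(sorted_vals, sorted_vals, side="right")
    p = mean_rank / m * 100.0
    p_used = np.where(mean_rank >= m, (1.0 - 1.0 / (4 * m)) * 100.0, p)
    p_eval = np.floor(p_used) if mode == "legacy_percent_table" else p_used
    if np.any(p_eval <= 0) or np.any(p_eval >= 100):
        raise ComputationError("cumulative percentage outside (0, 100) after adjustment")
    y = ndtri(p_eval / 100.0) + PROBIT_OFFSET
    frame = pd.DataFrame(
        {
            "indicator": sorted_labels,
            "rsr": sorted_vals,
            "f": f.astype(int),
            "f_cum": f_cum.astype(int),
            "rank": rank,
            "mean_rank": mean_rank,
            "p": p,
            "p_used": p_used,
            "y": y,
        }
    )
    return RsrTable(frame, mode)


def assign_grades(table: RsrTable, scheme: GradeScheme | None = None) -> RsrTable:
    """Attach a grade column from the probit intervals of *scheme*."""
    scheme = scheme or GradeScheme()
    frame = table.frame.copy()
    frame["grade"] = [scheme.grade(y) for y in frame["y"]]
    return RsrTable(frame, table.mode)


def grade_weights(
    w: WeightVector, *, mode: str = "exact", scheme: GradeScheme | None = None
) -> RsrTable:
    """Convenience chain: build the table and assign grades."""
    return assign_grades(build_rsr_table(w, mode=mode), scheme)
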