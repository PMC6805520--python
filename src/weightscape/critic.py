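"""Objective indicator weighting from respondent score data (CRITIC).

The method extracts two sources of information from a respondents-by-
indicators score table: the *contrast intensity* of each indicator (the
standard deviation of its min-max-normalized scores) and its *conflict*
with the other indicators (one minus the pairwise linear correlation).
Their product is the indicator's information content, normalized to
unity to give the objective weights.
"""
from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateDataError, ValidationError
from .weights import WeightVector


@dataclasses.dataclass(frozen=True)
class ScoreMatrix:
    """Respondents-by-indicators table of scores on the 0-10 scale."""

    indicator_labels: tuple[str, ...]
    respondent_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(str(lab) for lab in self.indicator_labels)
        ids = tuple(str(r) for r in self.respondent_ids)
        values = np.asarray(self.values, dtype=float).copy()
        if values.ndim != 2:
            raise ValidationError("score matrix must be two-dimensional")
        if values.shape != (len(ids), len(labels)):
            raise ValidationError("score matrix shape does not match labels/ids")
        if np.isnan(values).any():
            raise ValidationError(
                "score matrix contains missing cells; filter incomplete "
                "responses upstream (see survey filtering)"
            )
        if np.any(values < -1e-9) or np.any(values > 10 + 1e-9):
            raise ValidationError("scores must lie in [0, 10]")
        values.setflags(write=False)
        object.__setattr__(self, "indicator_labels", labels)
        object.__setattr__(self, "respondent_ids", ids)
        object.__setattr__(self, "values", values)

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "ScoreMatrix":
        return cls(
            tuple(str(c) for c in frame.columns),
            tuple(str(i) for i in frame.index),
            frame.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.respondent_ids), columns=list(self.indicator_labels)
        )


@dataclasses.dataclass(frozen=True)
class NormalizedScoreMatrix:
    """Min-max-normalized scores with per-indicator ideal/anti-ideal."""

    indicator_labels: tuple[str, ...]
    respondent_ids: tuple[str, ...]
    values: np.ndarray
    ideal: np.ndarray
    anti_ideal: np.ndarray
    constant_columns: np.ndarray  # boolean mask


@dataclasses.dataclass(frozen=True)
class CriticDiagnostics:
    """Per-indicator contrast, pairwise conflict, information and weights."""

    labels: tuple[str, ...]
    sigma: np.ndarray
    conflict: np.ndarray
    info: np.ndarray | None = None
    weights: WeightVector | None = None


def normalize_scores(
    scores: ScoreMatrix, *, directions: Sequence[str] | None = None
) -> NormalizedScoreMatrix:
    """Min-max normalize each indicator column onto [0, 1].

    ``x = (f - anti_ideal) / (ideal - anti_ideal)`` with the ideal being
    the column maximum for benefit-type indicators (the default) and the
    column minimum for cost-type ones.  Constant columns map to zeros
    and are flagged.
    """
    if scores.n_respondents < 2:
        raise ValidationError("normalization needs at least two respondents")
    x = scores.values
    m = scores.n_indicators
    if directions is None:
        directions = ["benefit"] * m
    if len(directions) != m:
        raise ValidationError("one direction per indicator required")
    col_min = x.min(axis=0)
    col_max = x.max(axis=0)
    ideal = np.where([d == "cost" for d in directions], col_min, col_max)
    anti = np.where([d == "cost" for d in directions], col_max, col_min)
    span = ideal - anti
    constant = span == 0
    if constant.any():
        bad = [scores.indicator_labels[j] for j in np.flatnonzero(constant)]
        warnings.warn(f"constant indicator column(s) {bad}: zero contrast", stacklevel=2)
    safe_span = np.where(constant, 1.0, span)
    norm = (x - anti) / safe_span
    norm[:, constant] = 0.0
    return NormalizedScoreMatrix(
        scores.indicator_labels,
        scores.respondent_ids,
        norm,
        np.asarray(ideal, dtype=float),
        np.asarray(anti, dtype=float),
        constant,
    )


def contrast_and_conflict(
    norm: NormalizedScoreMatrix, *, std_mode: str = "sample", method: str = "pearson"
) -> CriticDiagnostics:
    """Compute per-indicator standard deviations and the conflict matrix.

    Element-wise identical column pairs get correlation 0 by convention
    (no usable conflict information), as does any pair involving a
    constant column where the coefficient is undefined.
    """
    x = norm.values
    if x.shape[1] < 2:
        raise ValidationError("weighting needs at least two indicators")
    if std_mode not in ("sample", "population"):
        raise ConfigurationError(f"unknown std_mode {std_mode!r}")
    ddof = 1 if std_mode == "sample" else 0
    sigma = x.std(axis=0, ddof=ddof)
    m = x.shape[1]
    if method == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x, rowvar=False)
    elif method == "spearman":
        r = stats.spearmanr(x).statistic
        r = np.atleast_2d(r)
    else:
        raise ConfigurationError(f"unknown correlation method {method!r}")
    r = np.asarray(r, dtype=float)
    r[np.isnan(r)] = 0.0
    for j in range(m):
        for k in range(j + 1, m):
            if np.array_equal(x[:, j], x[:, k]):
                r[j, k] = r[k, j] = 0.0
    np.fill_diagonal(r, 1.0)
    return CriticDiagnostics(norm.indicator_labels, np.asarray(sigma, float), r)


def information_content(diag: CriticDiagnostics) -> CriticDiagnostics:
    """Fill in ``C_j = sigma_j * sum_k (1 - r_jk)``."""
    info = diag.sigma * (1.0 - diag.conflict).sum(axis=1)
    info = np.clip(info, 0.0, None)
    return dataclasses.replace(diag, info=info)


def critic_weights(diag: CriticDiagnostics) -> WeightVector:
    """Normalize information content to unity."""
    if diag.info is None:
        raise ConfigurationError("information content not yet computed")
    total = float(diag.info.sum())
    if total <= 0:
        raise DegenerateDataError(
            "all indicators carry zero information (constant or perfectly "
            "correlated columns); cannot derive weights"
        )
    return WeightVector(diag.labels, diag.info / total)


def critic(
    scores: ScoreMatrix,
    *,
    std_mode: str = "sample",
    method: str = "pearson",
    directions: Sequence[str] | None = None,
) -> CriticDiagnostics:
    """Run the full chain; returns diagnostics with weights filled in."""
    norm = normalize_scores(scores, directions=directions)
    diag = contrast_and_conflict(norm, std_mode=std_mode, method=method)
    diag = information_content(diag)
    return dataclasses.replace(diag, weights=critic_weights(diag))
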