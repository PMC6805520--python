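"""Readers and writers for the plain-text interchange formats.

Matrix CSVs carry a header row and a label column; cells may be decimals
or exact fractions such as ``1/3`` (parsed as rationals before float
conversion, so reciprocity survives the round trip).
"""
from __future__ import annotations

import csv
import json
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .weights import WeightVector


def parse_cell(text: str) -> float:
    """Parse a numeric cell, accepting fractions like ``1/3`` exactly."""
    text = text.strip()
    if not text:
        raise ValidationError("empty numeric cell")
    try:
        return float(Fraction(text))
    except (ValueError, ZeroDivisionError) as exc:
        raise ValidationError(f"cannot parse numeric cell {text!r}") from exc


def read_matrix_csv(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    """Read a labelled square matrix; returns ``(labels, values)``."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [row for row in csv.reader(fh) if any(cell.strip() for cell in row)]
    if len(rows) < 2:
        raise ValidationError(f"{path}: matrix file needs a header and data rows")
    header = [cell.strip() for cell in rows[0][1:]]
    labels: list[str] = []
    data: list[list[float]] = []
    for row in rows[1:]:
        labels.append(row[0].strip())
        data.append([parse_cell(cell) for cell in row[1 : len(header) + 1]])
    if labels != header:
        raise ValidationError(
            f"{path}: row labels {labels} do not match column labels {header}"
        )
    values = np.asarray(data, dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValidationError(f"{path}: matrix is not square")
    return tuple(labels), values


def write_matrix_csv(path: str | Path, labels: tuple[str, ...], values: np.ndarray) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + list(labels))
        for lab, row in zip(labels, np.asarray(values)):
            writer.writerow([lab] + [repr(float(v)) for v in row])


def read_weights_json(path: str | Path, key: str = "weights") -> WeightVector:
    """Read a weight vector from ``{"labels": [...], "<key>": [...]}`` JSON."""
    payload = json.loads(Path(path).read_text())
    if "labels" not in payload or key not in payload:
        raise ValidationError(f"{path}: expected 'labels' and {key!r} entries")
    return WeightVector.normalized(payload["labels"], payload[key])


def write_weights_json(path: str | Path, vector: WeightVector, key: str = "weights",
                       extra: dict | None = None) -> None:
    payload: dict = {"labels": list(vector.labels), key: [float(v) for v in vector.values]}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_scores_csv(path: str | Path):
    """Read a respondents-by-indicators score table.

    First column is the respondent id; remaining columns are indicators.
    Returns a :class:`~weightscape.critic.ScoreMatrix`.
    """
    from .critic import ScoreMatrix  # local import to avoid a cycle

    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValidationError(f"{path}: score table needs an id column and indicators")
    frame = frame.set_index(frame.columns[0])
    return ScoreMatrix.from_dataframe(frame)


def write_scores_csv(path: str | Path, scores) -> None:
    scores.to_dataframe().to_csv(path, index_label="respondent_id")
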