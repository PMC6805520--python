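"""Simplex-constrained weight vectors shared across all stages."""
from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping

import numpy as np

from .errors import ValidationError

#: tolerance for accepting a vector as lying on the unit simplex
SIMPLEX_ATOL = 1e-6


@dataclasses.dataclass(frozen=True)
class WeightVector:
    """Nonnegative weights over labelled items, summing to one.

    Parameters
    ----------
    labels
        Ordered item names; must be unique.
    values
        Nonnegative weights summing to 1 within ``SIMPLEX_ATOL``.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(str(lab) for lab in self.labels)
        values = np.asarray(self.values, dtype=float).copy()
        if values.ndim != 1 or len(labels) != values.size:
            raise ValidationError(
                "labels and values must be one-dimensional and the same length"
            )
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate labels in weight vector")
        if np.any(values < -1e-12):
            j = int(np.argmin(values))
            raise ValidationError(
                f"negative weight component {labels[j]}={values[j]:.3g}"
            )
        total = float(values.sum())
        if abs(total - 1.0) > SIMPLEX_ATOL:
            raise ValidationError(
                f"weights sum to {total:.8f}, expected 1 within {SIMPLEX_ATOL:g}"
            )
        values[values < 0] = 0.0
        values.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @classmethod
    def normalized(
        cls, labels: Iterable[str], values: Iterable[float], *, atol: float = 1e-3
    ) -> "WeightVector":
        """Build a vector, renormalizing a sum that is off by at most *atol*.

        Printed weight tables are rounded (typically to 4 dp), so vectors
        transcribed from them rarely sum to exactly one; this constructor
        accepts them while still rejecting genuinely broken input.
        """
        arr = np.asarray(list(values), dtype=float)
        if np.any(arr < -1e-12):
            raise ValidationError("negative weight component")
        total = float(arr.sum())
        if abs(total - 1.0) > atol:
            raise ValidationError(
                f"weights sum to {total:.6f}; off the simplex beyond {atol:g}"
            )
        return cls(tuple(labels), np.clip(arr, 0.0, None) / np.clip(arr, 0.0, None).sum())

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float], *, atol: float = 1e-3) -> "WeightVector":
        return cls.normalized(mapping.keys(), mapping.values(), atol=atol)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> float:
        try:
            return float(self.values[self.labels.index(label)])
        except ValueError:
            raise KeyError(label) from None

    def to_dict(self) -> dict[str, float]:
        return {lab: float(v) for lab, v in zip(self.labels, self.values)}

    def permuted(self, labels: Iterable[str]) -> "WeightVector":
        """Return the same weights reordered to *labels*."""
        labels = tuple(labels)
        if set(labels) != set(self.labels) or len(labels) != len(self.labels):
            raise ValidationError("permutation labels do not match vector labels")
        idx = [self.labels.index(lab) for lab in labels]
        return WeightVector(labels, self.values[idx])
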