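"""Subjective priority weighting from pairwise-comparison judgments.

Implements the network-process chain used throughout the toolkit:

* principal-eigenvector priorities of reciprocal comparison matrices,
* consistency index / consistency ratio checking against the standard
  random-index table,
* criterion re-weighting through a column-stochastic dependency matrix,
* global sub-criterion weights from a two-level hierarchy, and
* supermatrix application (single multiplication by default, with an
  optional limit-power mode).
"""
from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping

import numpy as np

from .errors import ComputationError, ConfigurationError, ValidationError
from .weights import WeightVector

#: Saaty's mean random consistency index by matrix order.
RANDOM_INDEX: dict[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
    10: 1.49,
    11: 1.51,
}

#: comparison matrices with a consistency ratio below this are acceptable
CR_THRESHOLD = 0.1


@dataclasses.dataclass(frozen=True)
class ComparisonMatrix:
    """Square positive reciprocal matrix of pairwise judgments.

    Entries follow the 1-9 intensity scale with reciprocals encoding the
    inverse comparison; the diagonal is one.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(str(lab) for lab in self.labels)
        values = np.asarray(self.values, dtype=float).copy()
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValidationError("comparison matrix must be square")
        if values.shape[0] < 2:
            raise ValidationError("comparison matrix needs at least two items")
        if len(labels) != values.shape[0]:
            raise ValidationError("label count does not match matrix order")
        values.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_csv(cls, path) -> "ComparisonMatrix":
        from .io import read_matrix_csv

        labels, values = read_matrix_csv(path)
        return validate_comparison_matrix(cls(labels, values))


@dataclasses.dataclass(frozen=True)
class PriorityResult:
    """Priority vector together with the principal eigenvalue."""

    weights: WeightVector
    lambda_max: float


@dataclasses.dataclass(frozen=True)
class ConsistencyReport:
    """Consistency diagnostics of a comparison matrix."""

    ci: float
    cr: float
    acceptable: bool
    ri_used: float


def validate_comparison_matrix(m: ComparisonMatrix, *, rtol: float = 1e-6) -> ComparisonMatrix:
    """Check positivity, unit diagonal and reciprocity; return *m* unchanged.

    Raises
    ------
    ValidationError
        Naming the first offending cell if any entry is non-positive, a
        diagonal entry differs from one, or ``a_ij * a_ji`` differs from
        one beyond *rtol*.
    """
    a = m.values
    if np.any(a <= 0):
        i, j = np.argwhere(a <= 0)[0]
        raise ValidationError(
            f"non-positive entry at ({m.labels[i]}, {m.labels[j]}): {a[i, j]:g}"
        )
    diag = np.diag(a)
    if np.any(np.abs(diag - 1.0) > 1e-9):
        i = int(np.argmax(np.abs(diag - 1.0)))
        raise ValidationError(f"diagonal entry for {m.labels[i]} is {diag[i]:g}, expected 1")
    prod = a * a.T
    bad = np.abs(prod - 1.0) > rtol
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"reciprocity violated at ({m.labels[i]}, {m.labels[j]}): "
            f"a_ij={a[i, j]:g}, a_ji={a[j, i]:g}, product {prod[i, j]:g}"
        )
    return m


def principal_priority(
    m: ComparisonMatrix,
    *,
    method: str = "power",
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> PriorityResult:
    """Derive the priority vector of a comparison matrix.

    The default solver is power iteration on the positive matrix (the
    Perron-Frobenius theorem guarantees convergence to the dominant
    eigenvector).  ``method="geometric"`` uses the geometric mean of rows
    as an independent cross-check; ``method="eig"`` uses a dense
    eigendecomposition.

    Returns
    -------
    PriorityResult
        Simplex-normalized priorities and the principal eigenvalue.
    """
    validate_comparison_matrix(m)
    a = m.values
    n = m.n
    if method == "power":
        w = np.full(n, 1.0 / n)
        for _ in range(max_iter):
            y = a @ w
            y /= y.sum()
            if np.max(np.abs(y - w)) < tol:
                w = y
                break
            w = y
        else:
            raise ComputationError(
                f"power iteration did not converge in {max_iter} iterations"
            )
        lam = float((a @ w).sum())
    elif method == "geometric":
        g = np.exp(np.mean(np.log(a), axis=1))
        w = g / g.sum()
        lam = float(np.mean((a @ w) / w))
    elif method == "eig":
        vals, vecs = np.linalg.eig(a)
        k = int(np.argmax(vals.real))
        lam = float(vals[k].real)
        w = np.abs(vecs[:, k].real)
        w = w / w.sum()
    else:
        raise ConfigurationError(f"unknown priority method {method!r}")
    return PriorityResult(WeightVector(m.labels, w), lam)


def consistency(
    m: ComparisonMatrix,
    result: PriorityResult | None = None,
    *,
    ri: float | None = None,
    strict: bool = False,
) -> ConsistencyReport:
    """Compute the consistency index and ratio of a comparison matrix.

    ``ci = (lambda_max - n) / (n - 1)`` and ``cr = ci / RI(n)``; for
    ``n <= 2`` the ratio is defined as zero.  With ``strict=True`` an
    unacceptable ratio raises; otherwise a warning is emitted and the
    report records ``acceptable=False`` (re-eliciting judgments is a
    human step a library cannot perform).
    """
    if result is None:
        result = principal_priority(m)
    n = m.n
    ci = (result.lambda_max - n) / (n - 1)
    if ci < -1e-9:
        raise ComputationError(f"negative consistency index {ci:g}")
    ci = max(ci, 0.0)
    if ri is None:
        if n not in RANDOM_INDEX:
            raise ConfigurationError(
                f"no random-index value for order {n}; supply ri= explicitly"
            )
        ri = RANDOM_INDEX[n]
    cr = 0.0 if n <= 2 else (0.0 if ri == 0 else ci / ri)
    acceptable = cr < CR_THRESHOLD
    if not acceptable:
        msg = f"consistency ratio {cr:.4f} >= {CR_THRESHOLD}; judgments should be revised"
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)
    return ConsistencyReport(ci=float(ci), cr=float(cr), acceptable=acceptable, ri_used=float(ri))


@dataclasses.dataclass(frozen=True)
class DependencyMatrix:
    """Column-stochastic inter-criterion dependency matrix, zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(str(lab) for lab in self.labels)
        values = np.asarray(self.values, dtype=float).copy()
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValidationError("dependency matrix must be square")
        if len(labels) != values.shape[0]:
            raise ValidationError("label count does not match matrix order")
        if np.any(values < 0):
            raise ValidationError("dependency matrix entries must be nonnegative")
        if np.any(np.abs(np.diag(values)) > 1e-12):
            i = int(np.argmax(np.abs(np.diag(values))))
            raise ValidationError(f"dependency diagonal must be zero (see {labels[i]})")
        colsums = values.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            j = int(np.argmax(np.abs(colsums - 1.0)))
            raise ValidationError(
                f"dependency column {labels[j]} sums to {colsums[j]:.6f}, expected 1"
            )
        values.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_csv(cls, path) -> "DependencyMatrix":
        from .io import read_matrix_csv

        labels, values = read_matrix_csv(path)
        return cls(labels, values)


def interdependent_weights(dep: DependencyMatrix, base: WeightVector) -> WeightVector:
    """Propagate base criterion weights through the dependency structure.

    Returns ``dep @ base``; column-stochasticity of *dep* keeps the
    result on the simplex.
    """
    if dep.labels != base.labels:
        raise ValidationError(
            f"dependency labels {dep.labels} do not match weight labels {base.labels}"
        )
    return WeightVector.normalized(dep.labels, dep.values @ base.values, atol=1e-6)


@dataclasses.dataclass(frozen=True)
class HierarchySpec:
    """Two-level hierarchy: ordered criteria, each with ordered children.

    ``local`` optionally carries per-criterion local priorities, either as
    a :class:`ComparisonMatrix` (to be solved) or a :class:`WeightVector`
    (supplied directly, e.g. transcribed from a published table).
    """

    criteria: tuple[str, ...]
    children: Mapping[str, tuple[str, ...]]
    local: Mapping[str, "ComparisonMatrix | WeightVector"] | None = None

    def __post_init__(self) -> None:
        criteria = tuple(self.criteria)
        children = {c: tuple(self.children[c]) for c in criteria}
        if set(self.children) != set(criteria):
            raise ValidationError("children mapping must cover exactly the criteria")
        subs = [s for c in criteria for s in children[c]]
        if len(set(subs)) != len(subs):
            raise ValidationError("a sub-criterion may have only one parent")
        if any(len(children[c]) < 1 for c in criteria):
            raise ValidationError("every criterion needs at least one sub-criterion")
        object.__setattr__(self, "criteria", criteria)
        object.__setattr__(self, "children", children)

    @property
    def subcriteria(self) -> tuple[str, ...]:
        return tuple(s for c in self.criteria for s in self.children[c])

    def parent_of(self, sub: str) -> str:
        for c in self.criteria:
            if sub in self.children[c]:
                return c
        raise KeyError(sub)

    def resolve_local_weights(self) -> dict[str, WeightVector]:
        """Local priority vector per criterion, solving matrices as needed."""
        if self.local is None:
            raise ConfigurationError("hierarchy carries no local priorities")
        out: dict[str, WeightVector] = {}
        for c in self.criteria:
            if c not in self.local:
                raise ConfigurationError(f"missing local priorities for criterion {c!r}")
            entry = self.local[c]
            if isinstance(entry, ComparisonMatrix):
                out[c] = principal_priority(entry).weights
            else:
                out[c] = entry
            if out[c].labels != self.children[c]:
                raise ValidationError(
                    f"local priorities for {c!r} are labelled {out[c].labels}, "
                    f"expected {self.children[c]}"
                )
        return out


def global_subcriteria_weights(
    criteria: WeightVector,
    hierarchy: HierarchySpec,
    local: Mapping[str, WeightVector] | None = None,
) -> WeightVector:
    """Weight each sub-criterion by ``local_weight * parent criterion weight``.

    Output follows the hierarchy's sub-criterion order and is normalized
    onto the simplex (local vectors transcribed from rounded tables may
    be off by a few 1e-4).
    """
    if tuple(criteria.labels) != hierarchy.criteria:
        raise ValidationError("criterion weights do not match hierarchy criteria")
    if local is None:
        local = hierarchy.resolve_local_weights()
    values = []
    for c in hierarchy.criteria:
        if c not in local:
            raise ConfigurationError(f"missing local priorities for criterion {c!r}")
        lw = local[c]
        values.extend(float(v) * criteria[c] for v in lw.values)
    return WeightVector.normalized(hierarchy.subcriteria, values, atol=1e-3)


@dataclasses.dataclass(frozen=True)
class Supermatrix:
    """Nonnegative square supermatrix over the sub-criteria.

    ``raw=True`` flags an unnormalized matrix; otherwise every column
    must be stochastic within 1e-6.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    raw: bool = False

    def __post_init__(self) -> None:
        labels = tuple(str(lab) for lab in self.labels)
        values = np.asarray(self.values, dtype=float).copy()
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValidationError("supermatrix must be square")
        if len(labels) != values.shape[0]:
            raise ValidationError("label count does not match supermatrix order")
        if np.any(values < 0):
            raise ValidationError("supermatrix entries must be nonnegative")
        if not self.raw:
            colsums = values.sum(axis=0)
            if np.any(np.abs(colsums - 1.0) > 1e-6):
                j = int(np.argmax(np.abs(colsums - 1.0)))
                raise ValidationError(
                    f"supermatrix column {labels[j]} sums to {colsums[j]:.6f}; "
                    "pass raw=True for an unnormalized matrix"
                )
        values.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_csv(cls, path, *, raw: bool = False) -> "Supermatrix":
        from .io import read_matrix_csv

        labels, values = read_matrix_csv(path)
        return cls(labels, values, raw=raw)


def apply_supermatrix(
    super_: Supermatrix,
    global_weights: WeightVector,
    *,
    mode: str = "single",
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> WeightVector:
    """Apply the supermatrix to the global weights.

    ``mode="single"`` performs one multiplication (the default synthesis
    here); ``mode="limit"`` raises the column-stochastic matrix to its
    limit power before multiplying.  Raw matrices are renormalized onto
    the simplex after multiplication.
    """
    if super_.labels != global_weights.labels:
        raise ValidationError("supermatrix labels do not match weight labels")
    s = super_.values
    if mode == "limit":
        if super_.raw:
            s = s / s.sum(axis=0, keepdims=True)
        p = s.copy()
        for _ in range(max_iter):
            q = p @ p
            if np.max(np.abs(q - p)) < tol:
                p = q
                break
            p = q
        else:
            raise ComputationError("supermatrix limit power did not converge")
        y = p @ global_weights.values
    elif mode == "single":
        y = s @ global_weights.values
    else:
        raise ConfigurationError(f"unknown supermatrix mode {mode!r}")
    total = y.sum()
    if total <= 0:
        raise ComputationError("supermatrix application produced a zero vector")
    return WeightVector.normalized(super_.labels, y / total, atol=1e-6)


@dataclasses.dataclass(frozen=True)
class AnpResult:
    """All intermediate vectors of the subjective-weighting chain."""

    criterion_priorities: PriorityResult
    criterion_consistency: ConsistencyReport
    interdependent: WeightVector
    global_weights: WeightVector
    subjective: WeightVector
    subjective_source: str  # "supermatrix", "global" or "override"


def run_anp(
    criterion_matrix: ComparisonMatrix,
    dependency: DependencyMatrix,
    hierarchy: HierarchySpec,
    *,
    supermatrix: Supermatrix | None = None,
    supermatrix_mode: str = "single",
    strict: bool = False,
) -> AnpResult:
    """Run the full subjective chain: priorities -> dependency -> globals
    -> optional supermatrix synthesis."""
    prio = principal_priority(criterion_matrix)
    report = consistency(criterion_matrix, prio, strict=strict)
    omega3 = interdependent_weights(dependency, prio.weights)
    globals_ = global_subcriteria_weights(omega3, hierarchy)
    if supermatrix is not None:
        subjective = apply_supermatrix(supermatrix, globals_, mode=supermatrix_mode)
        source = "supermatrix"
    else:
        subjective = globals_
        source = "global"
    return AnpResult(prio, report, omega3, globals_, subjective, source)
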