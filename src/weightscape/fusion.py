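"""Least-squares fusion of subjective and objective weight vectors.

The comprehensive weights minimize the summed squared deviations from
both input vectors subject to the sum-to-one constraint, solved as an
equality-constrained quadratic program so that unequal trust
coefficients remain supported.  Under equal trust the optimum is the
component-wise mean, which stays nonnegative for simplex inputs.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .anp import HierarchySpec
from .errors import ComputationError, ValidationError
from .weights import WeightVector


@dataclasses.dataclass(frozen=True)
class WeightBundle:
    """Subjective, objective and comprehensive weights on shared labels."""

    labels: tuple[str, ...]
    subjective: WeightVector
    objective: WeightVector
    comprehensive: WeightVector

    def to_frame(self) -> pd.DataFrame:
        """Table sorted descending by comprehensive weight."""
        frame = pd.DataFrame(
            {
                "subjective": self.subjective.values,
                "objective": self.objective.values,
                "comprehensive": self.comprehensive.values,
            },
            index=list(self.labels),
        )
        return frame.sort_values("comprehensive", ascending=False)


def _as_simplex(v: WeightVector | np.ndarray, labels=None, *, atol: float = 1e-3) -> WeightVector:
    if isinstance(v, WeightVector):
        return WeightVector.normalized(v.labels, v.values, atol=atol)
    return WeightVector.normalized(labels, v, atol=atol)


def least_squares_combine(
    u: WeightVector,
    v: WeightVector,
    *,
    alpha: float = 1.0,
    beta: float = 1.0,
    atol: float = 1e-3,
) -> WeightVector:
    """Fuse *u* (subjective) and *v* (objective) into comprehensive weights.

    Minimizes ``sum_j alpha*(w_j - u_j)**2 + beta*(w_j - v_j)**2`` subject
    to ``sum w = 1`` and ``w >= 0`` via the KKT system, with an active-set
    fallback should a component go negative (impossible under equal
    trust with simplex inputs).

    Inputs off the simplex by at most *atol* — e.g. vectors transcribed
    from tables rounded to 4 dp — are renormalized before solving.
    """
    if u.labels != v.labels:
        raise ValidationError("subjective and objective labels differ")
    if alpha < 0 or beta < 0 or alpha + beta <= 0:
        raise ValidationError("trust coefficients must be nonnegative, not both zero")
    uu = _as_simplex(u, atol=atol)
    vv = _as_simplex(v, atol=atol)
    m = len(uu)
    target = alpha * uu.values + beta * vv.values
    scale = alpha + beta
    free = np.ones(m, dtype=bool)
    w = np.zeros(m)
    for _ in range(m):
        k = int(free.sum())
        if k == 0:
            raise ComputationError("active-set solve eliminated every component")
        # KKT system on the free components: 2*scale*w + lam*1 = 2*target, 1'w = 1
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = 2.0 * scale * np.eye(k)
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.concatenate([2.0 * target[free], [1.0]])
        sol = np.linalg.solve(kkt, rhs)
        w = np.zeros(m)
        w[free] = sol[:k]
        if np.all(w[free] >= -1e-12):
            break
        free &= w >= -1e-12
    w = np.clip(w, 0.0, None)
    return WeightVector.normalized(uu.labels, w, atol=1e-6)


def fuse(
    u: WeightVector, v: WeightVector, *, alpha: float = 1.0, beta: float = 1.0
) -> WeightBundle:
    w = least_squares_combine(u, v, alpha=alpha, beta=beta)
    return WeightBundle(u.labels, _as_simplex(u), _as_simplex(v), w)


def grouped_shares(w: WeightVector, hierarchy: HierarchySpec) -> dict[str, float]:
    """Sum comprehensive weights per parent criterion, as percentages."""
    if set(w.labels) != set(hierarchy.subcriteria):
        raise ValidationError(
            "weight labels do not match the hierarchy's sub-criteria"
        )
    shares: dict[str, float] = {}
    for c in hierarchy.criteria:
        shares[c] = 100.0 * sum(w[s] for s in hierarchy.children[c])
    return shares
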