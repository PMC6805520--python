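import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weightscape import (
    ComparisonMatrix,
    ConfigurationError,
    DependencyMatrix,
    HierarchySpec,
    Supermatrix,
    ValidationError,
    WeightVector,
    apply_supermatrix,
    consistency,
    global_subcriteria_weights,
    interdependent_weights,
    principal_priority,
    validate_comparison_matrix,
)

SAATY = [1 / 9, 1 / 7, 1 / 5, 1 / 3, 1 / 2, 1.0, 2.0, 3.0, 5.0, 7.0, 9.0]


def reciprocal_matrix(upper, n):
    a = np.eye(n)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            a[i, j] = upper[k]
            a[j, i] = 1.0 / upper[k]
            k += 1
    return ComparisonMatrix(tuple(f"c{i}" for i in range(n)), a)


@st.composite
def reciprocal_matrices(draw, max_n=7):
    n = draw(st.integers(min_value=2, max_value=max_n))
    upper = draw(
        st.lists(st.sampled_from(SAATY), min_size=n * (n - 1) // 2, max_size=n * (n - 1) // 2)
    )
    return reciprocal_matrix(upper, n)


class TestValidation:
    def test_case_study_matrix_is_valid(self, fx):
        assert validate_comparison_matrix(fx.criterion_matrix) is fx.criterion_matrix

    def test_reciprocity_violation_names_cell(self):
        m = ComparisonMatrix(("a", "b"), [[1, 2], [2, 1]])
        with pytest.raises(ValidationError, match="reciprocity"):
            validate_comparison_matrix(m)

    def test_positivity(self):
        m = ComparisonMatrix(("a", "b"), [[1, -3], [-1 / 3, 1]])
        with pytest.raises(ValidationError, match="non-positive"):
            validate_comparison_matrix(m)

    def test_unit_diagonal(self):
        m = ComparisonMatrix(("a", "b"), [[2, 1], [1, 1]])
        with pytest.raises(ValidationError, match="diagonal"):
            validate_comparison_matrix(m)

    def test_too_small(self):
        with pytest.raises(ValidationError):
            ComparisonMatrix(("a",), [[1.0]])


class TestPrincipalPriority:
    def test_case_study_matrix(self, fx):
        result = principal_priority(fx.criterion_matrix)
        assert np.allclose(result.weights.values, fx.criterion_weights, atol=1e-4)
        assert result.lambda_max >= 3

    def test_all_ones_uniform(self):
        m = ComparisonMatrix(("a", "b", "c"), np.ones((3, 3)))
        result = principal_priority(m)
        assert np.allclose(result.weights.values, 1 / 3, atol=1e-12)
        assert result.lambda_max == pytest.approx(3.0, abs=1e-9)

    def test_consistent_matrix_recovers_weights(self):
        w = np.array([0.4, 0.3, 0.2, 0.1])
        a = w[:, None] / w[None, :]
        m = ComparisonMatrix(("a", "b", "c", "d"), a)
        result = principal_priority(m)
        assert np.allclose(result.weights.values, w, atol=1e-9)
        assert result.lambda_max == pytest.approx(4.0, abs=1e-9)

    def test_geometric_mode_cross_check(self, fx):
        power = principal_priority(fx.criterion_matrix)
        geo = principal_priority(fx.criterion_matrix, method="geometric")
        assert np.allclose(
            np.round(geo.weights.values, 4), np.round(power.weights.values, 4)
        )

    def test_unknown_method(self, fx):
        with pytest.raises(ConfigurationError):
            principal_priority(fx.criterion_matrix, method="nope")

    @settings(max_examples=40, deadline=None)
    @given(reciprocal_matrices())
    def test_matches_dense_eigen_oracle(self, m):
        result = principal_priority(m)
        # independent dense full-spectrum oracle
        vals, vecs = np.linalg.eig(m.values)
        k = int(np.argmax(vals.real))
        oracle = np.abs(vecs[:, k].real)
        oracle /= oracle.sum()
        assert np.allclose(result.weights.values, oracle, atol=1e-6)
        assert result.lambda_max == pytest.approx(float(vals[k].real), abs=1e-6)

    @settings(max_examples=40, deadline=None)
    @given(reciprocal_matrices())
    def test_simplex_and_lambda_bound(self, m):
        result = principal_priority(m)
        assert result.weights.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(result.weights.values >= 0)
        assert result.lambda_max >= m.n - 1e-9


class TestConsistency:
    def test_case_study_cr(self, fx):
        report = consistency(fx.criterion_matrix)
        assert report.cr == pytest.approx(0.0079, abs=0.0005)
        assert report.ri_used == 0.58
        assert report.acceptable

    def test_consistent_matrix_zero_cr(self):
        w = np.array([0.5, 0.25, 0.15, 0.1])
        m = ComparisonMatrix(tuple("abcd"), w[:, None] / w[None, :])
        report = consistency(m)
        assert report.ci == pytest.approx(0.0, abs=1e-9)
        assert report.cr == pytest.approx(0.0, abs=1e-9)

    def test_cyclic_matrix_unacceptable(self):
        m = ComparisonMatrix(("a", "b", "c"), [[1, 5, 1 / 5], [1 / 5, 1, 5], [5, 1 / 5, 1]])
        # dense eigen-oracle: circulant, lambda_max = 1 + 5 + 1/5 = 6.2
        lam = max(np.linalg.eigvals(m.values).real)
        assert lam == pytest.approx(6.2, abs=1e-9)
        with pytest.warns(UserWarning, match="consistency ratio"):
            report = consistency(m)
        assert report.cr > 0.1
        assert not report.acceptable

    def test_strict_mode_raises(self):
        m = ComparisonMatrix(("a", "b", "c"), [[1, 5, 1 / 5], [1 / 5, 1, 5], [5, 1 / 5, 1]])
        with pytest.raises(ValidationError):
            consistency(m, strict=True)

    def test_order_two_defined_as_zero(self):
        m = ComparisonMatrix(("a", "b"), [[1, 4], [1 / 4, 1]])
        report = consistency(m)
        assert report.cr == 0.0
        assert report.acceptable

    def test_missing_random_index(self):
        w = np.linspace(1, 2, 12)
        w /= w.sum()
        m = ComparisonMatrix(tuple(f"c{i}" for i in range(12)), w[:, None] / w[None, :])
        with pytest.raises(ConfigurationError):
            consistency(m)
        report = consistency(m, ri=1.54)
        assert report.cr == pytest.approx(0.0, abs=1e-9)


class TestDependency:
    def test_case_study_interdependence(self, fx):
        base = WeightVector(fx.criteria, fx.criterion_weights)
        out = interdependent_weights(fx.dependency, base)
        assert np.allclose(out.values, fx.interdependent, atol=1e-4)

    def test_doubly_stochastic_preserves_uniform(self):
        dep = DependencyMatrix(("a", "b", "c"), [[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        out = interdependent_weights(dep, WeightVector(("a", "b", "c"), [1 / 3] * 3))
        assert np.allclose(out.values, 1 / 3, atol=1e-12)

    def test_matches_manual_product(self, rng):
        m = 4
        raw = rng.random((m, m))
        np.fill_diagonal(raw, 0.0)
        raw /= raw.sum(axis=0, keepdims=True)
        labels = tuple("wxyz")
        dep = DependencyMatrix(labels, raw)
        base = rng.dirichlet(np.ones(m))
        expected = [sum(raw[i, j] * base[j] for j in range(m)) for i in range(m)]
        out = interdependent_weights(dep, WeightVector(labels, base))
        assert np.allclose(out.values, expected, atol=1e-12)

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValidationError, match="diagonal"):
            DependencyMatrix(("a", "b"), [[0.5, 0.5], [0.5, 0.5]])

    def test_rejects_bad_column_sum(self):
        with pytest.raises(ValidationError, match="sums to"):
            DependencyMatrix(("a", "b"), [[0, 0.5], [0.9, 0]])

    def test_label_mismatch(self, fx):
        base = WeightVector(("X", "Y", "Z"), fx.criterion_weights)
        with pytest.raises(ValidationError):
            interdependent_weights(fx.dependency, base)


class TestGlobalWeights:
    def test_case_study_spot_value(self, fx):
        omega3 = WeightVector.normalized(fx.criteria, fx.interdependent)
        out = global_subcriteria_weights(omega3, fx.hierarchy)
        assert out["I2"] == pytest.approx(0.2750, abs=1e-4)

    def test_full_case_study_table(self, fx):
        omega3 = WeightVector.normalized(fx.criteria, fx.interdependent)
        out = global_subcriteria_weights(omega3, fx.hierarchy)
        assert np.allclose(out.values, fx.global_weights, atol=1e-4)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_criterion_identity(self):
        h = HierarchySpec(
            ("only",),
            {"only": ("s1", "s2")},
            {"only": WeightVector(("s1", "s2"), [0.7, 0.3])},
        )
        out = global_subcriteria_weights(WeightVector(("only",), [1.0]), h)
        assert np.allclose(out.values, [0.7, 0.3], atol=1e-12)

    def test_missing_local_vector(self, fx):
        h = HierarchySpec(fx.criteria, dict(fx.hierarchy.children))
        omega3 = WeightVector.normalized(fx.criteria, fx.interdependent)
        with pytest.raises(ConfigurationError):
            global_subcriteria_weights(omega3, h)

    def test_local_matrices_are_solved(self):
        w = np.array([0.6, 0.4])
        m = ComparisonMatrix(("s1", "s2"), w[:, None] / w[None, :])
        h = HierarchySpec(("c",), {"c": ("s1", "s2")}, {"c": m})
        out = global_subcriteria_weights(WeightVector(("c",), [1.0]), h)
        assert np.allclose(out.values, w, atol=1e-9)


class TestSupermatrix:
    def test_identity(self, fx):
        sm = Supermatrix(fx.indicators, np.eye(11))
        w = fx.global_vector()
        out = apply_supermatrix(sm, w)
        assert np.allclose(out.values, w.values, atol=1e-12)

    def test_toy_matches_manual_product(self):
        labels = ("a", "b", "c")
        s = np.array([[0.2, 0.5, 0.1], [0.3, 0.25, 0.6], [0.5, 0.25, 0.3]])
        w = np.array([0.5, 0.3, 0.2])
        expected = [sum(s[i, j] * w[j] for j in range(3)) for i in range(3)]
        out = apply_supermatrix(Supermatrix(labels, s), WeightVector(labels, w))
        assert np.allclose(out.values, expected, atol=1e-12)

    def test_calibrated_fixture_reproduces_subjective(self, fx):
        out = apply_supermatrix(fx.calibrated_supermatrix(), fx.global_vector())
        assert np.allclose(out.values, np.asarray(fx.subjective) / sum(fx.subjective), atol=1e-9)
        assert np.allclose(out.values, fx.subjective, atol=1e-4)

    def test_raw_mode_renormalizes(self):
        labels = ("a", "b")
        sm = Supermatrix(labels, [[2.0, 1.0], [2.0, 3.0]], raw=True)
        out = apply_supermatrix(sm, WeightVector(labels, [0.5, 0.5]))
        assert out.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(out.values, [1.5 / 4.0, 2.5 / 4.0])

    def test_non_stochastic_requires_raw_flag(self):
        with pytest.raises(ValidationError, match="raw"):
            Supermatrix(("a", "b"), [[2.0, 1.0], [2.0, 3.0]])

    def test_limit_mode_reaches_stationary_distribution(self, rng):
        labels = tuple("abcd")
        s = rng.random((4, 4)) + 0.05
        s /= s.sum(axis=0, keepdims=True)
        sm = Supermatrix(labels, s)
        out = apply_supermatrix(sm, WeightVector(labels, rng.dirichlet(np.ones(4))))
        # oracle: stationary distribution from the dense eigendecomposition
        vals, vecs = np.linalg.eig(s)
        k = int(np.argmax(vals.real))
        pi = np.abs(vecs[:, k].real)
        pi /= pi.sum()
        out_limit = apply_supermatrix(sm, WeightVector(labels, rng.dirichlet(np.ones(4))), mode="limit")
        assert np.allclose(out_limit.values, pi, atol=1e-9)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=10_000))
def test_stochastic_operators_preserve_simplex(m, seed):
    rng = np.random.default_rng(seed)
    labels = tuple(f"s{i}" for i in range(m))
    raw = rng.random((m, m)) + 1e-3
    np.fill_diagonal(raw, 0.0)
    raw /= raw.sum(axis=0, keepdims=True)
    base = WeightVector(labels, rng.dirichlet(np.ones(m)))
    out = interdependent_weights(DependencyMatrix(labels, raw), base)
    assert out.values.sum() == pytest.approx(1.0, abs=1e-9)
    s = rng.random((m, m)) + 1e-3
    s /= s.sum(axis=0, keepdims=True)
    out2 = apply_supermatrix(Supermatrix(labels, s), base)
    assert out2.values.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(out2.values >= 0)
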