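"""Built-in verification fixture: the diabetes social-support case study.

All numbers published in the source case study (a three-criterion,
eleven-indicator social-support evaluation for type 2 diabetes
self-management) are bundled here so the pipeline can be verified
offline.  Provenance labels distinguish values transcribed from the
published tables (``reported``) from values derived arithmetically from
them (``derived``).

The published supermatrix itself is unavailable, so the subjective
vector cannot be independently recomputed; ``calibrated_supermatrix``
ships a rank-one column-stochastic stand-in that maps the global
weights onto the reported subjective vector, for plumbing/regression
tests only.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .anp import ComparisonMatrix, DependencyMatrix, HierarchySpec, Supermatrix
from .weights import WeightVector

CRITERIA: tuple[str, ...] = ("ES", "IS", "TS")
INDICATORS: tuple[str, ...] = (
    "E1", "E2", "E3", "E4", "I1", "I2", "I3", "T1", "T2", "T3", "T4",
)
CHILDREN: dict[str, tuple[str, ...]] = {
    "ES": ("E1", "E2", "E3", "E4"),
    "IS": ("I1", "I2", "I3"),
    "TS": ("T1", "T2", "T3", "T4"),
}


@dataclasses.dataclass(frozen=True)
class RsrRow:
    indicator: str
    rsr: float
    p_percent: float
    y: float


@dataclasses.dataclass(frozen=True)
class CaseStudyFixture:
    """Every published case-study value, loadable without network access."""

    criteria: tuple[str, ...]
    indicators: tuple[str, ...]
    criterion_matrix: ComparisonMatrix
    criterion_weights: tuple[float, ...]
    criterion_cr: float
    dependency: DependencyMatrix
    interdependent: tuple[float, ...]
    local_weights: dict[str, tuple[float, ...]]
    global_weights: tuple[float, ...]
    subjective: tuple[float, ...]
    sigma: tuple[float, ...]
    info_content: tuple[float, ...]
    objective: tuple[float, ...]
    comprehensive: dict[str, float]
    criterion_shares: dict[str, float]
    rsr_rows: tuple[RsrRow, ...]
    grade_thresholds: tuple[float, float]
    grade_partition: dict[int, tuple[str, ...]]
    n_recruited: int
    n_complete: int
    n_removed: int
    provenance: dict[str, str]

    @property
    def hierarchy(self) -> HierarchySpec:
        local = {
            c: WeightVector.normalized(CHILDREN[c], self.local_weights[c])
            for c in self.criteria
        }
        return HierarchySpec(self.criteria, CHILDREN, local)

    def subjective_vector(self) -> WeightVector:
        return WeightVector.normalized(self.indicators, self.subjective)

    def objective_vector(self) -> WeightVector:
        return WeightVector.normalized(self.indicators, self.objective)

    def global_vector(self) -> WeightVector:
        return WeightVector.normalized(self.indicators, self.global_weights)

    def comprehensive_vector(self) -> WeightVector:
        ordered = {lab: self.comprehensive[lab] for lab in self.indicators}
        return WeightVector.normalized(ordered.keys(), ordered.values())

    def calibrated_supermatrix(self) -> Supermatrix:
        """Rank-one stand-in mapping global weights to the subjective vector."""
        target = np.asarray(self.subjective, dtype=float)
        target = target / target.sum()
        values = np.tile(target[:, None], (1, len(self.indicators)))
        return Supermatrix(self.indicators, values)


def load_fixture() -> CaseStudyFixture:
    """Return the bundled case-study fixture."""
    criterion_matrix = ComparisonMatrix(
        CRITERIA,
        [
            [1.0, 3.0, 2.0],
            [1 / 3, 1.0, 1 / 2],
            [1 / 2, 2.0, 1.0],
        ],
    )
    dependency = DependencyMatrix(
        CRITERIA,
        [
            [0.0, 0.25, 0.25],
            [0.5, 0.0, 0.75],
            [0.5, 0.75, 0.0],
        ],
    )
    comprehensive = {  # descending order as published
        "I2": 0.2305,
        "I3": 0.1468,
        "T1": 0.0975,
        "T4": 0.0899,
        "E2": 0.0798,
        "E1": 0.0755,
        "I1": 0.0709,
        "T3": 0.0677,
        "T2": 0.0651,
        "E4": 0.0398,
        "E3": 0.0366,
    }
    rsr_rows = (
        RsrRow("E3", 0.0366, 9.09, 3.6592),
        RsrRow("E4", 0.0398, 18.18, 4.0846),
        RsrRow("T2", 0.0651, 27.27, 4.3872),
        RsrRow("T3", 0.0677, 36.36, 4.6415),
        RsrRow("I1", 0.0709, 45.45, 4.8743),
        RsrRow("E1", 0.0755, 54.55, 5.1004),
        RsrRow("E2", 0.0798, 63.64, 5.3319),
        RsrRow("T4", 0.0899, 72.73, 5.5828),
        RsrRow("T1", 0.0975, 81.82, 5.8779),
        RsrRow("I3", 0.1468, 90.91, 6.2816),
        RsrRow("I2", 0.2305, 97.73, 6.8808),
    )
    return CaseStudyFixture(
        criteria=CRITERIA,
        indicators=INDICATORS,
        criterion_matrix=criterion_matrix,
        criterion_weights=(0.5396, 0.1634, 0.2970),
        criterion_cr=0.0079,
        dependency=dependency,
        interdependent=(0.1151, 0.4926, 0.3924),
        local_weights={
            "ES": (0.4667, 0.2979, 0.0849, 0.1504),
            "IS": (0.1220, 0.5584, 0.3196),
            "TS": (0.4554, 0.1409, 0.1409, 0.2628),
        },
        global_weights=(
            0.0537, 0.0343, 0.0098, 0.0173, 0.0601, 0.2750,
            0.1574, 0.1787, 0.0553, 0.0553, 0.1031,
        ),
        subjective=(
            0.0615, 0.0587, 0.0050, 0.0089, 0.0520, 0.3409,
            0.2052, 0.0955, 0.0318, 0.0346, 0.1058,
        ),
        sigma=(
            0.3093, 0.3162, 0.2624, 0.2674, 0.2992, 0.3302,
            0.3037, 0.3004, 0.2788, 0.2766, 0.2839,
        ),
        info_content=(2.78, 3.14, 2.12, 2.20, 2.79, 3.74, 2.75, 3.10, 3.06, 3.14, 2.30),
        objective=(
            0.0894, 0.1009, 0.0681, 0.0708, 0.0898, 0.1201,
            0.0884, 0.0996, 0.0983, 0.1009, 0.0739,
        ),
        comprehensive=comprehensive,
        criterion_shares={"ES": 23.17, "IS": 44.81, "TS": 32.02},
        rsr_rows=rsr_rows,
        grade_thresholds=(4.0, 6.0),
        grade_partition={
            1: ("E3",),
            2: ("E4", "T2", "T3", "I1", "E1", "E2", "T4", "T1"),
            3: ("I3", "I2"),
        },
        n_recruited=3000,
        n_complete=2969,
        n_removed=31,
        provenance={
            "criterion_matrix": "reported",
            "criterion_weights": "reported",
            "criterion_cr": "reported",
            "dependency": "reported",
            "interdependent": "reported",
            "local_weights": "reported",
            "global_weights": "reported",
            "subjective": "reported (supermatrix unavailable; not recomputable)",
            "sigma": "reported (raw survey data unavailable; not recomputable)",
            "info_content": "reported (rounded to 2 dp)",
            "objective": "reported",
            "comprehensive": "reported",
            "criterion_shares": "ES/TS reported; IS derived as the complement",
            "rsr_rows": "reported",
            "grade_thresholds": "reported",
            "grade_partition": "reported",
            "n_recruited": "reported",
        },
    )


def export_fixture_files(out_dir) -> dict[str, str]:
    """Write the fixture bundle as CSV/JSON/YAML files runnable by the CLI.

    Returns a mapping of artifact name to path.  The written
    ``pipeline.yaml`` injects the reported subjective and objective
    vectors as overrides, so running it reproduces the published
    comprehensive weighting and grading end to end.
    """
    import yaml as _yaml
    from pathlib import Path

    from . import io as wio

    fx = load_fixture()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    wio.write_matrix_csv(out / "criteria.csv", fx.criterion_matrix.labels,
                         fx.criterion_matrix.values)
    paths["criteria"] = str(out / "criteria.csv")
    wio.write_matrix_csv(out / "dependency.csv", fx.dependency.labels, fx.dependency.values)
    paths["dependency"] = str(out / "dependency.csv")
    sm = fx.calibrated_supermatrix()
    wio.write_matrix_csv(out / "supermatrix.csv", sm.labels, sm.values)
    paths["supermatrix"] = str(out / "supermatrix.csv")

    hierarchy = {
        "criterion_matrix": "criteria.csv",
        "criteria": [
            {
                "name": c,
                "children": list(CHILDREN[c]),
                "weights": [float(v) for v in fx.local_weights[c]],
            }
            for c in fx.criteria
        ],
    }
    (out / "hierarchy.yaml").write_text(_yaml.safe_dump(hierarchy, sort_keys=False))
    paths["hierarchy"] = str(out / "hierarchy.yaml")

    wio.write_weights_json(out / "subjective.json", fx.subjective_vector())
    paths["subjective"] = str(out / "subjective.json")
    wio.write_weights_json(out / "objective.json", fx.objective_vector())
    paths["objective"] = str(out / "objective.json")

    pipeline = {
        "hierarchy": "hierarchy.yaml",
        "dependency": "dependency.csv",
        "supermatrix": "supermatrix.csv",
        "subjective_override": "subjective.json",
        "objective_override": "objective.json",
        "probit_mode": "legacy_percent_table",
        "grade_thresholds": [4.0, 6.0],
        "out_dir": "out",
    }
    (out / "pipeline.yaml").write_text(_yaml.safe_dump(pipeline, sort_keys=False))
    paths["pipeline"] = str(out / "pipeline.yaml")
    return paths
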