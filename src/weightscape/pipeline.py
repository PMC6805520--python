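"""End-to-end orchestration: subjective -> objective -> fusion -> grading."""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import io as wio
from .critic import critic as compute_critic
from .anp import (
    AnpResult,
    ComparisonMatrix,
    DependencyMatrix,
    HierarchySpec,
    Supermatrix,
    run_anp,
)
from .errors import ConfigurationError
from .fusion import WeightBundle, fuse, grouped_shares
from .rsr import GradeScheme, RsrTable, grade_weights
from .synth import SurveyConfig, filter_incomplete, generate_responses, score_responses
from .weights import WeightVector

logger = logging.getLogger(__name__)


def load_hierarchy_yaml(path) -> tuple[ComparisonMatrix, HierarchySpec]:
    """Load the criterion matrix and hierarchy from a YAML config.

    Each criterion entry carries ``name``, ``children`` and either a
    ``matrix`` CSV path or an inline ``weights`` list; file paths are
    resolved relative to the config file.
    """
    path = Path(path)
    payload = yaml.safe_load(path.read_text()) or {}
    base = path.parent
    if "criterion_matrix" not in payload or "criteria" not in payload:
        raise ConfigurationError(f"{path}: needs 'criterion_matrix' and 'criteria'")
    criterion_matrix = ComparisonMatrix.from_csv(base / payload["criterion_matrix"])
    names: list[str] = []
    children: dict[str, tuple[str, ...]] = {}
    local: dict[str, ComparisonMatrix | WeightVector] = {}
    for entry in payload["criteria"]:
        name = str(entry["name"])
        names.append(name)
        kids = tuple(str(k) for k in entry["children"])
        children[name] = kids
        if "matrix" in entry:
            local[name] = ComparisonMatrix.from_csv(base / entry["matrix"])
        elif "weights" in entry:
            local[name] = WeightVector.normalized(kids, entry["weights"])
        else:
            raise ConfigurationError(
                f"{path}: criterion {name!r} needs 'matrix' or 'weights'"
            )
    return criterion_matrix, HierarchySpec(tuple(names), children, local)


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration (paths already resolved)."""

    hierarchy: Path
    dependency: Path
    supermatrix: Path | None = None
    supermatrix_raw: bool = False
    supermatrix_mode: str = "single"
    scores: Path | None = None
    synth: SurveyConfig | None = None
    subjective_override: Path | None = None
    objective_override: Path | None = None
    alpha: float = 1.0
    beta: float = 1.0
    probit_mode: str = "exact"
    grade_thresholds: tuple[float, ...] = (4.0, 6.0)
    std_mode: str = "sample"
    strict_cr: bool = False
    out_dir: Path = Path("out")
    seed: int | None = None
    deterministic: bool = True

    def __post_init__(self) -> None:
        sources = [
            self.scores is not None,
            self.synth is not None,
            self.objective_override is not None,
        ]
        if sum(sources) != 1:
            raise ConfigurationError(
                "exactly one objective-weight source required: a scores table, "
                "a synthetic cohort config, or an objective override"
            )
        for label, p in (("hierarchy", self.hierarchy), ("dependency", self.dependency),
                         ("supermatrix", self.supermatrix), ("scores", self.scores),
                         ("subjective_override", self.subjective_override),
                         ("objective_override", self.objective_override)):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{label} file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        payload = yaml.safe_load(path.read_text()) or {}
        base = path.parent

        def resolve(key):
            return (base / payload[key]) if payload.get(key) else None

        synth_cfg = None
        if payload.get("synth") is not None:
            entry = payload["synth"]
            if isinstance(entry, str):
                synth_cfg = SurveyConfig.from_yaml(base / entry)
            else:
                synth_cfg = SurveyConfig(**entry)
        return cls(
            hierarchy=base / payload["hierarchy"],
            dependency=base / payload["dependency"],
            supermatrix=resolve("supermatrix"),
            supermatrix_raw=bool(payload.get("supermatrix_raw", False)),
            supermatrix_mode=payload.get("supermatrix_mode", "single"),
            scores=resolve("scores"),
            synth=synth_cfg,
            subjective_override=resolve("subjective_override"),
            objective_override=resolve("objective_override"),
            alpha=float(payload.get("alpha", 1.0)),
            beta=float(payload.get("beta", 1.0)),
            probit_mode=payload.get("probit_mode", "exact"),
            grade_thresholds=tuple(payload.get("grade_thresholds", (4.0, 6.0))),
            std_mode=payload.get("std_mode", "sample"),
            strict_cr=bool(payload.get("strict_cr", False)),
            out_dir=base / payload.get("out_dir", "out"),
            seed=payload.get("seed"),
            deterministic=bool(payload.get("deterministic", True)),
        )


@dataclasses.dataclass(frozen=True)
class PipelineResult:
    anp: AnpResult
    subjective: WeightVector
    subjective_source: str
    objective: WeightVector
    objective_source: str
    bundle: WeightBundle
    shares: dict[str, float]
    rsr: RsrTable
    hierarchy: HierarchySpec


def run_pipeline(cfg: PipelineConfig, *, write: bool = True) -> PipelineResult:
    """Execute every stage in order and (optionally) write the artifacts."""
    criterion_matrix, hierarchy = load_hierarchy_yaml(cfg.hierarchy)
    dependency = DependencyMatrix.from_csv(cfg.dependency)
    supermatrix = None
    if cfg.supermatrix is not None:
        supermatrix = Supermatrix.from_csv(cfg.supermatrix, raw=cfg.supermatrix_raw)
    anp_result = run_anp(
        criterion_matrix,
        dependency,
        hierarchy,
        supermatrix=supermatrix,
        supermatrix_mode=cfg.supermatrix_mode,
        strict=cfg.strict_cr,
    )
    if cfg.subjective_override is not None:
        subjective = wio.read_weights_json(cfg.subjective_override)
        subjective = subjective.permuted(hierarchy.subcriteria)
        subjective_source = "override"
    else:
        subjective = anp_result.subjective
        subjective_source = anp_result.subjective_source

    if cfg.objective_override is not None:
        objective = wio.read_weights_json(cfg.objective_override)
        objective_source = "override"
        diagnostics = None
    else:
        if cfg.scores is not None:
            scores = wio.read_scores_csv(cfg.scores)
            objective_source = "scores"
        else:
            responses = generate_responses(cfg.synth, seed=cfg.seed)
            kept = filter_incomplete(responses)
            logger.info("scored %d of %d synthetic respondents", len(kept), len(responses))
            scores = score_responses(kept, cfg.synth)
            objective_source = "synth"
        diagnostics = compute_critic(scores, std_mode=cfg.std_mode)
        objective = diagnostics.weights
    objective = objective.permuted(hierarchy.subcriteria)

    bundle = fuse(subjective, objective, alpha=cfg.alpha, beta=cfg.beta)
    shares = grouped_shares(bundle.comprehensive, hierarchy)
    rsr_table = grade_weights(
        bundle.comprehensive,
        mode=cfg.probit_mode,
        scheme=GradeScheme(cfg.grade_thresholds),
    )
    result = PipelineResult(
        anp_result, subjective, subjective_source, objective, objective_source,
        bundle, shares, rsr_table, hierarchy,
    )
    if write:
        _write_artifacts(cfg, result, diagnostics)
    return result


def _write_artifacts(cfg: PipelineConfig, result: PipelineResult, diagnostics) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    anp_payload = {
        "criterion_weights": result.anp.criterion_priorities.weights.to_dict(),
        "lambda_max": result.anp.criterion_priorities.lambda_max,
        "consistency": dataclasses.asdict(result.anp.criterion_consistency),
        "interdependent": result.anp.interdependent.to_dict(),
        "global_weights": result.anp.global_weights.to_dict(),
        "subjective": result.subjective.to_dict(),
        "subjective_source": result.subjective_source,
    }
    (out / "anp.json").write_text(json.dumps(anp_payload, indent=2) + "\n")
    obj_payload: dict = {
        "labels": list(result.objective.labels),
        "weights": [float(v) for v in result.objective.values],
        "source": result.objective_source,
    }
    if diagnostics is not None:
        obj_payload.update(
            sigma=[float(s) for s in diagnostics.sigma],
            conflict=np.asarray(diagnostics.conflict).tolist(),
            info=[float(c) for c in diagnostics.info],
        )
    (out / "objective.json").write_text(json.dumps(obj_payload, indent=2) + "\n")
    fused_frame = result.bundle.to_frame()
    fused_payload = {
        "order": list(fused_frame.index),
        "rows": fused_frame.reset_index(names="indicator").to_dict(orient="records"),
        "criterion_shares_percent": result.shares,
    }
    (out / "fused.json").write_text(json.dumps(fused_payload, indent=2) + "\n")
    rsr_payload = {
        "mode": result.rsr.mode,
        "rows": result.rsr.frame.to_dict(orient="records"),
        "grades": {str(g): list(v) for g, v in result.rsr.grade_partition().items()},
    }
    (out / "rsr.json").write_text(json.dumps(rsr_payload, indent=2) + "\n")
    (out / "report.md").write_text(render_report(result))
    (out / "report.json").write_text(
        json.dumps(
            {
                "anp": anp_payload,
                "objective": {k: v for k, v in obj_payload.items() if k != "conflict"},
                "fusion": fused_payload,
                "rsr": rsr_payload,
            },
            indent=2,
        )
        + "\n"
    )


def render_report(result: PipelineResult) -> str:
    """Deterministic markdown report (no timestamps)."""
    lines = ["# Indicator weighting report", ""]
    cons = result.anp.criterion_consistency
    lines += [
        "## Criterion priorities",
        "",
        f"- weights: {result.anp.criterion_priorities.weights.to_dict()}",
        f"- consistency ratio: {cons.cr:.4f} "
        f"({'acceptable' if cons.acceptable else 'NOT acceptable'})",
        f"- interdependent weights: {result.anp.interdependent.to_dict()}",
        "",
        "## Comprehensive weights (descending)",
        "",
        "| indicator | subjective | objective | comprehensive |",
        "| --- | --- | --- | --- |",
    ]
    frame = result.bundle.to_frame()
    for lab, row in frame.iterrows():
        lines.append(
            f"| {lab} | {row['subjective']:.4f} | {row['objective']:.4f} "
            f"| {row['comprehensive']:.4f} |"
        )
    lines += ["", "## Criterion shares", ""]
    for c, share in result.shares.items():
        lines.append(f"- {c}: {share:.2f}%")
    lines += ["", "## Grading", "", result.rsr.to_markdown(), "", "### Tiers", ""]
    tier_names = {1: "Low-sensitivity", 2: "Moderate-sensitivity", 3: "High-sensitivity"}
    for g in sorted(result.rsr.grade_partition(), reverse=True):
        members = ", ".join(result.rsr.grade_partition()[g])
        lines.append(f"- Grade {g} ({tier_names.get(g, 'tier')}): {members}")
    note = []
    if result.subjective_source == "override":
        note.append("subjective weights injected from a fixture/override, not recomputed")
    if result.objective_source == "override":
        note.append("objective weights injected from a fixture/override, not recomputed")
    if note:
        lines += ["", "> Note: " + "; ".join(note) + "."]
    return "\n".join(lines) + "\n"
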