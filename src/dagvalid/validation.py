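"""Decision rules and report assembly for DAG validation.

A marginal correlation is validated when its point estimate is in the
direction the DAG implies AND its absolute value is at least the magnitude
threshold (default 0.15).  A conditional independency is validated when the
absolute partial correlation is strictly below the threshold.  Confidence
intervals are always reported but never bind the verdict: in low-powered
study designs precision alone is a poor criterion, so whether a CI excludes
zero is surfaced as a flag and as a would-the-verdict-flip count only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import pandas as pd

from .composites import CompositeSpec, composite_score
from .dag import CausalDAG
from .implications import (
    ImpliedTestSet,
    IndependenceStatement,
    MarginalExpectation,
    expected_test_set,
)
from .stats import (
    CorrelationEstimate,
    EstimationConfig,
    InsufficientDataError,
    test_conditional,
    test_marginal,
)

__all__ = [
    "ValidationParams",
    "ValidationVerdict",
    "ValidationReport",
    "verdict_marginal",
    "verdict_conditional",
    "validate_dataset",
]

DEFAULT_THRESHOLD = 0.15

Verdict = Literal["validated", "not_validated", "untestable"]


@dataclass(frozen=True)
class ValidationParams:
    threshold: float = DEFAULT_THRESHOLD
    level: float = 0.95
    replicates: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")

    @property
    def estimation(self) -> EstimationConfig:
        return EstimationConfig(level=self.level, replicates=self.replicates, seed=self.seed)


@dataclass
class ValidationVerdict:
    implication: Union[MarginalExpectation, IndependenceStatement]
    estimate: Optional[CorrelationEstimate]
    verdict: Verdict
    direction_ok: Optional[bool] = None  # None = not applicable
    magnitude_ok: Optional[bool] = None
    ci_excludes_zero: Optional[bool] = None  # reported, never verdict-binding
    failure_flags: tuple[str, ...] = ()
    reason: Optional[str] = None  # set when untestable

    @property
    def kind(self) -> str:
        return "marginal" if isinstance(self.implication, MarginalExpectation) else "conditional"

    def to_dict(self) -> dict:
        imp = self.implication
        base = {
            "kind": self.kind,
            "x": imp.x,
            "y": imp.y,
            "verdict": self.verdict,
            "direction_ok": self.direction_ok,
            "magnitude_ok": self.magnitude_ok,
            "ci_excludes_zero": self.ci_excludes_zero,
            "failure_flags": list(self.failure_flags),
            "reason": self.reason,
            "estimate": self.estimate.to_dict() if self.estimate else None,
        }
        if isinstance(imp, MarginalExpectation):
            base["expected_sign"] = imp.expected_sign
        else:
            base["given"] = sorted(imp.conditioning_set)
        return base


def _sign_matches(rho: float, expected: str) -> Optional[bool]:
    if expected == "ambiguous":
        return None
    if rho == 0:
        return False
    return (rho > 0) == (expected == "positive")


def verdict_marginal(
    estimate: CorrelationEstimate,
    expectation: MarginalExpectation,
    threshold: float = DEFAULT_THRESHOLD,
) -> ValidationVerdict:
    """Direction + magnitude rule; |rho| exactly at threshold passes magnitude."""
    direction_ok = _sign_matches(estimate.rho, expectation.expected_sign)
    magnitude_ok = abs(estimate.rho) >= threshold
    validated = magnitude_ok and direction_ok is not False
    flags = []
    if direction_ok is False:
        flags.append("wrong_direction")
    if not magnitude_ok:
        flags.append("insufficient_magnitude")
    if direction_ok is None:
        flags.append("direction_untestable")
    return ValidationVerdict(
        implication=expectation,
        estimate=estimate,
        verdict="validated" if validated else "not_validated",
        direction_ok=direction_ok,
        magnitude_ok=magnitude_ok,
        ci_excludes_zero=not (estimate.ci_low <= 0 <= estimate.ci_high),
        failure_flags=tuple(flags) if not validated else (),
    )


def verdict_conditional(
    estimate: CorrelationEstimate,
    statement: IndependenceStatement,
    threshold: float = DEFAULT_THRESHOLD,
) -> ValidationVerdict:
    """|partial rho| strictly below threshold validates; at threshold fails."""
    magnitude_ok = abs(estimate.rho) < threshold
    flags = []
    if not magnitude_ok:
        # triage hint: a failed conditional test implicates its conditioning set
        flags.append("nonzero_partial_correlation")
        flags.append("suspect_conditioning_on:" + ",".join(sorted(statement.conditioning_set)))
    return ValidationVerdict(
        implication=statement,
        estimate=estimate,
        verdict="validated" if magnitude_ok else "not_validated",
        magnitude_ok=magnitude_ok,
        ci_excludes_zero=not (estimate.ci_low <= 0 <= estimate.ci_high),
        failure_flags=tuple(flags),
    )


@dataclass
class ValidationReport:
    dag_identity: str
    dataset_identity: str
    params: ValidationParams
    verdicts: list[ValidationVerdict] = field(default_factory=list)

    # -- summaries -------------------------------------------------------------
    @property
    def tested(self) -> list[ValidationVerdict]:
        return [v for v in self.verdicts if v.verdict != "untestable"]

    def counts(self) -> dict[str, int]:
        tested = self.tested
        return {
            "tested": len(tested),
            "validated": sum(v.verdict == "validated" for v in tested),
            "failed": sum(v.verdict == "not_validated" for v in tested),
            "untestable": sum(v.verdict == "untestable" for v in self.verdicts),
        }

    def ci_criterion_flips(self) -> int:
        """How many verdicts would change under a CI-excludes-zero criterion.

        A validated marginal whose CI crosses zero would fail; a validated
        conditional whose CI excludes zero would fail.  Reported for
        discussion only.
        """
        flips = 0
        for v in self.tested:
            if v.verdict != "validated" or v.estimate is None:
                continue
            if v.kind == "marginal" and not v.ci_excludes_zero:
                flips += 1
            elif v.kind == "conditional" and v.ci_excludes_zero:
                flips += 1
        return flips

    # -- rendering -------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "dag": self.dag_identity,
            "dataset": self.dataset_identity,
            "params": {
                "threshold": self.params.threshold,
                "level": self.params.level,
                "replicates": self.params.replicates,
                "seed": self.params.seed,
            },
            "counts": self.counts(),
            "ci_criterion_flips": self.ci_criterion_flips(),
            "verdicts": [v.to_dict() for v in self.verdicts],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        """Plain-text forest-style table, marginals then conditionals."""
        glyph = {"validated": "+", "not_validated": "x", "untestable": "?"}
        lines = [
            f"DAG:     {self.dag_identity}",
            f"dataset: {self.dataset_identity}",
            f"params:  threshold={self.params.threshold} level={self.params.level} "
            f"replicates={self.params.replicates} seed={self.params.seed}",
            "",
            f"{'':2} {'implication':48} {'rho':>7} {'95% CI':>17} {'n':>4}  verdict",
        ]
        for kind in ("marginal", "conditional"):
            block = [v for v in self.verdicts if v.kind == kind]
            if not block:
                continue
            lines.append(f"-- {kind} --")
            for v in block:
                label = str(v.implication)
                if v.estimate is None:
                    lines.append(f"{glyph[v.verdict]:2} {label:48} {'':7} {'':17} {'':4}  "
                                 f"{v.verdict} ({v.reason})")
                    continue
                e = v.estimate
                ci = f"[{e.ci_low:+.2f}, {e.ci_high:+.2f}]"
                lines.append(
                    f"{glyph[v.verdict]:2} {label:48} {e.rho:+7.3f} {ci:>17} "
                    f"{e.n_effective:>4}  {v.verdict}"
                )
        c = self.counts()
        lines.append("")
        lines.append(
            f"tested={c['tested']} validated={c['validated']} failed={c['failed']} "
            f"untestable={c['untestable']}  (CI-criterion would flip "
            f"{self.ci_criterion_flips()} validated verdicts)"
        )
        return "\n".join(lines) + "\n"


MappingEntry = Union[str, CompositeSpec]


def _resolve_columns(
    data: pd.DataFrame, mapping: dict[str, MappingEntry]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Build the node-level table: direct columns and composite scores."""
    node_cols = {}
    explained = {}
    for node, entry in mapping.items():
        if isinstance(entry, CompositeSpec):
            result = composite_score(data, entry)
            node_cols[node] = result.scores.reindex(data.index)
            explained[node] = result.explained_variance
        else:
            if entry not in data.columns:
                raise KeyError(f"mapped column {entry!r} for node {node!r} not in dataset")
            node_cols[node] = pd.to_numeric(data[entry], errors="coerce")
    return pd.DataFrame(node_cols, index=data.index), explained


def validate_dataset(
    dag: CausalDAG,
    data: pd.DataFrame,
    mapping: dict[str, MappingEntry],
    params: ValidationParams = ValidationParams(),
    dag_identity: str = "<dag>",
    dataset_identity: str = "<data>",
) -> ValidationReport:
    """Run every testable implication of the DAG against the mapped dataset.

    Implications whose variables are not all mapped, or whose complete-case
    count is insufficient, appear as ``untestable`` with a reason; estimation
    errors are recorded per-implication and never abort the run.
    """
    unknown = [n for n in mapping if n not in dag.roles]
    if unknown:
        raise KeyError(f"mapping refers to nodes absent from the DAG: {unknown}")
    if len(mapping) < 2:
        raise InsufficientDataError("mapping must cover at least 2 DAG nodes")
    node_data, _ = _resolve_columns(data, mapping)
    measured = set(mapping)

    implied = expected_test_set(dag)
    testable = implied.restrict(measured)
    report = ValidationReport(
        dag_identity=dag_identity, dataset_identity=dataset_identity, params=params
    )

    for expectation in implied.marginal:
        if expectation not in testable.marginal:
            report.verdicts.append(ValidationVerdict(
                implication=expectation, estimate=None, verdict="untestable",
                reason="unmeasured variable",
            ))
            continue
        try:
            est = test_marginal(node_data, (expectation.x, expectation.y), params.estimation)
        except (InsufficientDataError, KeyError) as err:
            report.verdicts.append(ValidationVerdict(
                implication=expectation, estimate=None, verdict="untestable",
                reason=str(err),
            ))
            continue
        report.verdicts.append(verdict_marginal(est, expectation, params.threshold))

    for statement in implied.conditional:
        if statement not in testable.conditional:
            report.verdicts.append(ValidationVerdict(
                implication=statement, estimate=None, verdict="untestable",
                reason="unmeasured variable",
            ))
            continue
        try:
            est = test_conditional(node_data, statement, params.estimation)
        except (InsufficientDataError, KeyError) as err:
            report.verdicts.append(ValidationVerdict(
                implication=statement, estimate=None, verdict="untestable",
                reason=str(err),
            ))
            continue
        report.verdicts.append(verdict_conditional(est, statement, params.threshold))

    return report


def content_hash(text: Union[str, bytes]) -> str:
    if isinstance(text, str):
        text = text.encode()
    return hashlib.sha256(text).hexdigest()[:16]
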