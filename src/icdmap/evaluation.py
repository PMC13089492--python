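"""Evaluation metrics against ground truth, aggregated across runs.

All denominators use the *evaluable* sources, N − Nnm, where N is the
total number of source codes in the (restricted) system and Nnm counts the
sources absent from the ground-truth table (typically intermediate parents
or codes mapping outside the chapter).

* top-1 accuracy = C / (N − Nnm); a one-to-one prediction is correct iff
  it is a member of the ground-truth set ("any partial match is
  complete"), and a rejected/unmapped evaluable source counts as wrong;
* classwise mean Jaccard = mean over evaluable sources of |P∩G| / |P∪G|
  (empty prediction with non-empty truth contributes 0);
* mapping coverage = fraction of evaluable sources with at least one
  prediction.

Run-to-run spread is summarised by the mean and *population* SD (divide
by n) across repeated runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .codesystem import CodeSystem, GroundTruthMap
from .errors import ConsistencyError, EvaluationError
from .mapping import (
    REJECTED,
    SELECTED,
    CandidateMap,
    FinalMapping,
    ResolutionOutcome,
    detect_source_to_parent,
)


@dataclass
class EvaluationFrame:
    """Predictions and ground truth for one run over one source system."""

    n_total: int
    entries: dict[str, tuple[set[str], set[str]]]  # sid -> (Pi, Gi)

    @property
    def n_not_mapped(self) -> int:
        return self.n_total - len(self.entries)

    @property
    def n_evaluable(self) -> int:
        return len(self.entries)

    @classmethod
    def from_mapping(
        cls,
        mapping: FinalMapping,
        truth: GroundTruthMap,
        source_system: CodeSystem,
    ) -> "EvaluationFrame":
        """Frame over every source code of the system.

        Sources absent from the ground truth are excluded from the
        evaluable entries (they feed Nnm); sources present in ground
        truth but without a prediction row get an empty prediction set.
        """
        preds = mapping.predictions()
        entries = {
            sid: (preds.get(sid, set()), set(truth.pairs[sid]))
            for sid in source_system.codes
            if sid in truth.pairs
        }
        return cls(n_total=len(source_system.codes), entries=entries)


def _check_frame(frame: EvaluationFrame) -> None:
    if frame.n_evaluable <= 0:
        raise EvaluationError("no evaluable sources (N - Nnm must be > 0)")


def top1_accuracy(frame: EvaluationFrame) -> float:
    """C / (N − Nnm) with the partial-match rule for set-valued truth."""
    _check_frame(frame)
    correct = 0
    for pi, gi in frame.entries.values():
        if len(pi) > 1:
            raise EvaluationError(
                "top-1 accuracy requires one-to-one predictions"
            )
        if pi and next(iter(pi)) in gi:
            correct += 1
    return correct / frame.n_evaluable


def jaccard_mean(frame: EvaluationFrame) -> float:
    """Classwise mean Jaccard similarity between Pi and Gi."""
    _check_frame(frame)
    total = 0.0
    for pi, gi in frame.entries.values():
        union = pi | gi
        if union:
            total += len(pi & gi) / len(union)
        # empty Pi with non-empty Gi: union non-empty, term 0; Gi is never
        # empty for an evaluable source
    return total / frame.n_evaluable


def mapping_coverage(frame: EvaluationFrame) -> float:
    """Fraction of evaluable sources with at least one predicted target."""
    _check_frame(frame)
    covered = sum(1 for pi, _ in frame.entries.values() if pi)
    return covered / frame.n_evaluable


@dataclass
class ConfusionCounts:
    """Resolution outcomes over source-to-parent cases only."""

    tp: int = 0  # selected a child that is in the ground-truth set
    tn: int = 0  # rejected, and no child of the flagged parent is in truth
    fp: int = 0  # selected a child outside the ground-truth set
    fn: int = 0  # rejected although some child was in the ground-truth set

    @property
    def n_cases(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def proportions(self) -> dict[str, float]:
        n = self.n_cases
        if n == 0:
            return {"tp": 0.0, "tn": 0.0, "fp": 0.0, "fn": 0.0}
        return {
            "tp": self.tp / n,
            "tn": self.tn / n,
            "fp": self.fp / n,
            "fn": self.fn / n,
        }

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "n_cases": self.n_cases,
            "proportions": self.proportions(),
        }


def resolution_confusion(
    candidates: list[CandidateMap],
    outcomes: list[ResolutionOutcome],
    truth: GroundTruthMap,
    target_system: CodeSystem,
) -> ConfusionCounts:
    """Confusion counts for granularity resolution.

    Only source-to-parent cases whose source appears in the ground truth
    are counted.  "A child is in truth" means an immediate child of the
    originally flagged parent is a member of the source's ground-truth
    set.  Simple-rule outcomes can never contribute TN or FN (the rule
    cannot reject).
    """
    outcome_by_source = {o.source_id: o for o in outcomes}
    counts = ConfusionCounts()
    for cand in candidates:
        if not detect_source_to_parent(cand):
            continue
        if cand.source_id not in truth.pairs:
            continue
        out = outcome_by_source.get(cand.source_id)
        if out is None:
            raise ConsistencyError(
                f"source-to-parent case {cand.source_id!r} has no outcome"
            )
        gi = truth.pairs[cand.source_id]
        child_hit = any(
            cid in gi for cid in target_system.child_ids(cand.target_id)
        )
        if out.decision == SELECTED:
            if out.child_id in gi:
                counts.tp += 1
            else:
                counts.fp += 1
        elif out.decision == REJECTED:
            if child_hit:
                counts.fn += 1
            else:
                counts.tn += 1
        else:
            raise ConsistencyError(
                f"unexpected decision {out.decision!r} for {cand.source_id!r}"
            )
    return counts


@dataclass
class MetricReport:
    """Per-run metric values with mean and population SD across runs."""

    runs: list[dict[str, float]]
    confusion: ConfusionCounts | None = None
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "runs": self.runs,
            "mean": self.mean,
            "sd": self.sd,
            "confusion": self.confusion.as_dict() if self.confusion else None,
        }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8", newline="")
        return text

    def table(self) -> str:
        """Human-readable summary table (metric, mean, sd)."""
        lines = [f"{'metric':<10}{'mean':>10}{'sd':>10}"]
        for key in sorted(self.mean):
            lines.append(f"{key:<10}{self.mean[key]:>10.4f}{self.sd[key]:>10.4f}")
        return "\n".join(lines)


def aggregate_runs(
    per_run: list[dict[str, float]],
    confusion: ConfusionCounts | None = None,
) -> MetricReport:
    """Mean and population SD per metric across repeated runs."""
    if not per_run:
        raise EvaluationError("at least one run required")
    keys = set(per_run[0])
    if any(set(r) != keys for r in per_run):
        raise EvaluationError("runs report inconsistent metric keys")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    n = len(per_run)
    for key in keys:
        vals = [r[key] for r in per_run]
        if min(vals) == max(vals):  # identical runs: exactly zero spread
            mean[key] = vals[0]
            sd[key] = 0.0
            continue
        mu = sum(vals) / n
        mean[key] = mu
        sd[key] = math.sqrt(sum((v - mu) ** 2 for v in vals) / n)
    return MetricReport(runs=list(per_run), confusion=confusion, mean=mean, sd=sd)


def evaluate_mapping(
    mapping: FinalMapping,
    truth: GroundTruthMap,
    source_system: CodeSystem,
) -> dict[str, float]:
    """Metric dict for one run; top-1 only in one-to-one mode."""
    frame = EvaluationFrame.from_mapping(mapping, truth, source_system)
    metrics: dict[str, float] = {
        "js": jaccard_mean(frame),
        "mc": mapping_coverage(frame),
    }
    if mapping.mode == "one-to-one":
        metrics["top1"] = top1_accuracy(frame)
    return metrics
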