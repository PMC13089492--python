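"""Final source→target mapping: argmax, granularity resolution, one-to-many.

The initial mapping is the cosine argmax over target embeddings.  When the
rank-1 target is a *non-leaf* (a "source-to-parent" case, the signature of
a granularity mismatch), one of two resolution strategies replaces it:

* **simple rule (SR)** — always select the immediate child of the flagged
  parent with the highest cosine similarity to the source.  Never rejects.
* **prompting (PR)** — build a multiple-choice prompt with the source
  description as anchor and the flagged parent's immediate children as
  options, plus an explicit reject option, and let a text-generation
  backend select exactly one label or reject all.  If the selected child
  is itself non-leaf, resolution re-applies recursively down the hierarchy
  up to a configurable depth.

One-to-many strategies bypass resolution: threshold (all targets scoring
at least λ) and top-K (the K best-scoring targets).
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from pathlib import Path

from .codesystem import CodeSystem
from .descriptions import GenerationBackend
from .embeddings import (
    EmbeddingSet,
    cosine_similarity,
    similarity_search,
    top1_search,
)
from .errors import (
    ArgumentError,
    BackendError,
    ChoiceParseError,
    ConsistencyError,
    IcdMapError,
)

logger = logging.getLogger(__name__)

REJECTED = "rejected"
SELECTED = "selected"
NOT_APPLICABLE = "not_applicable"

DEFAULT_REJECT_TEXT = "None of the above"

#: Multiple-choice prompt skeleton.  The anchor line and the "L. text"
#: option lines are a parsing contract shared with scripted responders.
CHOICE_PROMPT_HEADER = (
    "You are mapping codes between two clinical classification systems.\n"
    "Anchor term: {anchor}\n"
    "Which one of the following options describes the same clinical "
    "concept as the anchor term?\n"
)
CHOICE_PROMPT_FOOTER = (
    "Select exactly one option. If no option matches the anchor term, "
    "select \"{reject}\". Answer with the option letter only."
)

_OPTION_LINE = re.compile(r"^([A-Z])\. (.*)$")
_THINK_SEGMENT = re.compile(r"<think>.*?</think>", re.DOTALL | re.IGNORECASE)
_STANDALONE_LABEL = re.compile(r"(?<![A-Za-z])([A-Z])(?![A-Za-z])")
_NONE_PHRASE = re.compile(r"\bnone\b", re.IGNORECASE)


@dataclass(frozen=True)
class CandidateMap:
    """One source's rank-1 target before resolution."""

    source_id: str
    target_id: str
    score: float
    target_is_leaf: bool


@dataclass
class ResolutionOutcome:
    source_id: str
    decision: str  # SELECTED | REJECTED | NOT_APPLICABLE
    child_id: str | None
    method: str  # "simple_rule" | "prompting"
    prompt_text: str | None = None
    raw_response: str | None = None


@dataclass(frozen=True)
class MappingRecord:
    """One serialised row of a final mapping."""

    source_id: str
    target_id: str | None  # None for a rejected source
    score: float | None
    method: str
    decision: str


@dataclass
class FinalMapping:
    """The assembled mapping, one-to-one or set-valued."""

    mode: str  # "one-to-one" | "one-to-many"
    records: list[MappingRecord]
    unmapped: set[str] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def predictions(self) -> dict[str, set[str]]:
        """source id → predicted target set (empty for rejected sources)."""
        out: dict[str, set[str]] = {}
        for rec in self.records:
            out.setdefault(rec.source_id, set())
            if rec.target_id is not None:
                out[rec.source_id].add(rec.target_id)
        return out

    def pairs(self) -> dict[str, str]:
        """One-to-one view; raises if any source has several targets."""
        out: dict[str, str] = {}
        for rec in self.records:
            if rec.target_id is None:
                continue
            if rec.source_id in out:
                raise ConsistencyError(
                    f"source {rec.source_id!r} has multiple targets in "
                    "one-to-one mode"
                )
            out[rec.source_id] = rec.target_id
        return out

    def to_tsv(self, path: str | Path) -> None:
        """``source_id  target_id  score  method  decision`` rows, sorted."""
        lines = ["source_id\ttarget_id\tscore\tmethod\tdecision"]
        for rec in sorted(
            self.records, key=lambda r: (r.source_id, r.target_id or "")
        ):
            tid = rec.target_id or ""
            score = "" if rec.score is None else f"{rec.score:.6f}"
            lines.append(
                f"{rec.source_id}\t{tid}\t{score}\t{rec.method}\t{rec.decision}"
            )
        Path(path).write_text(
            "\n".join(lines) + "\n", encoding="utf-8", newline=""
        )


def load_mapping_tsv(path: str | Path) -> FinalMapping:
    """Read a serialised final mapping back from its TSV artifact."""
    import pandas as pd

    frame = pd.read_csv(
        Path(path), sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    expected = ["source_id", "target_id", "score", "method", "decision"]
    if list(frame.columns) != expected:
        raise ArgumentError(f"{path}: not a mapping TSV (header {list(frame.columns)})")
    records = []
    unmapped = set()
    methods = set()
    for row in frame.itertuples(index=False):
        methods.add(row.method)
        if row.decision == REJECTED:
            unmapped.add(row.source_id)
            records.append(MappingRecord(row.source_id, None, None, row.method, REJECTED))
        else:
            records.append(
                MappingRecord(
                    row.source_id, row.target_id,
                    float(row.score) if row.score else None,
                    row.method, row.decision,
                )
            )
    mode = "one-to-many" if methods & {"threshold", "topk"} else "one-to-one"
    return FinalMapping(mode=mode, records=records, unmapped=unmapped)


def initial_mapping(
    source: EmbeddingSet, target: EmbeddingSet, target_system: CodeSystem
) -> list[CandidateMap]:
    """Rank-1 cosine target per source code, with a leaf flag."""
    best = top1_search(source, target)
    return [
        CandidateMap(
            source_id=sid,
            target_id=tid,
            score=score,
            target_is_leaf=target_system.is_leaf(tid),
        )
        for sid, (tid, score) in sorted(best.items())
    ]


def detect_source_to_parent(candidate: CandidateMap) -> bool:
    """A non-leaf rank-1 target signals a granularity mismatch."""
    return not candidate.target_is_leaf


def resolve_simple_rule(
    candidate: CandidateMap,
    source: EmbeddingSet,
    target: EmbeddingSet,
    target_system: CodeSystem,
) -> ResolutionOutcome:
    """Select the flagged parent's immediate child with highest cosine.

    One level deep and never rejects — it always produces a map, even when
    the source landed on a wrong parent.
    """
    if not detect_source_to_parent(candidate):
        raise ArgumentError(
            f"candidate {candidate.source_id!r} is not a source-to-parent case"
        )
    child_ids = target_system.child_ids(candidate.target_id)
    if not child_ids:
        raise ConsistencyError(
            f"non-leaf target {candidate.target_id!r} has no children"
        )
    src_vec = source.vectors[candidate.source_id]
    scored = [
        (cosine_similarity(src_vec, target.vectors[cid]), cid)
        for cid in child_ids
    ]
    # highest score; exact ties broken by smallest child id
    best = min(scored, key=lambda t: (-t[0], t[1]))
    return ResolutionOutcome(
        source_id=candidate.source_id,
        decision=SELECTED,
        child_id=best[1],
        method="simple_rule",
    )


def build_choice_prompt(
    anchor: str,
    options: list[str],
    reject_text: str = DEFAULT_REJECT_TEXT,
) -> str:
    """Multiple-choice prompt: anchor, labelled options, final reject option."""
    if not options:
        raise ArgumentError("at least one option required")
    if len(options) >= len(string.ascii_uppercase):
        raise ArgumentError(
            f"too many options ({len(options)}); at most "
            f"{len(string.ascii_uppercase) - 1} supported"
        )
    labels = string.ascii_uppercase
    lines = [CHOICE_PROMPT_HEADER.format(anchor=anchor)]
    for i, text in enumerate(options):
        lines.append(f"{labels[i]}. {text}")
    lines.append(f"{labels[len(options)]}. {reject_text}")
    lines.append(CHOICE_PROMPT_FOOTER.format(reject=reject_text))
    return "\n".join(lines)


def parse_choice_response(raw: str, n_options: int) -> int | str:
    """Extract the chosen option index, or :data:`REJECTED`.

    Strips ``<think>…</think>`` reasoning segments first, then takes the
    first standalone letter that is a valid label; the label after the
    last option is the reject label.  A bare "none" phrase also counts as
    rejection.  Raises :class:`ChoiceParseError` when nothing parses.
    """
    if not raw:
        raise ChoiceParseError("empty response")
    text = _THINK_SEGMENT.sub(" ", raw)
    valid = string.ascii_uppercase[: n_options + 1]
    for match in _STANDALONE_LABEL.finditer(text):
        letter = match.group(1)
        if letter in valid:
            idx = valid.index(letter)
            return REJECTED if idx == n_options else idx
    if _NONE_PHRASE.search(text):
        return REJECTED
    raise ChoiceParseError(f"no parsable option label in response: {raw!r}")


def resolve_with_prompting(
    candidate: CandidateMap,
    backend: GenerationBackend,
    source_system: CodeSystem,
    target_system: CodeSystem,
    seed: int | None = None,
    reject_text: str = DEFAULT_REJECT_TEXT,
    max_depth: int = 3,
) -> ResolutionOutcome:
    """Resolve a source-to-parent case through multiple-choice prompting.

    Options are the *immediate* children of the flagged parent (sorted by
    code id), plus the reject option, always last.  A selected child that
    is itself non-leaf triggers another round, descending at most
    ``max_depth`` levels; an unparseable response counts as rejection with
    a warning.
    """
    if not detect_source_to_parent(candidate):
        raise ArgumentError(
            f"candidate {candidate.source_id!r} is not a source-to-parent case"
        )
    anchor = source_system.get(candidate.source_id).description
    parent_id = candidate.target_id
    prompt_text: str | None = None
    raw: str | None = None
    selected: str | None = None
    for _depth in range(max_depth):
        child_ids = target_system.child_ids(parent_id)
        if not child_ids:
            break  # current selection is a leaf; done
        options = [target_system.get(cid).description for cid in child_ids]
        prompt_text = build_choice_prompt(anchor, options, reject_text)
        try:
            raw = backend.complete(prompt_text, seed)
        except BackendError:
            raise
        except Exception as exc:
            raise BackendError(
                f"prompting backend failed: {exc}", prompt=prompt_text
            ) from exc
        try:
            parsed = parse_choice_response(raw, len(options))
        except ChoiceParseError:
            logger.warning(
                "unparseable choice response for source %r (recorded as "
                "rejection): %r",
                candidate.source_id,
                raw,
            )
            parsed = REJECTED
        if parsed == REJECTED:
            if selected is not None:
                break  # keep the last accepted level rather than discard it
            return ResolutionOutcome(
                candidate.source_id, REJECTED, None, "prompting",
                prompt_text, raw,
            )
        selected = child_ids[parsed]
        parent_id = selected
        if target_system.is_leaf(selected):
            break
    return ResolutionOutcome(
        candidate.source_id, SELECTED, selected, "prompting", prompt_text, raw
    )


def _is_descendant(system: CodeSystem, child_id: str, parent_id: str) -> bool:
    return any(a.code_id == parent_id for a in system.ancestors(child_id))


def assemble_final_mapping(
    candidates: list[CandidateMap],
    outcomes: list[ResolutionOutcome],
    target_system: CodeSystem | None = None,
    provenance: dict | None = None,
) -> FinalMapping:
    """Combine leaf candidates with resolution outcomes.

    Leaf candidates pass through; selected outcomes replace the parent
    target by the chosen child; rejections move the source to
    ``unmapped``.  When a target system is supplied, every selected child
    is verified to be a descendant of its flagged parent (hard error).
    """
    by_source = {c.source_id: c for c in candidates}
    outcome_by_source: dict[str, ResolutionOutcome] = {}
    for out in outcomes:
        if out.source_id not in by_source:
            raise ConsistencyError(
                f"outcome references unknown source {out.source_id!r}"
            )
        outcome_by_source[out.source_id] = out
    records: list[MappingRecord] = []
    unmapped: set[str] = set()
    for sid, cand in sorted(by_source.items()):
        if cand.target_is_leaf:
            records.append(
                MappingRecord(sid, cand.target_id, cand.score, "argmax", SELECTED)
            )
            continue
        out = outcome_by_source.get(sid)
        if out is None:
            raise ConsistencyError(
                f"source-to-parent case {sid!r} has no resolution outcome"
            )
        if out.decision == SELECTED:
            if out.child_id is None:
                raise ConsistencyError(f"selected outcome for {sid!r} lacks a child")
            if target_system is not None and not _is_descendant(
                target_system, out.child_id, cand.target_id
            ):
                raise ConsistencyError(
                    f"selected child {out.child_id!r} is not a descendant of "
                    f"flagged parent {cand.target_id!r}"
                )
            records.append(
                MappingRecord(sid, out.child_id, cand.score, out.method, SELECTED)
            )
        elif out.decision == REJECTED:
            unmapped.add(sid)
            records.append(MappingRecord(sid, None, None, out.method, REJECTED))
        else:
            raise ConsistencyError(
                f"unexpected decision {out.decision!r} for {sid!r}"
            )
    return FinalMapping(
        mode="one-to-one",
        records=records,
        unmapped=unmapped,
        provenance=provenance or {},
    )


def map_one_to_many_threshold(
    source: EmbeddingSet,
    target: EmbeddingSet,
    lam: float,
    provenance: dict | None = None,
) -> FinalMapping:
    """All targets scoring at least λ, per source (inclusive comparison).

    Inclusive ≥ keeps λ = 1 meaningful for exact-text twins.  A source may
    end up with an empty prediction set (it still appears, unmapped).
    """
    if not (-1.0 <= lam <= 1.0):
        raise ArgumentError(f"threshold λ must be in [-1, 1], got {lam}")
    ranked = similarity_search(source, target)
    records: list[MappingRecord] = []
    unmapped: set[str] = set()
    for sid in sorted(ranked):
        hits = [(tid, s) for tid, s in ranked[sid] if s >= lam]
        if not hits:
            unmapped.add(sid)
            records.append(MappingRecord(sid, None, None, "threshold", REJECTED))
        for tid, s in hits:
            records.append(MappingRecord(sid, tid, s, "threshold", SELECTED))
    prov = dict(provenance or {})
    prov["strategy"] = {"one_to_many": "threshold", "lambda": lam}
    return FinalMapping("one-to-many", records, unmapped, prov)


def map_one_to_many_topk(
    source: EmbeddingSet,
    target: EmbeddingSet,
    k: int,
    provenance: dict | None = None,
) -> FinalMapping:
    """The K best-scoring targets per source; never empty."""
    if k < 1:
        raise ArgumentError(f"K must be >= 1, got {k}")
    ranked = similarity_search(source, target)
    records: list[MappingRecord] = []
    for sid in sorted(ranked):
        for tid, s in ranked[sid][:k]:
            records.append(MappingRecord(sid, tid, s, "topk", SELECTED))
    prov = dict(provenance or {})
    prov["strategy"] = {"one_to_many": "topk", "k": k}
    return FinalMapping("one-to-many", records, set(), prov)
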