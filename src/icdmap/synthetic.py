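"""Synthetic paired code systems, ground truth, and scripted backends.

The generator emulates what makes cross-version clinical code mapping
hard, at a scale where exhaustive checking is possible:

* **linguistic variation** — descriptions are built from a token
  vocabulary organised into synonym classes; deriving the target system
  substitutes tokens for synonyms with probability ``p_synonym``
  (emulating "Ornithosis" vs "Psittacosis" style drift between versions);
* **code splits** — a source leaf becomes a non-leaf in the target whose
  label matches the source, with 2–4 children distinguished by
  discriminator tokens (one child is always the "unspecified" residual),
  emulating refinement in newer versions; ground truth maps the source to
  *all* children;
* **code consolidations** — a sibling group of source leaves collapses to
  one target code carrying the group parent's general label, emulating
  obsolete sub-classifications.

Scripted backends make the full pipeline runnable and deterministic
offline: a hashed bag-of-tokens encoder (optionally canonicalising
synonyms — an oracle that nullifies linguistic variation, which is what
good generated descriptions achieve), a ground-truth-aware multiple-choice
responder with a controllable error rate, an always-reject responder, and
an echoing text generator.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codesystem import Code, CodeSystem, GroundTruthMap
from .errors import BackendError, SimulationError

_TOKEN = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")

#: Synonym classes the default vocabulary is built from: each pair is two
#: interchangeable single-token spellings of one clinical concept.
DEFAULT_SYNONYM_PAIRS: list[tuple[str, str]] = [
    ("cholera", "vibriosis"), ("typhoid", "enteric-fever"),
    ("pneumonia", "lung-infection"), ("ornithosis", "psittacosis"),
    ("hepatitis", "liver-inflammation"), ("nephritis", "kidney-inflammation"),
    ("gastritis", "stomach-inflammation"), ("dermatitis", "skin-inflammation"),
    ("carditis", "heart-inflammation"), ("arthritis", "joint-inflammation"),
    ("acute", "sudden-onset"), ("chronic", "long-standing"),
    ("viral", "virus-related"), ("bacterial", "bacteria-related"),
    ("fungal", "mycotic"), ("parasitic", "parasite-related"),
    ("respiratory", "airway"), ("digestive", "alimentary"),
    ("intestinal", "bowel"), ("oesophageal", "esophageal"),
    ("renal", "nephric"), ("hepatic", "liver-related"),
    ("cardiac", "heart-related"), ("cerebral", "brain-related"),
    ("ocular", "eye-related"), ("aural", "ear-related"),
    ("nasal", "nose-related"), ("oral", "mouth-related"),
    ("febrile", "feverish"), ("haemorrhagic", "bleeding"),
    ("ulcerative", "ulcerating"), ("obstructive", "blocking"),
    ("congenital", "inborn"), ("acquired", "secondary"),
    ("malignant", "cancerous"), ("benign", "non-cancerous"),
    ("infectious", "communicable"), ("toxic", "poison-related"),
    ("allergic", "hypersensitive"), ("ischaemic", "ischemic"),
    ("septic", "septicaemic"), ("purulent", "suppurative"),
    ("granulomatous", "nodular"), ("atrophic", "wasting"),
    ("hypertrophic", "enlarged"), ("stenotic", "narrowed"),
    ("dilated", "distended"), ("perforated", "ruptured"),
    ("recurrent", "relapsing"), ("disseminated", "widespread"),
    ("localised", "localized"), ("bilateral", "two-sided"),
    ("unilateral", "one-sided"), ("proximal", "upper"),
    ("distal", "lower"), ("mucosal", "mucous-membrane"),
    ("vascular", "blood-vessel"), ("lymphatic", "lymph-related"),
    ("neural", "nerve-related"), ("muscular", "muscle-related"),
    ("osseous", "bony"), ("cystic", "cyst-forming"),
    ("fibrotic", "scarring"), ("necrotic", "dead-tissue"),
    ("oedematous", "swollen"), ("pruritic", "itching"),
]

#: Tokens appended to split children to emulate refined sub-conditions;
#: the last split child always gets the residual "unspecified" token.
DISCRIMINATOR_TOKENS = [
    "meningeal", "pulmonary", "septicemic", "cutaneous",
    "articular", "ophthalmic", "visceral",
]
RESIDUAL_TOKEN = "unspecified"


def default_vocabulary() -> dict[str, set[str]]:
    """Token → full synonym set (symmetric closure of the default pairs)."""
    vocab: dict[str, set[str]] = {}
    for a, b in DEFAULT_SYNONYM_PAIRS:
        vocab[a] = {a, b}
        vocab[b] = {a, b}
    return vocab


@dataclass
class SyntheticConfig:
    """Knobs for the paired-system generator.

    Defaults give a pair of moderate systems (hundreds of codes) with all
    three transformation kinds active at rates that exercise every code
    path without making any scenario rare.
    """

    n_chapters: int = 3
    depth: int = 3  # levels below a chapter root
    branching: tuple[int, int] = (2, 3)
    vocabulary: dict[str, set[str]] = field(default_factory=default_vocabulary)
    tokens_per_description: int = 2
    p_synonym: float = 0.3
    p_split: float = 0.15
    p_consolidate: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 2:
            raise SimulationError(f"depth must be >= 2, got {self.depth}")
        lo, hi = self.branching
        if not (1 <= lo <= hi):
            raise SimulationError(f"invalid branching range {self.branching}")
        for name in ("p_synonym", "p_split", "p_consolidate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise SimulationError(f"{name} must be in [0, 1], got {p}")
        if not self.vocabulary:
            raise SimulationError("vocabulary must be non-empty")
        if self.tokens_per_description < 1:
            raise SimulationError("tokens_per_description must be >= 1")

    def synonym_classes(self) -> list[tuple[str, ...]]:
        """Distinct synonym classes, each a sorted token tuple."""
        seen: set[tuple[str, ...]] = set()
        for tok, syns in sorted(self.vocabulary.items()):
            seen.add(tuple(sorted({tok} | set(syns))))
        return sorted(seen)


@dataclass
class ScenarioLog:
    """Per-source-leaf record of the transformation applied in derivation."""

    records: dict[str, dict] = field(default_factory=dict)

    def kinds(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.records.values():
            out[rec["kind"]] = out.get(rec["kind"], 0) + 1
        return out

    def to_json(self, path: str | Path, config: SyntheticConfig) -> None:
        payload = {
            "config": {
                "n_chapters": config.n_chapters,
                "depth": config.depth,
                "branching": list(config.branching),
                "tokens_per_description": config.tokens_per_description,
                "p_synonym": config.p_synonym,
                "p_split": config.p_split,
                "p_consolidate": config.p_consolidate,
                "seed": config.seed,
            },
            "synonyms": {
                t: sorted(s) for t, s in sorted(config.vocabulary.items())
            },
            "records": {sid: self.records[sid] for sid in sorted(self.records)},
        }
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
            newline="",
        )


# seed-stream offsets: one independent stream per operation
_GEN_STREAM = 1
_DERIVE_STREAM = 2


def generate_code_system(
    config: SyntheticConfig, system_id: str = "synthetic-src"
) -> CodeSystem:
    """Generate a forest of ``n_chapters`` full-depth chapters.

    Each description is ``tokens_per_description`` synonym-class
    representatives; a code never reuses a class used by an ancestor, and
    no two codes in the system share the same class set (so descriptions
    stay distinguishable even after synonym canonicalisation).
    """
    config.validate()
    rng = np.random.default_rng((config.seed, _GEN_STREAM))
    classes = config.synonym_classes()
    k = config.tokens_per_description
    if len(classes) < k + config.depth * k:
        raise SimulationError(
            f"vocabulary too small: {len(classes)} synonym classes for "
            f"descriptions of {k} tokens at depth {config.depth}"
        )
    used_sets: set[frozenset[int]] = set()

    def sample_description(excluded: set[int]) -> tuple[str, set[int]]:
        pool = [i for i in range(len(classes)) if i not in excluded]
        if len(pool) < k:
            raise SimulationError("vocabulary too small for ancestor-disjoint descriptions")
        for _ in range(1000):
            pick = rng.choice(len(pool), size=k, replace=False)
            idxs = {pool[int(i)] for i in pick}
            if frozenset(idxs) not in used_sets:
                used_sets.add(frozenset(idxs))
                tokens = sorted(classes[i][0] for i in idxs)
                return " ".join(tokens), idxs
        raise SimulationError("vocabulary too small: cannot find a fresh description")

    lo, hi = config.branching
    codes: list[Code] = []

    def expand(
        code_id: str, parent_id: str, chapter_id: str, level: int,
        ancestor_classes: set[int],
    ) -> None:
        desc, own = sample_description(ancestor_classes)
        codes.append(Code(code_id, desc, parent_id, chapter_id))
        if level >= config.depth:
            return
        n_children = int(rng.integers(lo, hi + 1))
        for i in range(1, n_children + 1):
            expand(
                f"{code_id}.{i}", code_id, chapter_id, level + 1,
                ancestor_classes | own,
            )

    for ch in range(1, config.n_chapters + 1):
        root_id = f"{ch:02d}"
        expand(root_id, "", root_id, 0, set())
    return CodeSystem(system_id, codes)


def derive_mapped_system(
    source: CodeSystem,
    config: SyntheticConfig,
    target_system_id: str = "synthetic-tgt",
) -> tuple[CodeSystem, GroundTruthMap, ScenarioLog]:
    """Derive the target system, ground truth, and scenario log.

    Internal nodes are copied (with synonym substitution).  Source leaves
    are partitioned into identity/synonym copies, splits, and
    consolidations; ground truth covers exactly the source leaves
    (intermediate parents have no ground-truth rows, feeding Nnm during
    evaluation, as with real crosswalk tables).
    """
    config.validate()
    rng = np.random.default_rng((config.seed, _DERIVE_STREAM))
    class_of: dict[str, tuple[str, ...]] = {}
    for cls in config.synonym_classes():
        for tok in cls:
            class_of[tok] = cls

    def substitute(desc: str) -> tuple[str, bool]:
        tokens = desc.split(" ")
        changed = False
        out = []
        for tok in tokens:
            cls = class_of.get(tok)
            alts = [t for t in cls if t != tok] if cls else []
            if alts and rng.random() < config.p_synonym:
                out.append(alts[int(rng.integers(len(alts)))])
                changed = True
            else:
                out.append(tok)
        return " ".join(out), changed

    tid = lambda sid: f"t{sid}"
    target_codes: list[Code] = []
    pairs: dict[str, set[str]] = {}
    log = ScenarioLog()

    leaf_ids = set(source.leaf_ids())
    # copy roots and internal nodes
    for sid in sorted(source.codes):
        if sid in leaf_ids:
            continue
        code = source.codes[sid]
        desc, _ = substitute(code.description)
        target_codes.append(
            Code(tid(sid), desc, tid(code.parent_id) if code.parent_id else "",
                 tid(code.chapter_id))
        )

    # group leaves by parent for consolidation decisions
    by_parent: dict[str, list[str]] = {}
    for sid in sorted(leaf_ids):
        by_parent.setdefault(source.codes[sid].parent_id, []).append(sid)

    for parent_id in sorted(by_parent, key=lambda p: (p == "", p)):
        group = by_parent[parent_id]
        consolidate = (
            len(group) >= 2
            and parent_id != ""
            and rng.random() < config.p_consolidate
        )
        if consolidate:
            general_desc, _ = substitute(source.codes[parent_id].description)
            cid = f"{tid(parent_id)}.x"
            target_codes.append(
                Code(cid, general_desc, tid(parent_id),
                     tid(source.codes[parent_id].chapter_id))
            )
            for sid in group:
                pairs[sid] = {cid}
                log.records[sid] = {
                    "kind": "consolidation", "group": list(group), "target": cid,
                }
            continue
        for sid in group:
            code = source.codes[sid]
            t_parent = tid(code.parent_id) if code.parent_id else ""
            t_chapter = tid(code.chapter_id)
            desc, changed = substitute(code.description)
            if rng.random() < config.p_split:
                split_parent = tid(sid)
                target_codes.append(Code(split_parent, desc, t_parent, t_chapter))
                n_children = int(rng.integers(2, 5))
                discs = list(
                    rng.choice(
                        DISCRIMINATOR_TOKENS, size=n_children - 1, replace=False
                    )
                ) + [RESIDUAL_TOKEN]
                child_ids = []
                for i, disc in enumerate(discs, start=1):
                    cid = f"{split_parent}.{i}"
                    target_codes.append(
                        Code(cid, f"{desc} {disc}", split_parent, t_chapter)
                    )
                    child_ids.append(cid)
                pairs[sid] = set(child_ids)
                log.records[sid] = {"kind": "split", "children": child_ids}
            else:
                target_codes.append(Code(tid(sid), desc, t_parent, t_chapter))
                pairs[sid] = {tid(sid)}
                log.records[sid] = {
                    "kind": "synonym" if changed else "identity",
                    "target": tid(sid),
                }

    target = CodeSystem(target_system_id, target_codes)
    truth = GroundTruthMap(source.system_id, target_system_id, pairs)
    return target, truth, log


# -- scripted backends ---------------------------------------------------


def _stable_hash(text: str) -> int:
    return int.from_bytes(hashlib.md5(text.encode("utf-8")).digest()[:4], "big")


class HashedBagEncoder:
    """Deterministic bag-of-tokens encoder over a fixed hashed index.

    Token counts are scattered into a fixed-dimension vector via a stable
    hash, so vectors are independent of which texts were seen first.  With
    ``canonicalize=True`` every token is first replaced by its
    synonym-class representative — an oracle encoder under which
    synonymous descriptions coincide exactly, emulating the effect of
    generated concise descriptions on linguistic variation.
    """

    def __init__(
        self,
        synonyms: dict[str, set[str]] | None = None,
        canonicalize: bool = False,
        dimension: int = 4096,
    ):
        self.dimension = dimension
        self.canonicalize = canonicalize
        self.backend_id = f"hashed-bag{'-canonical' if canonicalize else ''}"
        self._rep: dict[str, str] = {}
        if synonyms:
            for tok, syns in synonyms.items():
                self._rep[tok] = min({tok} | set(syns))

    def encode(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dimension, dtype=np.float64)
        for tok in _TOKEN.findall(text.lower()):
            if self.canonicalize:
                tok = self._rep.get(tok, tok)
            vec[_stable_hash(tok) % self.dimension] += 1.0
        return vec


def make_scripted_encoder(
    synonyms: dict[str, set[str]] | None,
    canonicalize: bool,
    dimension: int = 4096,
) -> HashedBagEncoder:
    return HashedBagEncoder(synonyms, canonicalize, dimension)


class EchoGenerator:
    """Returns the prompt verbatim.

    With the identity prompt template ``"{X}"`` this makes the generated
    description equal the input description — the neutral scripted stand-in
    for a concise-description model.
    """

    backend_id = "echo"

    def complete(self, prompt: str, seed: int | None = None) -> str:
        return prompt


_ANCHOR_LINE = re.compile(r"^Anchor term: (.*)$", re.MULTILINE)
_PROMPT_OPTION = re.compile(r"^([A-Z])\. (.*)$", re.MULTILINE)


def _parse_choice_prompt(prompt: str) -> tuple[str, list[tuple[str, str]]]:
    """(anchor, [(label, option text), ...]) — last option is the reject."""
    m = _ANCHOR_LINE.search(prompt)
    options = _PROMPT_OPTION.findall(prompt)
    if m is None or len(options) < 2:
        raise BackendError("malformed choice prompt", prompt=prompt)
    return m.group(1), options


class TruthChoiceResponder:
    """Ground-truth-aware multiple-choice responder.

    Resolves the anchor back to source code ids by description, and each
    option to target code ids; answers the label of the first option whose
    target is in the ground-truth set, else the reject label.  With
    probability ``error_rate`` it instead answers a uniformly chosen
    *wrong* label.  Deterministic under (constructor seed, call seed,
    prompt).
    """

    def __init__(
        self,
        truth: GroundTruthMap,
        source_system: CodeSystem,
        target_system: CodeSystem,
        error_rate: float = 0.0,
        seed: int = 0,
    ):
        if not (0.0 <= error_rate <= 1.0):
            raise SimulationError(f"error_rate must be in [0, 1], got {error_rate}")
        self.backend_id = f"truth-responder(err={error_rate})"
        self.truth = truth
        self.error_rate = error_rate
        self.seed = seed
        self._src_by_desc: dict[str, set[str]] = {}
        for code in source_system.codes.values():
            self._src_by_desc.setdefault(code.description, set()).add(code.code_id)
        self._tgt_by_desc: dict[str, set[str]] = {}
        for code in target_system.codes.values():
            self._tgt_by_desc.setdefault(code.description, set()).add(code.code_id)

    def complete(self, prompt: str, seed: int | None = None) -> str:
        anchor, options = _parse_choice_prompt(prompt)
        gt: set[str] = set()
        for sid in self._src_by_desc.get(anchor, set()):
            gt |= self.truth.targets(sid)
        correct_label = options[-1][0]  # reject unless a truth child appears
        for label, text in options[:-1]:
            if self._tgt_by_desc.get(text, set()) & gt:
                correct_label = label
                break
        if self.error_rate > 0.0:
            rng = np.random.default_rng(
                (self.seed, seed or 0, _stable_hash(prompt))
            )
            if rng.random() < self.error_rate:
                wrong = [lab for lab, _ in options if lab != correct_label]
                return wrong[int(rng.integers(len(wrong)))]
        return correct_label


class RejectResponder:
    """Always answers the reject (last) option label."""

    backend_id = "always-reject"

    def complete(self, prompt: str, seed: int | None = None) -> str:
        _, options = _parse_choice_prompt(prompt)
        return options[-1][0]


def make_scripted_responder(
    truth: GroundTruthMap,
    error_rate: float,
    seed: int,
    source_system: CodeSystem,
    target_system: CodeSystem,
) -> TruthChoiceResponder:
    return TruthChoiceResponder(truth, source_system, target_system, error_rate, seed)


def make_reject_responder() -> RejectResponder:
    return RejectResponder()
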