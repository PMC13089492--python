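"""Hierarchy-augmented and LLM-generated code descriptions.

Two enriched representations of a code's short clinical label:

* **HA (hierarchy-augmented)** — the label concatenated with its ancestor
  labels via "is" sentences, immediate parent first, chapter title last:
  ``"D is P1. P1 is P2. … P(j-1) is Pj."``.  Adds structural context so a
  sentence encoder sees where the concept sits in the classification.
* **LG (LLM-generated)** — a concise clinical description produced by
  prompting a text-generation backend.  Rephrasing by a language model
  tends to normalise lexical variation (synonymous labels converge on
  similar generated text), which is what makes the variant useful.

Generation backends are pluggable: anything with a
``complete(prompt, seed) -> str`` method and a ``backend_id``.  Scripted
deterministic backends used in tests live in :mod:`icdmap.synthetic`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

from .codesystem import CodeSystem
from .errors import ArgumentError, BackendError, GenerationError

#: Default prompt template for concise-description generation.  ``{X}`` is
#: the literal placeholder for the code description; override via the
#: ``lg_prompt_template`` config key.
DEFAULT_LG_PROMPT_TEMPLATE = (
    "Provide a concise, formal clinical description of the following "
    "condition: {X}. Respond with the description only."
)

PLACEHOLDER = "{X}"

_WS = re.compile(r"\s+")


def normalize_whitespace(text: str) -> str:
    """Strip ends and collapse internal whitespace runs; no case folding."""
    return _WS.sub(" ", text.strip())


@runtime_checkable
class GenerationBackend(Protocol):
    """Text-generation backend contract.

    Given a prompt and a seed, return a completion.  Scripted test
    backends must be deterministic under a fixed seed; real LLM backends
    may ignore the seed (stochastic generation).
    """

    backend_id: str

    def complete(self, prompt: str, seed: int | None = None) -> str: ...


@dataclass(frozen=True)
class HADescription:
    code_id: str
    text: str


@dataclass(frozen=True)
class LGDescription:
    code_id: str
    text: str
    backend_id: str
    seed: int | None


def build_ha_description(system: CodeSystem, code_id: str) -> HADescription:
    """Render the "is"-linked sentence chain for one code.

    Uses the labels the :class:`CodeSystem` stores, verbatim — no
    normalisation or reconciliation of near-duplicate labels.  A chapter
    root (no ancestors) renders as its bare description.
    """
    code = system.get(code_id)
    labels = [code.description] + [a.description for a in system.ancestors(code_id)]
    if len(labels) == 1:
        return HADescription(code_id, labels[0])
    sentences = [
        f"{labels[i]} is {labels[i + 1]}." for i in range(len(labels) - 1)
    ]
    return HADescription(code_id, " ".join(sentences))


def build_lg_prompt(description: str, template: str | None = None) -> str:
    """Substitute a code description into the concise-description template."""
    if not description:
        raise ArgumentError("description must be non-empty")
    template = DEFAULT_LG_PROMPT_TEMPLATE if template is None else template
    if PLACEHOLDER not in template:
        raise ArgumentError(
            f"prompt template is missing the {PLACEHOLDER!r} placeholder"
        )
    return template.replace(PLACEHOLDER, description)


def generate_lg_description(
    backend: GenerationBackend,
    code_id: str,
    description: str,
    seed: int | None = None,
    template: str | None = None,
) -> LGDescription:
    """Prompt the backend for a concise description and normalise it."""
    prompt = build_lg_prompt(description, template)
    try:
        raw = backend.complete(prompt, seed)
    except BackendError:
        raise
    except Exception as exc:  # backend adapters may raise anything
        raise BackendError(f"generation backend failed: {exc}", prompt=prompt) from exc
    text = normalize_whitespace(raw)
    if not text:
        raise GenerationError(
            f"backend {backend.backend_id!r} returned an empty completion "
            f"for code {code_id!r}"
        )
    return LGDescription(code_id, text, backend.backend_id, seed)
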