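"""Hierarchical code systems and ground-truth mapping tables.

A :class:`CodeSystem` models one version of a hierarchical clinical
classification (ICD-style): a forest of coded concepts, each with a short
clinical description, an optional parent, and a chapter label.  Chapter
titles are modelled as the root code of their chapter, so the full ancestor
chain of a leaf ends at the chapter title.

File dialect (both read and written here):

* code systems — UTF-8 TSV, LF line endings, header
  ``code_id\tdescription\tparent_id\tchapter_id``; an empty ``parent_id``
  marks a chapter root;
* ground-truth maps — UTF-8 TSV, header ``source_id\ttarget_id``; repeated
  ``source_id`` rows accumulate into a set (one-to-many ground truth).

Official release formats (CMS/IHACPA/WHO, GEM fixed-width files) are out of
scope: users convert to this dialect first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    CodeLookupError,
    CompositionError,
    FormatError,
    ReferentialError,
    StructureError,
)

logger = logging.getLogger(__name__)

SYSTEM_COLUMNS = ("code_id", "description", "parent_id", "chapter_id")
MAPPING_COLUMNS = ("source_id", "target_id")


@dataclass(frozen=True)
class Code:
    """One coded concept: id, clinical label, parent link, chapter label."""

    code_id: str
    description: str
    parent_id: str  # "" for a chapter root
    chapter_id: str


class CodeSystem:
    """A forest of :class:`Code` objects for one classification version.

    Validates on construction: unique non-empty ids, non-empty
    descriptions, resolvable parent links, acyclic chains, and chapter
    consistency (every code's chapter equals its root ancestor's chapter).
    """

    def __init__(self, system_id: str, codes: Iterable[Code]):
        self.system_id = system_id
        self.codes: dict[str, Code] = {}
        for code in codes:
            if not code.code_id:
                raise FormatError(f"{system_id}: empty code_id")
            if not code.description.strip():
                raise FormatError(
                    f"{system_id}: code {code.code_id!r} has an empty description"
                )
            if code.code_id in self.codes:
                raise FormatError(f"{system_id}: duplicate code_id {code.code_id!r}")
            self.codes[code.code_id] = code
        self._children: dict[str, set[str]] = {cid: set() for cid in self.codes}
        self.chapter_index: dict[str, set[str]] = {}
        for code in self.codes.values():
            if code.parent_id:
                if code.parent_id not in self.codes:
                    raise ReferentialError(
                        f"{system_id}: code {code.code_id!r} has dangling "
                        f"parent_id {code.parent_id!r}"
                    )
                self._children[code.parent_id].add(code.code_id)
            self.chapter_index.setdefault(code.chapter_id, set()).add(code.code_id)
        self._validate_forest()

    def _validate_forest(self) -> None:
        state: dict[str, int] = {}  # 0 = visiting, 1 = done
        for start in self.codes:
            chain = []
            cid: str | None = start
            while cid is not None and cid not in state:
                state[cid] = 0
                chain.append(cid)
                parent = self.codes[cid].parent_id
                cid = parent or None
            if cid is not None and state[cid] == 0:
                raise StructureError(
                    f"{self.system_id}: cycle in parent links at {cid!r}"
                )
            for c in chain:
                state[c] = 1
        for code in self.codes.values():
            root = code
            while root.parent_id:
                root = self.codes[root.parent_id]
            if code.chapter_id != root.chapter_id:
                raise StructureError(
                    f"{self.system_id}: code {code.code_id!r} has chapter "
                    f"{code.chapter_id!r} but its root {root.code_id!r} has "
                    f"{root.chapter_id!r}"
                )

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code_id: str) -> bool:
        return code_id in self.codes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodeSystem):
            return NotImplemented
        return self.system_id == other.system_id and self.codes == other.codes

    def get(self, code_id: str) -> Code:
        try:
            return self.codes[code_id]
        except KeyError:
            raise CodeLookupError(
                f"{self.system_id}: unknown code_id {code_id!r}"
            ) from None

    def ancestors(self, code_id: str) -> list[Code]:
        """Ancestor chain, immediate parent first, chapter root last."""
        code = self.get(code_id)
        out: list[Code] = []
        while code.parent_id:
            code = self.codes[code.parent_id]
            out.append(code)
        return out

    def children(self, code_id: str) -> set[Code]:
        """Immediate children only; empty set for a leaf."""
        self.get(code_id)
        return {self.codes[cid] for cid in self._children[code_id]}

    def child_ids(self, code_id: str) -> list[str]:
        """Immediate child ids in lexicographic order."""
        self.get(code_id)
        return sorted(self._children[code_id])

    def is_leaf(self, code_id: str) -> bool:
        """True iff the code has no children.

        A chapter root with no children counts as a leaf (degenerate
        singleton chapter).
        """
        self.get(code_id)
        return not self._children[code_id]

    def leaf_ids(self) -> list[str]:
        return sorted(cid for cid in self.codes if not self._children[cid])

    def restrict_to_chapter(self, chapter_id: str) -> "CodeSystem":
        """Sub-system containing only the codes of one chapter.

        Ancestor chains of surviving codes are unchanged (a chapter is
        closed under the parent relation), so the forest invariant holds.
        """
        if chapter_id not in self.chapter_index:
            raise CodeLookupError(
                f"{self.system_id}: unknown chapter {chapter_id!r}"
            )
        keep = self.chapter_index[chapter_id]
        return CodeSystem(
            self.system_id,
            [self.codes[cid] for cid in sorted(keep)],
        )


@dataclass
class GroundTruthMap:
    """Source code id → non-empty set of target code ids."""

    source_system: str
    target_system: str
    pairs: dict[str, set[str]] = field(default_factory=dict)

    def __contains__(self, source_id: str) -> bool:
        return source_id in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def targets(self, source_id: str) -> set[str]:
        return set(self.pairs.get(source_id, set()))

    def validate_against(
        self, source: CodeSystem, target: CodeSystem
    ) -> None:
        """Check every referenced id exists in its system."""
        for sid, tids in self.pairs.items():
            if sid not in source:
                raise ReferentialError(
                    f"ground truth references unknown source id {sid!r}"
                )
            for tid in tids:
                if tid not in target:
                    raise ReferentialError(
                        f"ground truth references unknown target id {tid!r}"
                    )


# -- tabular I/O ---------------------------------------------------------


def _read_tsv(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if tuple(frame.columns) != columns:
        raise FormatError(
            f"{path}: expected header {list(columns)}, found {list(frame.columns)}"
        )
    return frame


def load_code_system(path: str | Path, system_id: str | None = None) -> CodeSystem:
    """Load a code system from the documented 4-column TSV dialect."""
    path = Path(path)
    frame = _read_tsv(path, SYSTEM_COLUMNS)
    codes = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        if not row.code_id:
            raise FormatError(f"{path}:{row_no}: empty code_id")
        codes.append(
            Code(
                code_id=row.code_id,
                description=row.description,
                parent_id=row.parent_id,
                chapter_id=row.chapter_id,
            )
        )
    seen: set[str] = set()
    for row_no, code in enumerate(codes, start=2):
        if code.code_id in seen:
            raise FormatError(f"{path}:{row_no}: duplicate code_id {code.code_id!r}")
        seen.add(code.code_id)
    return CodeSystem(system_id or path.stem, codes)


def write_code_system(system: CodeSystem, path: str | Path) -> None:
    """Emit the documented dialect bit-exactly: tabs, LF, header first."""
    lines = ["\t".join(SYSTEM_COLUMNS)]
    for cid in sorted(system.codes):
        c = system.codes[cid]
        lines.append(f"{c.code_id}\t{c.description}\t{c.parent_id}\t{c.chapter_id}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="")


def load_mapping_table(
    path: str | Path,
    source_system: str = "source",
    target_system: str = "target",
) -> GroundTruthMap:
    """Load a two-column mapping TSV; repeated sources accumulate."""
    path = Path(path)
    frame = _read_tsv(path, MAPPING_COLUMNS)
    if len(frame) == 0:
        raise FormatError(f"{path}: mapping table has no rows")
    pairs: dict[str, set[str]] = {}
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        if not row.source_id or not row.target_id:
            raise FormatError(f"{path}:{row_no}: blank id field")
        pairs.setdefault(row.source_id, set()).add(row.target_id)
    return GroundTruthMap(source_system, target_system, pairs)


def write_mapping_table(truth: GroundTruthMap, path: str | Path) -> None:
    lines = ["\t".join(MAPPING_COLUMNS)]
    for sid in sorted(truth.pairs):
        for tid in sorted(truth.pairs[sid]):
            lines.append(f"{sid}\t{tid}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="")


def compose_mappings(
    first: GroundTruthMap, second: GroundTruthMap
) -> GroundTruthMap:
    """Relational composition for sequential mapping through a pivot system.

    ``result[s] = union over m in first[s] of second[m]``.  Sources whose
    entire intermediate set is absent from ``second`` are dropped and
    reported via a warning — sequential crosswalks are expected to be
    incomplete, so incompleteness is not an error.
    """
    if first.target_system != second.source_system:
        raise CompositionError(
            f"cannot compose: first targets {first.target_system!r} but "
            f"second sources {second.source_system!r}"
        )
    pairs: dict[str, set[str]] = {}
    dropped: list[str] = []
    for sid, mids in first.pairs.items():
        out: set[str] = set()
        for mid in mids:
            out |= second.pairs.get(mid, set())
        if out:
            pairs[sid] = out
        else:
            dropped.append(sid)
    if dropped:
        logger.warning(
            "compose_mappings: %d source(s) dropped (no intermediate had a "
            "map): %s",
            len(dropped),
            ", ".join(sorted(dropped)[:10]),
        )
    return GroundTruthMap(first.source_system, second.target_system, pairs)


# module-level functional aliases matching the operation names
def ancestors(system: CodeSystem, code_id: str) -> list[Code]:
    return system.ancestors(code_id)


def children(system: CodeSystem, code_id: str) -> set[Code]:
    return system.children(code_id)


def is_leaf(system: CodeSystem, code_id: str) -> bool:
    return system.is_leaf(code_id)


def restrict_to_chapter(system: CodeSystem, chapter_id: str) -> CodeSystem:
    return system.restrict_to_chapter(chapter_id)
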