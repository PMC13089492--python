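"""Encoding, fusion and cosine similarity search.

Each code gets a fixed-dimension vector from a pluggable sentence-encoder
backend.  When both the hierarchy-augmented (HA) and the generated (LG)
description variants are enabled, their two encodings are fused by the
elementwise mean, ``e = (e_ha + e_lg) / 2``; baseline mode (neither
variant) encodes the raw code description alone.  Fused vectors are *not*
re-normalised before cosine — cosine is scale-invariant, and normalising
before the mean would change what the fusion averages.

Ranking ties are broken by ascending target code id so that runs are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .codesystem import CodeSystem
from .descriptions import (
    GenerationBackend,
    build_ha_description,
    generate_lg_description,
)
from .errors import ArgumentError, BackendError, DegenerateVectorError


@runtime_checkable
class EncoderBackend(Protocol):
    """Sentence-encoder contract: text → fixed-dimension real vector.

    Identical text must yield an identical vector; ``dimension`` is
    constant for the lifetime of the backend.
    """

    backend_id: str
    dimension: int

    def encode(self, text: str) -> np.ndarray: ...


class SentenceTransformerEncoder:
    """Adapter for a real sentence-transformers checkpoint.

    Imported lazily so the package works without torch installed; any
    SBERT-family model (e.g. ``all-mpnet-base-v2``) can stand behind it.
    """

    def __init__(self, model_name: str = "all-mpnet-base-v2"):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise BackendError(
                "sentence-transformers is not installed; install it to use "
                f"the {model_name!r} encoder, or use a scripted encoder"
            ) from exc
        self._model = SentenceTransformer(model_name)
        self.backend_id = f"sbert:{model_name}"
        self.dimension = int(self._model.get_sentence_embedding_dimension())

    def encode(self, text: str) -> np.ndarray:  # pragma: no cover
        if not text:
            raise ArgumentError("cannot encode empty text")
        return np.asarray(self._model.encode(text), dtype=np.float64)


@dataclass(frozen=True)
class Variants:
    """Which description variants feed the embedding.

    ``Variants(False, False)`` is the baseline: raw code description only.
    """

    ha: bool = True
    lg: bool = True

    @property
    def label(self) -> str:
        if self.ha and self.lg:
            return "ha+lg"
        if self.ha:
            return "ha"
        if self.lg:
            return "lg"
        return "baseline"


@dataclass(frozen=True)
class Provenance:
    encoder_id: str
    generator_id: str | None
    seed: int | None
    variants: Variants


@dataclass
class EmbeddingSet:
    """Per-code fused vectors for one system under one configuration."""

    system_id: str
    vectors: dict[str, np.ndarray]
    provenance: Provenance | None = None

    def __post_init__(self) -> None:
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) > 1:
            raise ArgumentError(f"inconsistent vector shapes: {dims}")

    @property
    def dimension(self) -> int:
        first = next(iter(self.vectors.values()))
        return int(first.shape[0])

    def __len__(self) -> int:
        return len(self.vectors)

    def ids(self) -> list[str]:
        return sorted(self.vectors)

    def matrix(self) -> tuple[list[str], np.ndarray]:
        """(sorted ids, stacked row matrix) view of the set."""
        ids = self.ids()
        return ids, np.vstack([self.vectors[i] for i in ids])


def save_embeddings(emb: EmbeddingSet, path) -> None:
    """Persist an embedding set (exact float64 round trip, npz container)."""
    import json

    ids, matrix = emb.matrix()
    prov = None
    if emb.provenance is not None:
        p = emb.provenance
        prov = json.dumps(
            {
                "encoder_id": p.encoder_id,
                "generator_id": p.generator_id,
                "seed": p.seed,
                "ha": p.variants.ha,
                "lg": p.variants.lg,
            }
        )
    np.savez(
        path,
        system_id=np.array(emb.system_id),
        ids=np.array(ids),
        matrix=matrix,
        provenance=np.array(prov if prov is not None else ""),
    )


def load_embeddings(path) -> EmbeddingSet:
    """Inverse of :func:`save_embeddings`; vectors are bit-identical."""
    import json

    with np.load(path, allow_pickle=False) as data:
        ids = [str(i) for i in data["ids"]]
        matrix = data["matrix"]
        prov_raw = str(data["provenance"])
        provenance = None
        if prov_raw:
            p = json.loads(prov_raw)
            provenance = Provenance(
                encoder_id=p["encoder_id"],
                generator_id=p["generator_id"],
                seed=p["seed"],
                variants=Variants(ha=p["ha"], lg=p["lg"]),
            )
        return EmbeddingSet(
            system_id=str(data["system_id"]),
            vectors={cid: matrix[i].copy() for i, cid in enumerate(ids)},
            provenance=provenance,
        )


def encode_text(backend: EncoderBackend, text: str) -> np.ndarray:
    if not text:
        raise ArgumentError("cannot encode empty text")
    try:
        vec = np.asarray(backend.encode(text), dtype=np.float64)
    except (ArgumentError, BackendError):
        raise
    except Exception as exc:
        raise BackendError(f"encoder backend failed on {text!r}: {exc}") from exc
    if vec.ndim != 1 or vec.shape[0] != backend.dimension:
        raise BackendError(
            f"encoder {backend.backend_id!r} returned shape {vec.shape}, "
            f"expected ({backend.dimension},)"
        )
    return vec


def fuse_embeddings(
    e_ha: np.ndarray | None, e_lg: np.ndarray | None
) -> np.ndarray:
    """Elementwise mean of the two variant encodings.

    With one variant disabled (``None``) the other is returned unchanged.
    """
    if e_ha is None and e_lg is None:
        raise ArgumentError("at least one embedding required")
    if e_ha is None:
        return e_lg  # type: ignore[return-value]
    if e_lg is None:
        return e_ha
    if e_ha.shape != e_lg.shape:
        raise ArgumentError(
            f"dimension mismatch: {e_ha.shape} vs {e_lg.shape}"
        )
    return (e_ha + e_lg) / 2.0


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(a, b) = a·b / (‖a‖‖b‖), in [-1, 1]."""
    if a.shape != b.shape:
        raise ArgumentError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateVectorError("cosine undefined for a zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


def embed_code_system(
    system: CodeSystem,
    encoder: EncoderBackend,
    generator: GenerationBackend | None = None,
    variants: Variants = Variants(),
    seed: int | None = None,
    lg_prompt_template: str | None = None,
) -> EmbeddingSet:
    """Build one fused vector per code of (a possibly restricted) system.

    Iterates codes in sorted id order, but every per-code vector depends
    only on that code's descriptions, so the result is independent of
    insertion order.  Zero-norm vectors are rejected eagerly with the
    offending code id attached.
    """
    if variants.lg and generator is None:
        raise ArgumentError("LG variant enabled but no generation backend given")
    vectors: dict[str, np.ndarray] = {}
    for cid in sorted(system.codes):
        code = system.codes[cid]
        try:
            if not variants.ha and not variants.lg:
                fused = encode_text(encoder, code.description)
            else:
                e_ha = None
                e_lg = None
                if variants.ha:
                    e_ha = encode_text(
                        encoder, build_ha_description(system, cid).text
                    )
                if variants.lg:
                    lg = generate_lg_description(
                        generator, cid, code.description, seed, lg_prompt_template
                    )
                    e_lg = encode_text(encoder, lg.text)
                fused = fuse_embeddings(e_ha, e_lg)
        except Exception as exc:
            exc.add_note(f"while embedding code {cid!r} of {system.system_id!r}")
            raise
        if not np.any(fused):
            raise DegenerateVectorError(
                f"code {cid!r} of {system.system_id!r} embedded to a "
                "zero vector"
            )
        vectors[cid] = fused
    return EmbeddingSet(
        system_id=system.system_id,
        vectors=vectors,
        provenance=Provenance(
            encoder_id=encoder.backend_id,
            generator_id=generator.backend_id if generator else None,
            seed=seed,
            variants=variants,
        ),
    )


def _normalized_matrices(
    source: EmbeddingSet, target: EmbeddingSet
) -> tuple[list[str], np.ndarray, list[str], np.ndarray]:
    if len(source) == 0 or len(target) == 0:
        raise ArgumentError("embedding sets must be non-empty")
    if source.dimension != target.dimension:
        raise ArgumentError(
            f"dimension mismatch: {source.dimension} vs {target.dimension}"
        )
    sids, S = source.matrix()
    tids, T = target.matrix()
    s_norm = np.linalg.norm(S, axis=1, keepdims=True)
    t_norm = np.linalg.norm(T, axis=1, keepdims=True)
    if np.any(s_norm == 0) or np.any(t_norm == 0):
        raise DegenerateVectorError("zero-norm vector in embedding set")
    return sids, S / s_norm, tids, T / t_norm


def _snap_unit(sims: np.ndarray) -> np.ndarray:
    """Snap scores within rounding error of ±1 to exactly ±1.

    Identical texts must score exactly 1.0 (the inclusive λ = 1 threshold
    relies on it), but the normalised matrix product can land 1 ulp short.
    """
    sims[np.abs(sims - 1.0) < 1e-12] = 1.0
    sims[np.abs(sims + 1.0) < 1e-12] = -1.0
    return sims


def similarity_search(
    source: EmbeddingSet, target: EmbeddingSet
) -> dict[str, list[tuple[str, float]]]:
    """Full cosine ranking of all targets for every source code.

    Descending score; exact score ties broken by ascending target id.
    """
    sids, Sn, tids, Tn = _normalized_matrices(source, target)
    sims = _snap_unit(Sn @ Tn.T)
    out: dict[str, list[tuple[str, float]]] = {}
    for i, sid in enumerate(sids):
        row = sims[i]
        order = sorted(range(len(tids)), key=lambda j: (-row[j], tids[j]))
        out[sid] = [(tids[j], float(row[j])) for j in order]
    return out


def top1_search(
    source: EmbeddingSet, target: EmbeddingSet
) -> dict[str, tuple[str, float]]:
    """Best target per source under the same tie-break as the full ranking."""
    sids, Sn, tids, Tn = _normalized_matrices(source, target)
    sims = _snap_unit(Sn @ Tn.T)
    out: dict[str, tuple[str, float]] = {}
    for i, sid in enumerate(sids):
        row = sims[i]
        best = row.max()
        tied = [tids[j] for j in np.flatnonzero(row == best)]
        out[sid] = (min(tied), float(best))
    return out
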