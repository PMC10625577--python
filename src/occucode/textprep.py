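"""Free-text normalization and sentence embedding of job descriptions.

Descriptions are tokenized, lower-cased, stripped of punctuation and stemmed,
then embedded into fixed-length vectors. A record's input classes (e.g.
occupation and sector) are embedded separately and fused by elementwise
summation, so a missing class is a no-op.
"""

from __future__ import annotations

import abc
import dataclasses
import hashlib
import re
import unicodedata
from collections.abc import Iterable, Mapping, Sequence
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InternalContractError, InvalidCodeError
from .schemes import Code, SchemeSpec, parse_code
from .stemming import porter_stem

__all__ = [
    "InputRecord",
    "Embedder",
    "HashedBagOfStems",
    "SentenceModelEmbedder",
    "SUPPORTED_LANGUAGES",
    "normalize",
    "embed",
    "build_feature_matrix",
    "read_episodes",
]

#: Supported language tags for :func:`normalize`. ``"none"`` skips stemming
#: (used for synthetic abstract-token corpora, where stemming is identity).
SUPPORTED_LANGUAGES = ("en", "none")

_PUNCT_RE = re.compile(r"[^\w\s]|_", re.UNICODE)


@dataclasses.dataclass
class InputRecord:
    """One job episode: free text per input class plus an optional gold code."""

    entry_id: str
    texts: Mapping[str, str]
    gold: Optional[Code] = None
    origin: str = "data"  # "data" or "index" (coding-index augmentation)

    def text_for(self, input_class: str) -> str:
        """Text of an input class; a missing class reads as empty text."""
        return self.texts.get(input_class, "") or ""


def normalize(text: str, language: str = "en") -> list[str]:
    """Tokenize, strip punctuation, lowercase and stem ``text``.

    Empty or whitespace-only text yields an empty token list. Accented
    characters are kept (NFC-normalized), matching the French/Dutch source
    material.
    """
    if language not in SUPPORTED_LANGUAGES:
        raise ConfigurationError(
            f"unsupported language tag {language!r}; supported: {list(SUPPORTED_LANGUAGES)}"
        )
    cleaned = _PUNCT_RE.sub(" ", unicodedata.normalize("NFC", text).lower())
    tokens = cleaned.split()
    if language == "en":
        tokens = [porter_stem(tok) for tok in tokens]
    return tokens


class Embedder(abc.ABC):
    """Deterministic text-to-vector contract.

    Identical input text must always yield the identical vector, and empty
    text must map to the all-zero vector (the additive identity under
    summation fusion).
    """

    #: output dimensionality
    dim: int
    #: stable identifier recorded in model artifacts
    identifier: str

    @abc.abstractmethod
    def embed_text(self, text: str) -> np.ndarray:
        """Embed one free-text description into a ``dim``-length float vector."""


class HashedBagOfStems(Embedder):
    """Default embedder: signed hashed bag of stemmed tokens.

    Each token is hashed (keyed blake2b, fixed seed) to a coordinate and a
    sign; the text's vector is the signed count per coordinate. Deterministic
    across processes, needs no model download, and gives disjoint
    vocabularies near-orthogonal vectors in expectation.
    """

    def __init__(self, dim: int = 256, language: str = "en", hash_seed: int = 0):
        if dim < 1:
            raise ConfigurationError("dim must be positive")
        if language not in SUPPORTED_LANGUAGES:
            raise ConfigurationError(
                f"unsupported language tag {language!r}; supported: {list(SUPPORTED_LANGUAGES)}"
            )
        self.dim = dim
        self.language = language
        self.hash_seed = hash_seed
        self.identifier = f"hashed-bag-of-stems/dim={dim}/lang={language}/seed={hash_seed}"

    def _hash(self, token: str) -> int:
        digest = hashlib.blake2b(
            token.encode("utf-8"), digest_size=8, key=str(self.hash_seed).encode()
        ).digest()
        return int.from_bytes(digest, "big")

    def embed_text(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=np.float64)
        for token in normalize(text, self.language):
            h = self._hash(token)
            sign = 1.0 if h & 1 else -1.0
            vec[(h >> 1) % self.dim] += sign
        return vec


class SentenceModelEmbedder(Embedder):
    """Optional adapter for pretrained sentence-embedding models.

    Requires the ``sentence-transformers`` package (not a hard dependency).
    Stemming is deliberately skipped: pretrained sentence models expect
    surface forms.
    """

    def __init__(self, model_name: str = "all-MiniLM-L6-v2"):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ConfigurationError(
                "SentenceModelEmbedder requires the optional 'sentence-transformers' "
                "package; install it or use the default hashed-bag-of-stems embedder"
            ) from exc
        self._model = SentenceTransformer(model_name)
        self.dim = int(self._model.get_sentence_embedding_dimension())
        self.identifier = f"sentence-model/{model_name}"

    def embed_text(self, text: str) -> np.ndarray:  # pragma: no cover - optional
        if not text.strip():
            return np.zeros(self.dim, dtype=np.float64)
        return np.asarray(self._model.encode([text])[0], dtype=np.float64)


def embed(
    record: InputRecord, embedder: Embedder, input_classes: Sequence[str]
) -> np.ndarray:
    """Fused embedding of a record: elementwise sum over its input classes."""
    total = np.zeros(embedder.dim, dtype=np.float64)
    for cls in input_classes:
        vec = embedder.embed_text(record.text_for(cls))
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != (embedder.dim,):
            raise InternalContractError(
                f"embedder {embedder.identifier!r} returned shape {vec.shape}, "
                f"expected ({embedder.dim},)"
            )
        total += vec
    if not np.all(np.isfinite(total)):
        raise InternalContractError(
            f"embedder {embedder.identifier!r} produced non-finite values"
        )
    return total


def build_feature_matrix(
    records: Sequence[InputRecord], embedder: Embedder, input_classes: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Stack fused embeddings row-wise; returns the matrix and aligned entry ids."""
    if len(records) == 0:
        raise DataError("cannot build a feature matrix from zero records")
    matrix = np.empty((len(records), embedder.dim), dtype=np.float64)
    ids = []
    for i, rec in enumerate(records):
        matrix[i] = embed(rec, embedder, input_classes)
        ids.append(rec.entry_id)
    return matrix, ids


def read_episodes(
    path: str,
    input_classes: Mapping[str, str] | Sequence[str],
    id_column: str = "entry_id",
    gold_column: Optional[str] = "gold_code",
    scheme: Optional[SchemeSpec] = None,
    delimiter: str = ",",
) -> list[InputRecord]:
    """Read a job-episode table from CSV.

    ``input_classes`` maps input-class name -> CSV column (or lists columns
    used as both). When ``scheme`` is given, non-empty gold codes are parsed
    (and validated) against it; otherwise gold is ignored.
    """
    if not isinstance(input_classes, Mapping):
        input_classes = {name: name for name in input_classes}
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [col for col in [id_column, *input_classes.values()] if col not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    has_gold = (
        scheme is not None and gold_column is not None and gold_column in df.columns
    )
    records: list[InputRecord] = []
    seen_ids: set[str] = set()
    for rowd in df.to_dict(orient="records"):
        entry_id = str(rowd[id_column])
        if entry_id in seen_ids:
            raise DataError(f"{path}: duplicate entry_id {entry_id!r}")
        seen_ids.add(entry_id)
        texts = {name: rowd[col] for name, col in input_classes.items()}
        gold: Optional[Code] = None
        if has_gold:
            raw = rowd[gold_column].strip()
            if raw:
                try:
                    gold = parse_code(scheme, raw)  # type: ignore[arg-type]
                except InvalidCodeError as exc:
                    raise InvalidCodeError(f"{path}: entry {entry_id}: {exc}") from exc
        records.append(InputRecord(entry_id=entry_id, texts=texts, gold=gold))
    return records
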