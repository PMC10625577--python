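"""Gradient-boosted-tree occupational coder with confidence-scored suggestions.

The model maps fused text embeddings to complete codes. Training uses the
train partition only; the validation partition drives early stopping; the
test partition is reserved for evaluation. Class imbalance is deliberately
left untouched (synthetic over/undersampling is inapplicable to classes of
size one).

Backend note: the boosted-tree ensemble is scikit-learn's
``HistGradientBoostingClassifier``. Hyperparameters without a backend
equivalent (``max_delta_step``, ``gamma``, ``subsample``, ``colsample_*``)
are accepted for interface fidelity and recorded as unmapped in the training
metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from collections.abc import Sequence
from typing import Optional

import joblib
import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import log_loss

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateModelError,
    DegenerateSplitError,
    InvalidCodeError,
)
from .schemes import Code, SchemeSpec, is_complete, parse_code
from .textprep import Embedder, InputRecord, build_feature_matrix

__all__ = [
    "HyperParams",
    "DatasetSplit",
    "TrainedCoder",
    "CodeSuggestion",
    "filter_viable",
    "split_dataset",
    "augment_with_index",
    "train_coder",
    "predict_topk",
    "predict_suggestions",
    "select_input_classes",
    "save_coder",
    "load_coder",
]


@dataclasses.dataclass(frozen=True)
class HyperParams:
    """Boosting hyperparameters; defaults are the fixed published setting."""

    eta: float = 0.6
    max_delta_step: float = 1.0
    max_depth: int = 20
    gamma: float = 1.5
    lambda_: float = 1e-4
    min_child_weight: float = 0.0
    subsample: float = 0.75
    colsample_by_tree: float = 1.0
    colsample_by_level: float = 1.0
    early_stopping_rounds: int = 1
    #: hard cap on boosting rounds (the stopping rule is published, a cap is not)
    max_rounds: int = 500

    #: fields the scikit-learn backend cannot honour
    UNMAPPED = ("max_delta_step", "gamma", "subsample", "colsample_by_tree", "colsample_by_level")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class DatasetSplit:
    """Disjoint, exhaustive train/test/validation partitions of a dataset."""

    train: list[InputRecord]
    test: list[InputRecord]
    validation: list[InputRecord]
    fractions: tuple[float, float, float] = (0.60, 0.30, 0.10)
    seed: int = 42

    def replace_train(self, train: list[InputRecord]) -> "DatasetSplit":
        """Copy of the split with a substituted (e.g. augmented) train set."""
        return dataclasses.replace(self, train=list(train))


@dataclasses.dataclass(frozen=True)
class CodeSuggestion:
    """A predicted code with its class-probability confidence."""

    code: Code
    confidence: float
    rank: int


@dataclasses.dataclass
class TrainedCoder:
    """A trained classification model plus everything needed to apply it."""

    model: HistGradientBoostingClassifier
    scheme: SchemeSpec
    label_table: tuple[str, ...]  # index -> canonical complete code
    embedder: Embedder
    input_classes: tuple[str, ...]
    metadata: dict

    @property
    def n_classes(self) -> int:
        return len(self.label_table)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "labels": self.label_table,
                "embedder": self.embedder.identifier,
                "input_classes": self.input_classes,
                "metadata": {k: v for k, v in sorted(self.metadata.items())},
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def filter_viable(
    records: Sequence[InputRecord],
) -> tuple[list[InputRecord], list[tuple[InputRecord, str]]]:
    """Split records into viable (complete gold code) and rejected-with-reason."""
    viable: list[InputRecord] = []
    rejected: list[tuple[InputRecord, str]] = []
    for rec in records:
        if rec.gold is None:
            rejected.append((rec, "uncoded"))
        elif not is_complete(rec.gold):
            rejected.append((rec, "incomplete"))
        else:
            viable.append(rec)
    return viable, rejected


def split_dataset(
    records: Sequence[InputRecord],
    fractions: tuple[float, float, float] = (0.60, 0.30, 0.10),
    seed: int = 42,
) -> DatasetSplit:
    """Random train/test/validation partition with largest-remainder sizing."""
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise DataError(f"fractions must be three positive numbers, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DataError(f"fractions must sum to 1, got {fractions}")
    n = len(records)
    if n < len(fractions):
        raise DegenerateSplitError(f"{n} records cannot populate 3 partitions")
    exact = [n * f for f in fractions]
    sizes = [int(e) for e in exact]
    remainders = sorted(
        range(3), key=lambda i: (exact[i] - sizes[i], -i), reverse=True
    )
    for i in remainders[: n - sum(sizes)]:
        sizes[i] += 1
    if any(s == 0 for s in sizes):
        raise DegenerateSplitError(f"partition sizes {sizes} include an empty part")
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [records[i] for i in perm]
    train = shuffled[: sizes[0]]
    test = shuffled[sizes[0] : sizes[0] + sizes[1]]
    validation = shuffled[sizes[0] + sizes[1] :]
    return DatasetSplit(
        train=train, test=test, validation=validation,
        fractions=tuple(fractions), seed=seed,
    )


def augment_with_index(
    train: Sequence[InputRecord], index: Sequence[InputRecord]
) -> list[InputRecord]:
    """Append coding-index records (deduplicated by code + texts) to the
    training collection, flagged with ``origin='index'``."""
    out = list(train)
    seen: set[tuple] = set()
    for rec in index:
        if rec.gold is None:
            raise InvalidCodeError(f"index entry {rec.entry_id!r} carries no code")
        if not is_complete(rec.gold):
            raise InvalidCodeError(
                f"index entry {rec.entry_id!r} has incomplete code {rec.gold.canonical!r}"
            )
        key = (rec.gold.canonical, tuple(sorted(rec.texts.items())))
        if key in seen:
            continue
        seen.add(key)
        out.append(dataclasses.replace(rec, origin="index"))
    return out


def _labels_to_indices(records: Sequence[InputRecord], label_table: Sequence[str]) -> np.ndarray:
    index = {code: i for i, code in enumerate(label_table)}
    return np.array([index[rec.gold.canonical] for rec in records], dtype=np.int64)


def train_coder(
    split: DatasetSplit,
    params: HyperParams,
    embedder: Embedder,
    input_classes: Sequence[str],
    seed: int = 42,
) -> TrainedCoder:
    """Train the boosted-tree coder on the train partition with early stopping
    monitored on the validation partition (multiclass log-loss)."""
    train = split.train
    if not train:
        raise DataError("empty training partition")
    label_table = tuple(sorted({rec.gold.canonical for rec in train if rec.gold is not None}))
    if len(label_table) < 2:
        raise DegenerateModelError(
            f"training data has {len(label_table)} distinct code(s); need at least 2"
        )
    if any(rec.gold is None for rec in train):
        raise DataError("training records must all carry gold codes (run filter_viable)")
    scheme = train[0].gold.scheme

    X_train, _ = build_feature_matrix(train, embedder, input_classes)
    if not np.all(np.isfinite(X_train)):
        raise DataError("non-finite feature values in training matrix")
    y_train = _labels_to_indices(train, label_table)

    known = set(label_table)
    val_usable = [rec for rec in split.validation if rec.gold is not None and rec.gold.canonical in known]
    if split.validation and not val_usable:
        val_usable = []
    X_val = y_val = None
    if val_usable:
        X_val, _ = build_feature_matrix(val_usable, embedder, input_classes)
        y_val = _labels_to_indices(val_usable, label_table)

    def make_model(max_iter: int, warm_start: bool) -> HistGradientBoostingClassifier:
        return HistGradientBoostingClassifier(
            learning_rate=params.eta,
            max_depth=params.max_depth,
            max_leaf_nodes=None,  # depth-limited trees, as in the reference setting
            l2_regularization=params.lambda_,
            min_samples_leaf=1,
            max_iter=max_iter,
            warm_start=warm_start,
            early_stopping=False,
            random_state=seed,
        )

    all_classes = np.arange(len(label_table))
    if X_val is not None:
        model = make_model(max_iter=1, warm_start=True)
        best_loss = np.inf
        best_round = 0
        rounds_without_improvement = 0
        for rounds in range(1, params.max_rounds + 1):
            model.set_params(max_iter=rounds)
            model.fit(X_train, y_train)
            loss = log_loss(y_val, model.predict_proba(X_val), labels=all_classes)
            if loss < best_loss - 1e-12:
                best_loss = loss
                best_round = rounds
                rounds_without_improvement = 0
            else:
                rounds_without_improvement += 1
                if rounds_without_improvement >= params.early_stopping_rounds:
                    break
        # rewind to the best round with a fresh deterministic fit
        model = make_model(max_iter=best_round, warm_start=False)
        model.fit(X_train, y_train)
        n_rounds = best_round
        val_loss = float(best_loss)
    else:
        # no usable validation labels: train to the cap, no early stopping
        n_rounds = params.max_rounds
        model = make_model(max_iter=n_rounds, warm_start=False)
        model.fit(X_train, y_train)
        val_loss = float("nan")

    metadata = {
        "rounds": n_rounds,
        "seed": seed,
        "validation_log_loss": val_loss,
        "early_stopping_metric": "multiclass log-loss",
        "n_train": len(train),
        "n_train_index_origin": sum(1 for r in train if r.origin == "index"),
        "unmapped_hyperparams": list(HyperParams.UNMAPPED),
        "hyperparams": params.to_dict(),
        "backend": "sklearn.HistGradientBoostingClassifier",
    }
    return TrainedCoder(
        model=model,
        scheme=scheme,
        label_table=label_table,
        embedder=embedder,
        input_classes=tuple(input_classes),
        metadata=metadata,
    )


def _rank_probabilities(proba: np.ndarray, k: int) -> list[tuple[int, float]]:
    """Indices and probabilities of the top-k classes; ties broken by label index."""
    order = np.lexsort((np.arange(len(proba)), -proba))
    return [(int(i), float(proba[i])) for i in order[:k]]


def predict_suggestions(
    coder: TrainedCoder, records: Sequence[InputRecord], k: int = 10
) -> list[list[CodeSuggestion]]:
    """Ranked top-k suggestion lists for a batch of records."""
    if k < 1:
        raise DataError(f"k must be >= 1, got {k}")
    X, _ = build_feature_matrix(records, coder.embedder, coder.input_classes)
    proba = coder.model.predict_proba(X)
    k_eff = min(k, coder.n_classes)
    out: list[list[CodeSuggestion]] = []
    for row in proba:
        suggestions = [
            CodeSuggestion(
                code=parse_code(coder.scheme, coder.label_table[idx]),
                confidence=p,
                rank=rank,
            )
            for rank, (idx, p) in enumerate(_rank_probabilities(row, k_eff), start=1)
        ]
        out.append(suggestions)
    return out


def predict_topk(coder: TrainedCoder, record: InputRecord, k: int = 10) -> list[CodeSuggestion]:
    """Ranked top-k code suggestions for one record."""
    return predict_suggestions(coder, [record], k)[0]


def select_input_classes(
    records: Sequence[InputRecord],
    candidate_classes: Sequence[str],
    params: HyperParams,
    embedder: Embedder,
    fractions: tuple[float, float, float] = (0.60, 0.30, 0.10),
    seed: int = 42,
) -> tuple[tuple[str, ...], list[dict]]:
    """Exhaustive wrapper feature selection over input-class subsets.

    Trains one model per non-empty subset of ``candidate_classes`` on the
    same split and scores test accuracy. Returns the winning subset (ties:
    highest accuracy, then fewest classes, then lexicographic) and the full
    score table.
    """
    if not 1 <= len(candidate_classes) <= 6:
        raise ConfigurationError(
            f"{len(candidate_classes)} candidate classes; the exhaustive wrapper "
            "supports 1-6 (2^n - 1 models must stay tractable)"
        )
    viable, _ = filter_viable(records)
    split = split_dataset(viable, fractions=fractions, seed=seed)
    table: list[dict] = []
    for size in range(1, len(candidate_classes) + 1):
        for subset in itertools.combinations(sorted(candidate_classes), size):
            coder = train_coder(split, params, embedder, subset, seed=seed)
            suggestions = predict_suggestions(coder, split.test, k=1)
            correct = sum(
                1
                for rec, sugg in zip(split.test, suggestions)
                if rec.gold is not None and sugg[0].code.canonical == rec.gold.canonical
            )
            accuracy = 100.0 * correct / len(split.test)
            table.append(
                {"input_classes": subset, "test_accuracy": accuracy, "rounds": coder.metadata["rounds"]}
            )
    best_acc = max(row["test_accuracy"] for row in table)
    candidates = [row for row in table if row["test_accuracy"] == best_acc]
    candidates.sort(key=lambda row: (len(row["input_classes"]), row["input_classes"]))
    best = candidates[0]
    return tuple(best["input_classes"]), table


# ---------------------------------------------------------------------------
# Persistence

_ARTIFACT_VERSION = 1


def save_coder(coder: TrainedCoder, path: str) -> None:
    """Serialize a trained coder (model + label table + config) to one file."""
    joblib.dump({"version": _ARTIFACT_VERSION, "coder": coder, "config_hash": coder.config_hash()}, path)


def load_coder(path: str) -> TrainedCoder:
    """Load a coder saved by :func:`save_coder`."""
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("version") != _ARTIFACT_VERSION:
        raise DataError(f"{path}: not a recognized coder artifact")
    return payload["coder"]
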