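"""Shared fixtures: schemes, synthetic corpora and a trained benchmark coder.

Everything is generated programmatically at test time; the expensive
clean-corpus training is session-scoped.
"""

from __future__ import annotations

import dataclasses

import pytest

from occucode.coder import (
    HyperParams,
    augment_with_index,
    filter_viable,
    predict_suggestions,
    split_dataset,
    train_coder,
)
from occucode.schemes import builtin_scheme
from occucode.synthdata import CorpusSpec, generate_corpus, generate_scheme
from occucode.textprep import HashedBagOfStems


@pytest.fixture(scope="session")
def isco88():
    return builtin_scheme("isco88")


@pytest.fixture(scope="session")
def isco68():
    return builtin_scheme("isco68")


@pytest.fixture(scope="session")
def naf():
    return builtin_scheme("naf2008")


@pytest.fixture(scope="session")
def pcs():
    return builtin_scheme("pcs2003")


@pytest.fixture(scope="session")
def synth_scheme_and_codes():
    """Synthetic 3-level scheme with 5/10/20 outcome categories."""
    return generate_scheme([5, 10, 20], seed=1)


@dataclasses.dataclass
class Benchmark:
    """Clean separable corpus + trained coder + test-set suggestions."""

    scheme: object
    codes: list
    records: list
    index: list
    split: object
    embedder: HashedBagOfStems
    coder: object
    suggestions: list  # top-5 per test record
    gold: list  # aligned gold codes of the test partition


def _build_benchmark(seed: int = 1) -> Benchmark:
    scheme, codes = generate_scheme([5, 10, 20], seed=seed)
    spec = CorpusSpec(
        scheme=scheme,
        codes=codes,
        n_entries=1000,  # 20 codes x 50 examples
        vocab_per_code=1,
        target_median_words=2,
        noise_rate=0.0,
        seed=seed,
    )
    records, index = generate_corpus(spec)
    viable, _ = filter_viable(records)
    split = split_dataset(viable, seed=seed)
    split = split.replace_train(augment_with_index(split.train, index))
    embedder = HashedBagOfStems(dim=512, language="none")
    coder = train_coder(split, HyperParams(), embedder, spec.input_classes, seed=seed)
    suggestions = predict_suggestions(coder, split.test, k=5)
    return Benchmark(
        scheme=scheme,
        codes=codes,
        records=records,
        index=index,
        split=split,
        embedder=embedder,
        coder=coder,
        suggestions=suggestions,
        gold=[rec.gold for rec in split.test],
    )


@pytest.fixture(scope="session")
def benchmark():
    return _build_benchmark(seed=1)
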