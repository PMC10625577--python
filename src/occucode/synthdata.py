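"""Synthetic schemes, corpora, coding indexes and JEMs for desk-scale runs.

The generators emulate the statistical structure of real occupational data
without any of its content: very short descriptions (median 1-3 words),
power-law class imbalance down to singleton classes, placeholder-incomplete
gold codes, and exposure matrices in which only a small fraction of codes
carry non-zero exposure. Tokens are abstract (``w3c0t5``), so stemming is an
identity on them by construction.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from typing import Optional

import numpy as np

from .errors import ConfigurationError, DataError
from .jem import ContinuousJEM, ExposureIndices, OrdinalJEM
from .schemes import Code, LevelDef, SchemeSpec, parse_code
from .textprep import InputRecord

__all__ = [
    "CorpusSpec",
    "JemSpec",
    "DEFAULT_AGENTS",
    "generate_scheme",
    "generate_corpus",
    "generate_continuous_jem",
    "generate_ordinal_jem",
]

_ALPHABET = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: Default agent list for ordinal matrices: 12 generic industrial exposures.
DEFAULT_AGENTS = tuple(f"agent_{i:02d}" for i in range(1, 13))


def generate_scheme(
    n_level_sizes: Sequence[int], seed: int = 0, name: Optional[str] = None
) -> tuple[SchemeSpec, list[Code]]:
    """Build a prefix-structured scheme whose per-level outcome-category
    counts equal ``n_level_sizes``, and the full list of its deepest codes."""
    sizes = [int(s) for s in n_level_sizes]
    if not sizes or any(s < 1 for s in sizes):
        raise ConfigurationError(f"level sizes must be positive, got {sizes}")
    if any(b < a for a, b in zip(sizes, sizes[1:])):
        raise ConfigurationError(f"level sizes must be non-decreasing, got {sizes}")
    if sizes[0] > len(_ALPHABET):
        raise ConfigurationError(
            f"cannot create {sizes[0]} level-1 groups with one character"
        )
    rng = np.random.default_rng(seed)
    prefixes = [_ALPHABET[i] for i in range(sizes[0])]
    for parent_count, child_count in zip(sizes, sizes[1:]):
        base, extra = divmod(child_count, parent_count)
        if base + 1 > len(_ALPHABET) and extra:
            raise ConfigurationError(
                f"level growth {parent_count}->{child_count} exceeds the "
                f"per-position alphabet ({len(_ALPHABET)} characters)"
            )
        if base > len(_ALPHABET):
            raise ConfigurationError(
                f"level growth {parent_count}->{child_count} exceeds the "
                f"per-position alphabet ({len(_ALPHABET)} characters)"
            )
        # which parents receive an extra child is randomized but reproducible
        extras = set(rng.choice(parent_count, size=extra, replace=False).tolist())
        next_prefixes = []
        for i, parent in enumerate(prefixes):
            n_children = base + (1 if i in extras else 0)
            next_prefixes.extend(parent + _ALPHABET[j] for j in range(n_children))
        prefixes = next_prefixes
    scheme = SchemeSpec(
        name=name or f"synthetic-{'x'.join(map(str, sizes))}",
        levels=tuple(LevelDef(depth=d) for d in range(1, len(sizes) + 1)),
        separators=(),
        placeholder="#",
        alphabet=(_ALPHABET,) * len(sizes),
    )
    codes = [parse_code(scheme, p) for p in prefixes]
    return scheme, codes


@dataclasses.dataclass
class CorpusSpec:
    """Recipe for a synthetic job-description corpus."""

    scheme: SchemeSpec
    codes: Optional[Sequence[Code]] = None  # explicit code list; else sampled
    n_codes: int = 20
    n_entries: int = 1000
    input_classes: tuple[str, ...] = ("occupation", "sector")
    target_median_words: int = 2  # per input class
    vocab_per_code: int = 8
    n_noise_tokens: int = 50
    noise_rate: float = 0.0
    imbalance: float = 0.0  # power-law exponent for class sizes
    incomplete_rate: float = 0.0  # fraction of gold codes given placeholders
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_rate", "incomplete_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.codes is not None:
            self.codes = list(self.codes)
            self.n_codes = len(self.codes)
        if self.n_codes < 2:
            raise ConfigurationError("need at least 2 codes")
        if self.vocab_per_code < 1:
            raise ConfigurationError(
                "vocab_per_code must be >= 1; increase the per-code vocabulary"
            )
        if not self.input_classes:
            raise ConfigurationError("need at least one input class")
        if self.target_median_words < 1:
            raise ConfigurationError("target_median_words must be >= 1")
        if self.n_entries < self.n_codes:
            raise ConfigurationError(
                f"n_entries ({self.n_entries}) must be >= n_codes ({self.n_codes})"
            )


def _sample_codes(spec: CorpusSpec, rng: np.random.Generator) -> list[Code]:
    scheme = spec.scheme
    codes: set[str] = set()
    limit = spec.n_codes * 200
    attempts = 0
    while len(codes) < spec.n_codes:
        attempts += 1
        if attempts > limit:
            raise DataError(
                f"could not sample {spec.n_codes} distinct codes from scheme "
                f"{scheme.name!r}"
            )
        raw = "".join(
            scheme.alphabet[pos][rng.integers(len(scheme.alphabet[pos]))]
            for pos in range(scheme.code_length)
        )
        codes.add(raw)
    return [parse_code(scheme, raw) for raw in sorted(codes)]


def _class_sizes(spec: CorpusSpec, rng: np.random.Generator) -> np.ndarray:
    """Bounded power-law class sizes: each class gets at least one entry and
    the remainder is allocated by Zipf weights rank^(-imbalance)."""
    n_codes, n_entries = spec.n_codes, spec.n_entries
    if n_entries < n_codes:
        raise ConfigurationError(
            f"n_entries ({n_entries}) must be >= n_codes ({n_codes})"
        )
    sizes = np.ones(n_codes, dtype=np.int64)
    rest = n_entries - n_codes
    ranks = np.arange(1, n_codes + 1, dtype=np.float64)
    weights = ranks ** (-spec.imbalance)
    weights /= weights.sum()
    exact = rest * weights
    extra = np.floor(exact).astype(np.int64)
    remainder = rest - int(extra.sum())
    if remainder:
        order = np.argsort(-(exact - extra), kind="stable")
        extra[order[:remainder]] += 1
    return sizes + extra


def _word_count(spec: CorpusSpec, rng: np.random.Generator) -> int:
    return max(1, int(rng.poisson(spec.target_median_words)))


def generate_corpus(spec: CorpusSpec) -> tuple[list[InputRecord], list[InputRecord]]:
    """Generate (episode records, coding-index records) per the corpus spec.

    Each code owns a private vocabulary per input class; entry tokens are
    drawn from it, contaminated by shared noise tokens at ``noise_rate``. An
    ``incomplete_rate`` fraction of gold codes get placeholder suffixes. The
    coding index holds one clean canonical description per code.
    """
    rng = np.random.default_rng(spec.seed)
    codes = list(spec.codes) if spec.codes is not None else _sample_codes(spec, rng)
    scheme = spec.scheme
    vocab = {
        (ci, cls): [f"w{ci}c{k}t{t}" for t in range(spec.vocab_per_code)]
        for ci in range(len(codes))
        for k, cls in enumerate(spec.input_classes)
    }
    noise = [f"noise{j}" for j in range(max(1, spec.n_noise_tokens))]
    sizes = _class_sizes(spec, rng)

    records: list[InputRecord] = []
    entry_no = 0
    for ci, code in enumerate(codes):
        for _ in range(int(sizes[ci])):
            texts = {}
            for cls in spec.input_classes:
                words = []
                for _ in range(_word_count(spec, rng)):
                    if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
                        words.append(noise[rng.integers(len(noise))])
                    else:
                        pool = vocab[(ci, cls)]
                        words.append(pool[rng.integers(len(pool))])
                texts[cls] = " ".join(words)
            gold = code
            if spec.incomplete_rate > 0 and rng.random() < spec.incomplete_rate:
                # keep the prefix of a random non-deepest level
                cut_level = int(rng.integers(1, scheme.n_levels))
                depth = scheme.levels[cut_level - 1].depth
                gold = Code(
                    scheme=scheme,
                    significant=code.significant[:depth].ljust(
                        scheme.code_length, scheme.placeholder
                    ),
                )
            records.append(
                InputRecord(entry_id=f"e{entry_no:06d}", texts=texts, gold=gold)
            )
            entry_no += 1

    index: list[InputRecord] = []
    for ci, code in enumerate(codes):
        texts = {
            cls: " ".join(vocab[(ci, cls)][: min(3, spec.vocab_per_code)])
            for cls in spec.input_classes
        }
        index.append(
            InputRecord(entry_id=f"idx{ci:04d}", texts=texts, gold=code, origin="index")
        )
    return records, index


@dataclasses.dataclass
class JemSpec:
    """Recipe for a synthetic exposure matrix."""

    exposed_code_fraction: float = 0.10
    agents: tuple[str, ...] = DEFAULT_AGENTS
    probability_range: tuple[float, float] = (5.0, 100.0)
    intensity_range: tuple[float, float] = (0.1, 10.0)
    frequency_range: tuple[float, float] = (5.0, 100.0)
    #: ordinal protocol: chance an agent of an exposed code is non-zero,
    #: and chance a non-zero level is high (2) rather than low (1)
    agent_exposure_prob: float = 0.5
    high_level_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.exposed_code_fraction <= 1.0:
            raise ConfigurationError(
                f"exposed_code_fraction must be in [0, 1], got {self.exposed_code_fraction}"
            )


def generate_continuous_jem(spec: JemSpec, codes: Sequence[Code]) -> ContinuousJEM:
    """Continuous JEM: an ``exposed_code_fraction`` Bernoulli draw per code;
    exposed codes get indices uniform in the declared ranges, the rest zero."""
    rng = np.random.default_rng(spec.seed)
    jem = ContinuousJEM(name=f"synthetic-continuous-s{spec.seed}")
    for code in codes:
        if rng.random() < spec.exposed_code_fraction:
            idx = ExposureIndices(
                probability=float(rng.uniform(*spec.probability_range)),
                intensity=float(rng.uniform(*spec.intensity_range)),
                frequency=float(rng.uniform(*spec.frequency_range)),
            )
        else:
            idx = ExposureIndices(0.0, 0.0, 0.0)
        jem.add(code, idx)
    return jem


def generate_ordinal_jem(spec: JemSpec, codes: Sequence[Code]) -> OrdinalJEM:
    """Ordinal JEM: exposed codes get a 0/1/2 level per agent (at least one
    non-zero); unexposed codes are all-zero."""
    rng = np.random.default_rng(spec.seed)
    jem = OrdinalJEM(agents=spec.agents, name=f"synthetic-ordinal-s{spec.seed}")
    for code in codes:
        levels = {agent: 0 for agent in spec.agents}
        if rng.random() < spec.exposed_code_fraction:
            for agent in spec.agents:
                if rng.random() < spec.agent_exposure_prob:
                    levels[agent] = 2 if rng.random() < spec.high_level_prob else 1
            if all(v == 0 for v in levels.values()):
                forced = spec.agents[rng.integers(len(spec.agents))]
                levels[forced] = 1
        jem.add(code, levels)
    return jem
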