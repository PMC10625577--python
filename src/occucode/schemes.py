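"""Hierarchical occupational/activity classification schemes and codes.

A scheme describes codes as fixed-length strings of *significant* characters.
Each coding level is either a prefix of a given length or a lookup table that
maps a deeper prefix to a coarser category (used for section-style top levels).
Uncodable positions are marked with a placeholder character and codes may be
rendered with conventional separators (e.g. ``1-21.10``).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from importlib import resources
from typing import Optional, Union

import yaml

from .errors import ConfigurationError, InvalidCodeError, NotCodableAtLevelError

__all__ = [
    "LevelDef",
    "SchemeSpec",
    "Code",
    "parse_code",
    "truncate",
    "is_complete",
    "count_outcome_categories",
    "load_scheme",
    "scheme_from_dict",
    "builtin_scheme",
    "BUILTIN_SCHEMES",
]

BUILTIN_SCHEMES = ("naf2008", "pcs2003", "isco88", "isco68")


@dataclasses.dataclass(frozen=True)
class LevelDef:
    """One coding level: a prefix of ``depth`` significant characters.

    When ``table`` is given, the level's category label is ``table[prefix]``
    rather than the prefix itself (e.g. activity sections keyed on the
    two-digit division).
    """

    depth: int
    table: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigurationError(f"level depth must be >= 1, got {self.depth}")
        if self.table is not None and not self.table:
            raise ConfigurationError("level lookup table must not be empty")


@dataclasses.dataclass(frozen=True)
class SchemeSpec:
    """Definition of a hierarchical classification scheme."""

    name: str
    levels: tuple[LevelDef, ...]
    separators: tuple[tuple[int, str], ...] = ()
    placeholder: str = "#"
    alphabet: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.levels:
            raise ConfigurationError("scheme needs at least one level")
        if len(self.placeholder) != 1:
            raise ConfigurationError("placeholder must be a single character")
        # Prefix levels must deepen strictly; a lookup level may share the
        # depth of its key with a neighbouring prefix level.
        prev_prefix_depth = 0
        for lv in self.levels:
            if lv.table is None:
                if lv.depth <= prev_prefix_depth:
                    raise ConfigurationError(
                        f"{self.name}: level prefix depths must strictly increase"
                    )
                prev_prefix_depth = lv.depth
            else:
                if any(self.placeholder in key for key in lv.table):
                    raise ConfigurationError(
                        f"{self.name}: placeholder inside a lookup-table key"
                    )
        if self.levels[-1].table is not None:
            raise ConfigurationError(f"{self.name}: deepest level cannot be a lookup table")
        if len(self.alphabet) != self.code_length:
            raise ConfigurationError(
                f"{self.name}: alphabet must give allowed characters for each of "
                f"{self.code_length} positions"
            )
        for pos, char in self.separators:
            if not (1 <= pos < self.code_length):
                raise ConfigurationError(f"{self.name}: separator position {pos} out of range")
            if len(char) != 1:
                raise ConfigurationError("separator must be a single character")

    @property
    def code_length(self) -> int:
        """Number of significant characters of a full-depth code."""
        return self.levels[-1].depth

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def render(self, significant: str) -> str:
        """Render significant characters with separators, dropping the
        placeholder-padded tail."""
        end = len(significant)
        while end > 0 and significant[end - 1] == self.placeholder:
            end -= 1
        sep_at = dict(self.separators)
        out: list[str] = []
        for i in range(end):
            out.append(significant[i])
            if i + 1 < end and (i + 1) in sep_at:
                out.append(sep_at[i + 1])
        return "".join(out)


@dataclasses.dataclass(frozen=True)
class Code:
    """A (possibly incomplete) code within a scheme."""

    scheme: SchemeSpec
    significant: str

    def __post_init__(self) -> None:
        if len(self.significant) != self.scheme.code_length:
            raise InvalidCodeError(
                f"significant length {len(self.significant)} != scheme "
                f"code length {self.scheme.code_length}"
            )

    @property
    def canonical(self) -> str:
        return self.scheme.render(self.significant)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Code):
            return NotImplemented
        return self.scheme.name == other.scheme.name and self.significant == other.significant

    def __hash__(self) -> int:
        return hash((self.scheme.name, self.significant))

    def __str__(self) -> str:
        return self.canonical


def parse_code(scheme: SchemeSpec, raw: str) -> Code:
    """Parse a raw code string: validate characters, strip separators and
    right-pad shorter-than-full codes with placeholders."""
    text = raw.strip().upper()
    if not text:
        raise InvalidCodeError("empty code string")
    sep_at = dict(scheme.separators)
    significant: list[str] = []
    for ch in text:
        pos = len(significant)
        if pos in sep_at and ch == sep_at[pos]:
            continue  # expected separator, drop it
        if pos >= scheme.code_length:
            raise InvalidCodeError(
                f"{raw!r}: longer than the deepest level of scheme {scheme.name!r}"
            )
        if ch != scheme.placeholder and ch not in scheme.alphabet[pos]:
            raise InvalidCodeError(
                f"{raw!r}: character {ch!r} not allowed at position {pos + 1} "
                f"of scheme {scheme.name!r}"
            )
        significant.append(ch)
    padded = "".join(significant).ljust(scheme.code_length, scheme.placeholder)
    return Code(scheme=scheme, significant=padded)


def truncate(code: Code, level: int) -> str:
    """Category label of ``code`` at the 1-based coding ``level``."""
    scheme = code.scheme
    if not 1 <= level <= scheme.n_levels:
        raise ValueError(f"level must be in 1..{scheme.n_levels}, got {level}")
    lv = scheme.levels[level - 1]
    prefix = code.significant[: lv.depth]
    if scheme.placeholder in prefix:
        raise NotCodableAtLevelError(
            f"{code.canonical!r} is not codable at level {level} "
            f"(placeholder within the first {lv.depth} characters)"
        )
    if lv.table is not None:
        try:
            return lv.table[prefix]
        except KeyError:
            raise InvalidCodeError(
                f"prefix {prefix!r} missing from the level-{level} lookup table "
                f"of scheme {scheme.name!r}"
            ) from None
    return scheme.render(prefix)


def is_complete(code: Code) -> bool:
    """True iff the code has no placeholder positions."""
    return code.scheme.placeholder not in code.significant


def count_outcome_categories(codes: Iterable[Code], level: int) -> int:
    """Number of distinct category labels at ``level`` (the OC count)."""
    return len({truncate(c, level) for c in codes})


# ---------------------------------------------------------------------------
# Scheme configuration files


def _parse_alphabet(
    value: Union[str, Sequence[str]], code_length: int
) -> tuple[str, ...]:
    if isinstance(value, str):
        return (value,) * code_length
    alphabet = tuple(str(v) for v in value)
    return alphabet


def scheme_from_dict(data: Mapping[str, object]) -> SchemeSpec:
    """Build a SchemeSpec from a parsed configuration mapping."""
    known = {"name", "placeholder", "levels", "separators", "alphabet"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown scheme config keys: {sorted(unknown)}")
    try:
        raw_levels = data["levels"]
        name = str(data["name"])
    except KeyError as exc:
        raise ConfigurationError(f"scheme config missing key: {exc}") from None
    levels: list[LevelDef] = []
    for item in raw_levels:  # type: ignore[union-attr]
        if isinstance(item, Mapping):
            table = item.get("table")
            levels.append(
                LevelDef(
                    depth=int(item["depth"]),
                    table={str(k): str(v) for k, v in table.items()} if table else None,
                )
            )
        else:
            levels.append(LevelDef(depth=int(item)))
    code_length = levels[-1].depth if levels else 0
    separators = tuple(
        (int(pos), str(char)) for pos, char in data.get("separators", [])  # type: ignore[union-attr]
    )
    return SchemeSpec(
        name=name,
        levels=tuple(levels),
        separators=separators,
        placeholder=str(data.get("placeholder", "#")),
        alphabet=_parse_alphabet(data.get("alphabet", ""), code_length),
    )


def scheme_to_dict(spec: SchemeSpec) -> dict:
    """Inverse of :func:`scheme_from_dict`, for writing scheme config files."""
    levels: list[object] = []
    for lv in spec.levels:
        if lv.table is None:
            levels.append(lv.depth)
        else:
            levels.append({"depth": lv.depth, "table": dict(lv.table)})
    return {
        "name": spec.name,
        "placeholder": spec.placeholder,
        "alphabet": list(spec.alphabet),
        "separators": [[pos, char] for pos, char in spec.separators],
        "levels": levels,
    }


def load_scheme(path: str) -> SchemeSpec:
    """Load a scheme definition from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: scheme file must contain a mapping")
    return scheme_from_dict(data)


def builtin_scheme(name: str) -> SchemeSpec:
    """Load one of the shipped scheme definitions (see BUILTIN_SCHEMES)."""
    key = name.lower().replace("-", "").replace("_", "")
    if key not in BUILTIN_SCHEMES:
        raise ConfigurationError(
            f"unknown built-in scheme {name!r}; available: {list(BUILTIN_SCHEMES)}"
        )
    ref = resources.files("occucode.data").joinpath(f"{key}.yaml")
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return scheme_from_dict(data)
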