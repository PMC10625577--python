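"""Job-exposure matrices and exposure-assessment evaluation protocols.

Two JEM families are supported: continuous matrices keyed by an occupation
code (optionally with an activity-sector code and calendar period) carrying
probability/intensity/frequency indices whose product is the total exposure;
and ordinal matrices mapping an occupation code to a 0/1/2 exposure level per
agent. Evaluation compares JEM outputs under gold vs predicted codes, for all
individuals and for the subset exposed under the gold codes.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Sequence
from typing import Optional, Union

import pandas as pd
from scipy import stats

from .errors import DataError, MissingKeyError, UndefinedStatisticError
from .evaluation import accuracy as _accuracy
from .evaluation import cohens_kappa as _kappa
from .decision_support import ConfidenceBin, bin_outcomes
from .schemes import Code

__all__ = [
    "ExposureIndices",
    "ContinuousJEM",
    "OrdinalJEM",
    "JemEvalResult",
    "EXPOSED",
    "NOT_EXPOSED",
    "total_exposure",
    "dichotomize",
    "exposed_subset",
    "evaluate_continuous",
    "evaluate_ordinal",
    "kendall_tau",
    "read_continuous_jem",
    "read_ordinal_jem",
    "write_continuous_jem",
    "write_ordinal_jem",
]

EXPOSED = "exposed"
NOT_EXPOSED = "not_exposed"

ORDINAL_LEVELS = (0, 1, 2)


@dataclasses.dataclass(frozen=True)
class ExposureIndices:
    """Probability (% exposed workers), intensity (mean dose, arbitrary
    units) and frequency (% of working time) of exposure."""

    probability: float
    intensity: float
    frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 100.0:
            raise DataError(f"probability {self.probability} outside [0, 100]")
        if not 0.0 <= self.frequency <= 100.0:
            raise DataError(f"frequency {self.frequency} outside [0, 100]")
        if self.intensity < 0.0:
            raise DataError(f"intensity {self.intensity} must be >= 0")


ZERO_EXPOSURE = ExposureIndices(0.0, 0.0, 0.0)

CodeLike = Union[str, Code]
KeyLike = Union[CodeLike, tuple]


def _canon(code: CodeLike) -> str:
    return code.canonical if isinstance(code, Code) else str(code)


def _key(item: KeyLike) -> tuple[str, Optional[str]]:
    """Normalize a code or (occupation, sector) pair to a lookup key."""
    if isinstance(item, tuple):
        occ = _canon(item[0])
        sector = _canon(item[1]) if len(item) > 1 and item[1] is not None else None
        return occ, sector
    return _canon(item), None


class ContinuousJEM:
    """Exposure matrix with probability/intensity/frequency indices.

    Entries are keyed by occupation code, optional sector code, and optional
    calendar period (inclusive year range). Lookups for absent keys return
    zero exposure and increment ``unmatched_count`` under the default
    ``"zero"`` policy; the ``"strict"`` policy raises instead.
    """

    def __init__(self, name: str = "continuous-jem"):
        self.name = name
        self._entries: dict[
            tuple[str, Optional[str], Optional[tuple[int, int]]], ExposureIndices
        ] = {}
        self.unmatched_count = 0
        self.matched_count = 0

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def has_periods(self) -> bool:
        return any(period is not None for _, _, period in self._entries)

    def reset_counters(self) -> None:
        self.unmatched_count = 0
        self.matched_count = 0

    def add(
        self,
        occupation: CodeLike,
        indices: ExposureIndices,
        sector: Optional[CodeLike] = None,
        period: Optional[tuple[int, int]] = None,
    ) -> None:
        key = (_canon(occupation), _canon(sector) if sector is not None else None, period)
        if key in self._entries:
            raise DataError(f"{self.name}: duplicate entry for key {key}")
        self._entries[key] = indices

    def lookup(
        self,
        occupation: KeyLike,
        sector: Optional[CodeLike] = None,
        period: Optional[int] = None,
        policy: str = "zero",
    ) -> ExposureIndices:
        occ, sec = _key(occupation) if sector is None else (_canon(occupation), _canon(sector))
        if period is not None and not self.has_periods:
            warnings.warn(
                f"{self.name}: period {period} given but the matrix is period-less; ignored",
                stacklevel=2,
            )
            period = None
        if period is None:
            hit = self._entries.get((occ, sec, None))
            if hit is None:
                # single-period default: a matrix with exactly one period band
                # per key still resolves without an explicit period
                candidates = [
                    idx for (o, s, p), idx in self._entries.items() if o == occ and s == sec
                ]
                hit = candidates[0] if len(candidates) == 1 else None
        else:
            hit = None
            for (o, s, p), idx in self._entries.items():
                if o == occ and s == sec and p is not None and p[0] <= period <= p[1]:
                    hit = idx
                    break
        if hit is None:
            if policy == "strict":
                raise MissingKeyError(f"{self.name}: no entry for ({occ}, {sec}, {period})")
            self.unmatched_count += 1
            return ZERO_EXPOSURE
        self.matched_count += 1
        return hit


class OrdinalJEM:
    """Exposure matrix assigning each occupation code a 0/1/2 level per agent."""

    def __init__(self, agents: Sequence[str], name: str = "ordinal-jem"):
        if not agents:
            raise DataError("ordinal JEM needs a non-empty agent list")
        self.agents = tuple(agents)
        self.name = name
        self._entries: dict[str, dict[str, int]] = {}
        self.unmatched_count = 0
        self.matched_count = 0

    def __len__(self) -> int:
        return len(self._entries)

    def reset_counters(self) -> None:
        self.unmatched_count = 0
        self.matched_count = 0

    def add(self, occupation: CodeLike, levels: dict[str, int]) -> None:
        occ = _canon(occupation)
        if occ in self._entries:
            raise DataError(f"{self.name}: duplicate entry for {occ!r}")
        if set(levels) != set(self.agents):
            raise DataError(
                f"{self.name}: entry for {occ!r} must cover exactly the agents "
                f"{list(self.agents)}"
            )
        for agent, level in levels.items():
            if level not in ORDINAL_LEVELS:
                raise DataError(
                    f"{self.name}: level {level!r} for agent {agent!r} not in 0/1/2"
                )
        self._entries[occ] = {agent: int(levels[agent]) for agent in self.agents}

    def lookup(self, occupation: KeyLike, policy: str = "zero") -> dict[str, int]:
        occ, _ = _key(occupation)
        hit = self._entries.get(occ)
        if hit is None:
            if policy == "strict":
                raise MissingKeyError(f"{self.name}: no entry for {occ!r}")
            self.unmatched_count += 1
            return {agent: 0 for agent in self.agents}
        self.matched_count += 1
        return dict(hit)


@dataclasses.dataclass
class JemEvalResult:
    """Exposure-assessment evaluation report (continuous or ordinal protocol)."""

    n_all: int
    n_exposed: int
    accuracy_all: float
    kappa_all: float
    accuracy_exposed: Optional[float] = None
    kappa_exposed: Optional[float] = None
    # continuous protocol
    dichotomous_accuracy_all: Optional[float] = None
    dichotomous_kappa_all: Optional[float] = None
    dichotomous_accuracy_exposed: Optional[float] = None
    dichotomous_kappa_exposed: Optional[float] = None
    kendall_tau: Optional[float] = None
    kendall_p: Optional[float] = None
    # ordinal protocol
    per_agent_accuracy: Optional[dict[str, float]] = None
    per_agent_kappa: Optional[dict[str, float]] = None
    per_level_accuracy: Optional[dict[str, dict[int, Optional[float]]]] = None
    per_agent_accuracy_exposed: Optional[dict[str, float]] = None
    # confidence binning
    confidence_bins_all: Optional[list[ConfidenceBin]] = None
    confidence_bins_exposed: Optional[list[ConfidenceBin]] = None
    unmatched_lookups: int = 0


def total_exposure(idx: ExposureIndices) -> float:
    """Product of the three indices, probability and frequency as proportions."""
    return (idx.probability / 100.0) * idx.intensity * (idx.frequency / 100.0)


def dichotomize(total: float) -> str:
    """Exposed iff the total exposure is strictly greater than zero."""
    if total < 0:
        raise DataError(f"total exposure must be >= 0, got {total}")
    return EXPOSED if total > 0 else NOT_EXPOSED


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Kendall rank correlation (tau-b) with a two-sided
    normal-approximation p-value."""
    if len(x) != len(y):
        raise DataError("kendall_tau inputs misaligned")
    if len(x) < 2:
        raise DataError("kendall_tau needs at least 2 observations")
    if len(set(x)) < 2 or len(set(y)) < 2:
        raise UndefinedStatisticError("tau undefined for all-constant input")
    if len(x) == 2:
        # scipy's tie-corrected normal approximation needs n >= 3; with two
        # distinct pairs tau is exactly +-1 and no p-value is meaningful
        sx = (x[1] > x[0]) - (x[1] < x[0])
        sy = (y[1] > y[0]) - (y[1] < y[0])
        return float(sx * sy), math.nan
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _gold_totals(gold: Sequence[KeyLike], jem: ContinuousJEM, policy: str) -> list[float]:
    return [total_exposure(jem.lookup(g, policy=policy)) for g in gold]


def exposed_subset(
    records: Sequence, jem: Union[ContinuousJEM, OrdinalJEM], policy: str = "zero"
) -> list:
    """Subset of items whose gold-derived exposure is non-zero.

    Items may be InputRecords (their ``gold`` code is used), codes, or
    (occupation, sector) pairs.
    """
    out = []
    for item in records:
        key = getattr(item, "gold", item)
        if key is None:
            continue
        if isinstance(jem, ContinuousJEM):
            exposed = total_exposure(jem.lookup(key, policy=policy)) > 0
        else:
            exposed = any(level > 0 for level in jem.lookup(key, policy=policy).values())
        if exposed:
            out.append(item)
    return out


def _min_confidence(conf) -> float:
    if isinstance(conf, (tuple, list)):
        return float(min(conf))
    return float(conf)


def evaluate_continuous(
    gold_codes: Sequence[KeyLike],
    pred_codes: Sequence[KeyLike],
    jem: ContinuousJEM,
    confidences: Optional[Sequence] = None,
    policy: str = "zero",
) -> JemEvalResult:
    """Continuous-JEM protocol: exact-match accuracy and kappa on total
    exposure, the dichotomized variants, Kendall's tau-b over totals, and
    exposed-only versions (exposed under the gold codes).

    ``confidences`` may give one value per record or a pair per record (the
    minimum of the pair is used for binning, matching paired occupation +
    sector coding).
    """
    if len(gold_codes) != len(pred_codes):
        raise DataError("gold and predicted code lists misaligned")
    if confidences is not None and len(confidences) != len(gold_codes):
        raise DataError("confidences misaligned with code lists")
    jem.reset_counters()
    gold_tot = _gold_totals(gold_codes, jem, policy)
    pred_tot = _gold_totals(pred_codes, jem, policy)
    unmatched = jem.unmatched_count

    gold_cat = [repr(t) for t in gold_tot]
    pred_cat = [repr(t) for t in pred_tot]
    gold_dich = [dichotomize(t) for t in gold_tot]
    pred_dich = [dichotomize(t) for t in pred_tot]

    try:
        tau, tau_p = kendall_tau(gold_tot, pred_tot)
    except UndefinedStatisticError:
        tau, tau_p = math.nan, math.nan

    exposed_idx = [i for i, t in enumerate(gold_tot) if t > 0]
    result = JemEvalResult(
        n_all=len(gold_tot),
        n_exposed=len(exposed_idx),
        accuracy_all=_accuracy(pred_cat, gold_cat),
        kappa_all=_kappa(pred_cat, gold_cat),
        dichotomous_accuracy_all=_accuracy(pred_dich, gold_dich),
        dichotomous_kappa_all=_kappa(pred_dich, gold_dich),
        kendall_tau=tau,
        kendall_p=tau_p,
        unmatched_lookups=unmatched,
    )
    if exposed_idx:
        pe = [pred_cat[i] for i in exposed_idx]
        ge = [gold_cat[i] for i in exposed_idx]
        result.accuracy_exposed = _accuracy(pe, ge)
        result.kappa_exposed = _kappa(pe, ge)
        pde = [pred_dich[i] for i in exposed_idx]
        gde = [gold_dich[i] for i in exposed_idx]
        result.dichotomous_accuracy_exposed = _accuracy(pde, gde)
        result.dichotomous_kappa_exposed = _kappa(pde, gde)
    if confidences is not None:
        confs = [_min_confidence(c) for c in confidences]
        correct = [p == g for p, g in zip(pred_cat, gold_cat)]
        result.confidence_bins_all = bin_outcomes(confs, correct)
        if exposed_idx:
            result.confidence_bins_exposed = bin_outcomes(
                [confs[i] for i in exposed_idx], [correct[i] for i in exposed_idx]
            )
    return result


def evaluate_ordinal(
    gold_codes: Sequence[KeyLike],
    pred_codes: Sequence[KeyLike],
    jem: OrdinalJEM,
    confidences: Optional[Sequence] = None,
    policy: str = "zero",
) -> JemEvalResult:
    """Ordinal-JEM protocol: an episode counts as correct only when every
    agent's level matches the gold standard; per-agent accuracy/kappa and
    per-level accuracy are reported alongside, plus exposed-only versions
    (any gold agent level > 0)."""
    if len(gold_codes) != len(pred_codes):
        raise DataError("gold and predicted code lists misaligned")
    if confidences is not None and len(confidences) != len(gold_codes):
        raise DataError("confidences misaligned with code lists")
    jem.reset_counters()
    gold_profiles = [jem.lookup(g, policy=policy) for g in gold_codes]
    pred_profiles = [jem.lookup(p, policy=policy) for p in pred_codes]
    unmatched = jem.unmatched_count

    def profile_label(profile: dict[str, int]) -> str:
        return "".join(str(profile[a]) for a in jem.agents)

    gold_lab = [profile_label(p) for p in gold_profiles]
    pred_lab = [profile_label(p) for p in pred_profiles]

    def per_agent(indices: Sequence[int]) -> tuple[dict[str, float], dict[str, float]]:
        acc, kap = {}, {}
        for agent in jem.agents:
            g = [str(gold_profiles[i][agent]) for i in indices]
            p = [str(pred_profiles[i][agent]) for i in indices]
            acc[agent] = _accuracy(p, g)
            kap[agent] = _kappa(p, g)
        return acc, kap

    all_idx = list(range(len(gold_lab)))
    agent_acc, agent_kappa = per_agent(all_idx)

    per_level: dict[str, dict[int, Optional[float]]] = {}
    for agent in jem.agents:
        per_level[agent] = {}
        for level in ORDINAL_LEVELS:
            idx = [i for i in all_idx if gold_profiles[i][agent] == level]
            per_level[agent][level] = (
                100.0 * sum(1 for i in idx if pred_profiles[i][agent] == level) / len(idx)
                if idx
                else None
            )

    exposed_idx = [
        i for i in all_idx if any(level > 0 for level in gold_profiles[i].values())
    ]
    result = JemEvalResult(
        n_all=len(gold_lab),
        n_exposed=len(exposed_idx),
        accuracy_all=_accuracy(pred_lab, gold_lab),
        kappa_all=_kappa(pred_lab, gold_lab),
        per_agent_accuracy=agent_acc,
        per_agent_kappa=agent_kappa,
        per_level_accuracy=per_level,
        unmatched_lookups=unmatched,
    )
    if exposed_idx:
        pe = [pred_lab[i] for i in exposed_idx]
        ge = [gold_lab[i] for i in exposed_idx]
        result.accuracy_exposed = _accuracy(pe, ge)
        result.kappa_exposed = _kappa(pe, ge)
        result.per_agent_accuracy_exposed = per_agent(exposed_idx)[0]
    if confidences is not None:
        confs = [_min_confidence(c) for c in confidences]
        correct = [p == g for p, g in zip(pred_lab, gold_lab)]
        result.confidence_bins_all = bin_outcomes(confs, correct)
        if exposed_idx:
            result.confidence_bins_exposed = bin_outcomes(
                [confs[i] for i in exposed_idx], [correct[i] for i in exposed_idx]
            )
    return result


# ---------------------------------------------------------------------------
# CSV interchange


def read_continuous_jem(path: str, name: Optional[str] = None) -> ContinuousJEM:
    """Read a continuous JEM from CSV (columns: occupation_code, optional
    sector_code, optional period_start/period_end, probability, intensity,
    frequency)."""
    df = pd.read_csv(path, dtype={"occupation_code": str, "sector_code": str})
    required = {"occupation_code", "probability", "intensity", "frequency"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    jem = ContinuousJEM(name=name or path)
    for row in df.to_dict(orient="records"):
        sector = row.get("sector_code")
        if sector is not None and (pd.isna(sector) or str(sector) == ""):
            sector = None
        period = None
        if "period_start" in row and not pd.isna(row["period_start"]):
            period = (int(row["period_start"]), int(row["period_end"]))
        jem.add(
            str(row["occupation_code"]),
            ExposureIndices(
                probability=float(row["probability"]),
                intensity=float(row["intensity"]),
                frequency=float(row["frequency"]),
            ),
            sector=sector,
            period=period,
        )
    return jem


def write_continuous_jem(jem: ContinuousJEM, path: str) -> None:
    rows = []
    for (occ, sector, period), idx in jem._entries.items():
        rows.append(
            {
                "occupation_code": occ,
                "sector_code": sector if sector is not None else "",
                "period_start": period[0] if period else "",
                "period_end": period[1] if period else "",
                "probability": idx.probability,
                "intensity": idx.intensity,
                "frequency": idx.frequency,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ordinal_jem(path: str, name: Optional[str] = None) -> OrdinalJEM:
    """Read an ordinal JEM from CSV (occupation_code plus one column per agent)."""
    df = pd.read_csv(path, dtype={"occupation_code": str})
    if "occupation_code" not in df.columns:
        raise DataError(f"{path}: missing column 'occupation_code'")
    agents = [c for c in df.columns if c != "occupation_code"]
    jem = OrdinalJEM(agents=agents, name=name or path)
    for row in df.to_dict(orient="records"):
        jem.add(
            str(row["occupation_code"]),
            {agent: int(row[agent]) for agent in agents},
        )
    return jem


def write_ordinal_jem(jem: OrdinalJEM, path: str) -> None:
    rows = [
        {"occupation_code": occ, **levels} for occ, levels in jem._entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
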