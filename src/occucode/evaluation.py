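"""Agreement metrics and the human-vs-model statistical comparison.

Accuracy is the percentage of exact label matches; inter-coder reliability is
Cohen's kappa, (Po - Pe) / (1 - Pe), with Pe the chance agreement from the
two coders' marginal label distributions. Per-level metrics truncate both
code lists to each coding level of the scheme.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from collections.abc import Mapping, Sequence
from typing import Optional, Union

import numpy as np
from scipy import stats

from .errors import DataError, InsufficientDataError
from .schemes import Code, SchemeSpec, count_outcome_categories, truncate

__all__ = [
    "LevelMetrics",
    "ComparisonResult",
    "accuracy",
    "cohens_kappa",
    "per_level_metrics",
    "per_group_accuracy",
    "compare_groups",
    "compare_humans_model",
]

Label = Union[str, Code]


def _as_labels(values: Sequence[Label]) -> list[str]:
    return [v.canonical if isinstance(v, Code) else str(v) for v in values]


def _check_aligned(predicted: Sequence, gold: Sequence) -> None:
    if len(predicted) != len(gold):
        raise DataError(
            f"predicted ({len(predicted)}) and gold ({len(gold)}) lists misaligned"
        )
    if len(predicted) == 0:
        raise DataError("cannot evaluate empty lists")


@dataclasses.dataclass(frozen=True)
class LevelMetrics:
    """Agreement at one coding level."""

    level: int
    outcome_categories: int
    accuracy: float  # percent
    kappa: float
    n: int


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    """Two-sample comparison of human vs model kappas at one level."""

    n_human: int
    n_model: int
    mean_human: float
    mean_model: float
    range_human: tuple[float, float]
    range_model: tuple[float, float]
    sd_human: float  # sample SD (n-1)
    sd_model: float
    shapiro_p_human: float
    shapiro_p_model: float
    levene_p: float
    t: float
    df: float
    p: float
    hedges_g: float
    alpha: float = 0.05
    welch_used: bool = False


def accuracy(predicted: Sequence[Label], gold: Sequence[Label]) -> float:
    """Percent of exact matches between aligned label lists."""
    _check_aligned(predicted, gold)
    pred = _as_labels(predicted)
    true = _as_labels(gold)
    matches = sum(1 for p, g in zip(pred, true) if p == g)
    return 100.0 * matches / len(pred)


def cohens_kappa(predicted: Sequence[Label], gold: Sequence[Label]) -> float:
    """Chance-corrected agreement (Po - Pe) / (1 - Pe).

    Pe sums, over labels, the product of the two coders' marginal
    proportions. The degenerate case where both coders always assign the
    same single label (Po = Pe = 1) returns 1.0.
    """
    _check_aligned(predicted, gold)
    pred = _as_labels(predicted)
    true = _as_labels(gold)
    n = len(pred)
    po = sum(1 for p, g in zip(pred, true) if p == g) / n
    pred_marginals = Counter(pred)
    true_marginals = Counter(true)
    pe = sum(
        (pred_marginals[label] / n) * (true_marginals[label] / n)
        for label in pred_marginals
    )
    if pe >= 1.0 - 1e-15:
        return 1.0
    return (po - pe) / (1.0 - pe)


def per_level_metrics(
    predicted: Sequence[Code], gold: Sequence[Code], scheme: SchemeSpec
) -> list[LevelMetrics]:
    """Accuracy, kappa and outcome-category count at every coding level."""
    _check_aligned(predicted, gold)
    out = []
    for level in range(1, scheme.n_levels + 1):
        pred_lab = [truncate(c, level) for c in predicted]
        gold_lab = [truncate(c, level) for c in gold]
        out.append(
            LevelMetrics(
                level=level,
                outcome_categories=count_outcome_categories(gold, level),
                accuracy=accuracy(pred_lab, gold_lab),
                kappa=cohens_kappa(pred_lab, gold_lab),
                n=len(pred_lab),
            )
        )
    return out


def per_group_accuracy(
    predicted: Sequence[Code], gold: Sequence[Code], scheme: SchemeSpec
) -> dict[str, float]:
    """Full-code accuracy within each level-1 (major) group of the gold codes."""
    _check_aligned(predicted, gold)
    groups: dict[str, list[tuple[str, str]]] = {}
    for p, g in zip(predicted, gold):
        groups.setdefault(truncate(g, 1), []).append((p.canonical, g.canonical))
    return {
        group: 100.0 * sum(1 for p, g in pairs if p == g) / len(pairs)
        for group, pairs in sorted(groups.items())
    }


def _welch_df(s1: float, s2: float, n1: int, n2: int) -> float:
    v1, v2 = s1**2 / n1, s2**2 / n2
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def compare_groups(
    human: Sequence[float], model: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Independent two-sample comparison of kappa values.

    Normality is screened per group (Shapiro-Wilk) and equality of variances
    with Levene's test (mean-centred). The pooled t-test (df = n1 + n2 - 2)
    is used when Levene's p >= alpha; Welch's correction otherwise. Effect
    size is Hedges g (pooled SD, small-sample correction factor
    1 - 3 / (4(n1 + n2) - 9)); positive g means the model scores higher.
    """
    h = np.asarray(human, dtype=float)
    m = np.asarray(model, dtype=float)
    n1, n2 = len(h), len(m)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(
            f"need at least 2 values per group, got {n1} and {n2}"
        )
    sd_h = float(np.std(h, ddof=1))
    sd_m = float(np.std(m, ddof=1))
    shapiro_h = float(stats.shapiro(h).pvalue) if n1 >= 3 else math.nan
    shapiro_m = float(stats.shapiro(m).pvalue) if n2 >= 3 else math.nan
    levene_p = float(stats.levene(h, m, center="mean").pvalue)
    welch = levene_p < alpha
    if welch:
        t_res = stats.ttest_ind(m, h, equal_var=False)
        df = _welch_df(sd_m, sd_h, n2, n1)
    else:
        t_res = stats.ttest_ind(m, h, equal_var=True)
        df = float(n1 + n2 - 2)
    pooled_sd = math.sqrt(
        ((n1 - 1) * sd_h**2 + (n2 - 1) * sd_m**2) / (n1 + n2 - 2)
    )
    correction = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    hedges_g = (
        correction * (float(np.mean(m)) - float(np.mean(h))) / pooled_sd
        if pooled_sd > 0
        else math.nan
    )
    return ComparisonResult(
        n_human=n1,
        n_model=n2,
        mean_human=float(np.mean(h)),
        mean_model=float(np.mean(m)),
        range_human=(float(np.min(h)), float(np.max(h))),
        range_model=(float(np.min(m)), float(np.max(m))),
        sd_human=sd_h,
        sd_model=sd_m,
        shapiro_p_human=shapiro_h,
        shapiro_p_model=shapiro_m,
        levene_p=levene_p,
        t=float(t_res.statistic),
        df=df,
        p=float(t_res.pvalue),
        hedges_g=hedges_g,
        alpha=alpha,
        welch_used=welch,
    )


def compare_humans_model(
    human_kappas: Mapping[int, Sequence[float]],
    model_kappas: Mapping[int, Sequence[float]],
    alpha: float = 0.05,
) -> dict[int, ComparisonResult]:
    """Per-level human-vs-model comparison over matching coding levels."""
    levels = sorted(set(human_kappas) & set(model_kappas))
    if not levels:
        raise DataError("no common coding levels between the two groups")
    return {
        level: compare_groups(human_kappas[level], model_kappas[level], alpha=alpha)
        for level in levels
    }
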