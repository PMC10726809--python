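"""Cohort aggregation and the study's statistical toolkit.

A cohort is a tidy table with columns ``animal_id, tissue, group, metric,
value`` — one row per measured object and metric. Two units of analysis are
supported and must be chosen explicitly by the caller: per-animal means
(each animal contributes one value, the convention for whole-cohort 3D
morphometry figures) or per-mitochondrion pooling (each object is a dot,
the convention for in-vitro knockout panels). The two give very different
degrees of freedom, so there is deliberately no silent default.

Tests provided:

* unpaired two-sample *t* (pooled variance by default — the classic Student
  form that Fisher's protected LSD machinery assumes; Welch behind a flag);
* exact Mann-Whitney for small samples (full enumeration of group
  assignments, tie-safe), normal approximation with tie correction
  otherwise;
* one-way ANOVA with Fisher's protected LSD pairwise comparisons;
* the star convention: p <= 0.05 / 0.01 / 0.001 / 0.0001 mapping to
  * / ** / *** / **** (inclusive thresholds).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DomainError, ValidationError

__all__ = [
    "TestResult",
    "COHORT_COLUMNS",
    "validate_cohort",
    "aggregate_per_animal",
    "compare_two",
    "anova_lsd",
    "stars",
    "histogram_percent",
    "round_percent_display",
    "mitotype_order",
]

COHORT_COLUMNS = ("animal_id", "tissue", "group", "metric", "value")

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test: str
    n_per_group: tuple[int, ...]
    stars: str


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns {missing}")
    if not np.isfinite(table["value"]).all():
        raise ValidationError("cohort table contains non-finite values")
    return table


def aggregate_per_animal(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """One arithmetic mean per (animal, group) for the chosen metric."""
    validate_cohort(table)
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValidationError(f"metric {metric!r} absent from cohort table")
    out = (
        sub.groupby(["animal_id", "group"], sort=True)["value"]
        .mean()
        .reset_index()
        .rename(columns={"value": "mean_value"})
    )
    absent = set(table["animal_id"]) - set(out["animal_id"])
    if absent:
        warnings.warn(f"animals with no {metric!r} records excluded: {sorted(absent)}")
    return out


# ---------------------------------------------------------------------------
# two-group tests


def _mann_whitney_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by full enumeration of assignments.

    Tie-safe: the U statistic counts 0.5 per tied cross-pair. Enumerates all
    C(n1+n2, n1) splits of the combined sample, so only suitable for small n.
    """
    combined = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0

    def u_stat(g1: np.ndarray, g2: np.ndarray) -> float:
        diff = g1[:, None] - g2[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    u_obs = u_stat(x, y)
    dev_obs = abs(u_obs - mu)
    idx = np.arange(n1 + n2)
    count = 0
    total = 0
    for pick in combinations(idx, n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(pick)] = True
        u = u_stat(combined[mask], combined[~mask])
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
    return u_obs, count / total


def compare_two(
    group_a,
    group_b,
    test: str = "t_unpaired",
    welch: bool = False,
    exact_threshold: int = 12,
) -> TestResult:
    """Compare two independent samples with the study's two-group tests."""
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if test == "t_unpaired":
        if len(x) < 2 or len(y) < 2:
            raise ValidationError("t test needs n >= 2 per group")
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            if x[0] == y[0]:
                stat, p = 0.0, 1.0
            else:
                raise DegenerateDataError(
                    "zero variance in both groups with unequal means: "
                    "t statistic undefined"
                )
        else:
            stat, p = stats.ttest_ind(x, y, equal_var=not welch)
        name = "welch_t" if welch else "t_unpaired"
        return TestResult(float(stat), float(p), name, (len(x), len(y)), stars(float(p)))
    if test == "mann_whitney":
        if len(x) < 1 or len(y) < 1:
            raise ValidationError("Mann-Whitney needs n >= 1 per group")
        if len(x) + len(y) <= exact_threshold:
            stat, p = _mann_whitney_exact(x, y)
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
        return TestResult(float(stat), float(p), "mann_whitney", (len(x), len(y)), stars(float(p)))
    raise ValidationError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# k-group tests


@dataclass
class AnovaLsdResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    pairwise_p: pd.DataFrame
    protected: bool  # omnibus p <= 0.05: pairwise p values are interpretable


def anova_lsd(groups: list, alpha: float = 0.05) -> AnovaLsdResult:
    """One-way ANOVA with Fisher's protected LSD pairwise tests.

    Pairwise p-values come from t statistics built on the pooled within-group
    mean square and its degrees of freedom. Under Fisher's protection rule
    they are only interpreted when the omnibus p <= alpha; all pairwise p are
    emitted regardless, with ``protected`` flagging whether the gate passed.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValidationError("need at least two groups")
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValidationError(f"group {i} has n={len(g)} < 2")
    n_total = sum(len(g) for g in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b, df_w = k - 1, n_total - k
    msw = ss_within / df_w
    if msw == 0:
        f = 0.0 if ss_between == 0 else math.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f = (ss_between / df_b) / msw
        p = float(stats.f.sf(f, df_b, df_w))
    pw = np.full((k, k), np.nan)
    for i in range(k):
        pw[i, i] = 1.0
    for i, j in combinations(range(k), 2):
        gi, gj = arrays[i], arrays[j]
        if msw == 0:
            pij = 1.0 if gi.mean() == gj.mean() else 0.0
        else:
            t = (gi.mean() - gj.mean()) / math.sqrt(msw * (1 / len(gi) + 1 / len(gj)))
            pij = float(2 * stats.t.sf(abs(t), df_w))
        pw[i, j] = pw[j, i] = pij
    pairwise = pd.DataFrame(pw, index=range(k), columns=range(k))
    return AnovaLsdResult(float(f), p, df_b, df_w, pairwise, protected=p <= alpha)


def stars(p: float) -> str:
    """Map a p-value to the figure-caption star convention (inclusive <=)."""
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"p must be in [0, 1], got {p}")
    for threshold, mark in STAR_THRESHOLDS:
        if p <= threshold:
            return mark
    return "ns"


# ---------------------------------------------------------------------------
# distributions and mito-otyping


def histogram_percent(values, bin_edges) -> np.ndarray:
    """Percent-of-total histogram; bins half-open [lo, hi), last bin closed.

    Returns exact float percentages summing to 100; use
    :func:`round_percent_display` for display rounding that preserves the sum.
    """
    values = np.asarray(values, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if values.size == 0:
        raise ValidationError("histogram needs at least one value")
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValidationError("bin edges must be strictly increasing with >= 2 entries")
    counts, _ = np.histogram(values, bins=edges)
    return counts / counts.sum() * 100.0 if counts.sum() else counts.astype(float)


def round_percent_display(percentages, decimals: int = 0) -> np.ndarray:
    """Largest-remainder rounding so displayed percentages sum to exactly 100."""
    p = np.asarray(percentages, dtype=float)
    scale = 10**decimals
    scaled = p * scale
    floors = np.floor(scaled)
    shortfall = int(round(100 * scale - floors.sum()))
    order = np.argsort(-(scaled - floors), kind="stable")
    floors[order[:shortfall]] += 1
    return floors / scale


def mitotype_order(records, columns: int) -> list[tuple[int, int, int]]:
    """Karyotype-like montage layout: objects sorted ascending by volume.

    Returns ``(object_id, row, col)`` triples in placement order; ties in
    volume break by ascending object id, so the layout is deterministic and
    invariant to input shuffling.
    """
    recs = list(records)
    if not recs:
        raise ValidationError("mito-otyping needs at least one record")
    if columns < 1:
        raise ValidationError("grid width must be >= 1")
    ordered = sorted(recs, key=lambda r: (r.volume_um3, r.object_id))
    return [
        (r.object_id, i // columns, i % columns) for i, r in enumerate(ordered)
    ]
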