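"""Lipidomics differential abundance and lipid-set enrichment.

Pipeline, mirroring standard practice for shotgun lipidomics class-level
analysis:

1. **Name parsing** — species follow the ``"CLS xx:x/yy:y"`` scheme: an
   abbreviated class code (PC, TG, Cer, CAR, ...) then one or more
   ``carbons:double-bonds`` acyl chains separated by ``/``.
2. **De-duplication** — when one lipid name has several readings, the
   reading with the highest total abundance is kept.
3. **Normalization** — for display-style matrices each feature is divided
   by the median of the reference (young) samples and log2 transformed, so
   the reference centers at 0 per feature.
4. **Moderated t** — per-feature two-sample comparison on log2 data with
   empirical-Bayes variance shrinkage: the feature variances are assumed
   drawn from a scaled inverse chi-square prior with parameters ``(d0,
   s0^2)`` estimated by method of moments on the log residual variances
   (digamma/trigamma matching); the posterior variance
   ``s~^2 = (d0 s0^2 + d s^2) / (d0 + d)`` feeds a t statistic with
   ``d + d0`` degrees of freedom. ``d0 = 0`` recovers the ordinary t,
   ``d0 = inf`` a z-like statistic with the pooled prior variance.
5. **FDR** — Benjamini-Hochberg step-up; significance requires adjusted
   p < 0.05 AND |log2 fold change| > 1.
6. **LSEA** — lipid-set enrichment over class and chain-length sets, ranked
   by log2 fold change. The enrichment score is the GSEA-style weighted
   Kolmogorov-Smirnov running sum: walking down the ranking, member hits
   advance a |logFC|-weighted cumulative ``P_hit`` while misses advance the
   uniform ``P_miss``, and the ES is the signed deviation ``P_hit - P_miss``
   at its maximal absolute excursion; a set containing every feature has no
   misses to contrast against and scores 0. Null by random membership
   permutations; ``p = (1 + #{|ES_perm| >= |ES|}) / (1 + n_perm)``, BH
   adjusted across tested sets. Sets smaller than ``min_size`` (default 4)
   are reported untested.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DomainError, FormatError, ValidationError

__all__ = [
    "LipidSpecies",
    "parse_lipid_name",
    "dedupe_features",
    "median_log2_normalize",
    "moderated_t",
    "bh_adjust",
    "de_filter",
    "derive_lipid_sets",
    "lsea",
]

_LIPID_RE = re.compile(
    r"^\s*(?P<cls>[A-Za-z][A-Za-z0-9\-]*)\s+(?P<chains>\d+:\d+(?:/\d+:\d+)*)\s*$"
)


@dataclass(frozen=True)
class LipidSpecies:
    lipid_class: str
    chains: tuple[tuple[int, int], ...]

    @property
    def total_carbons(self) -> int:
        return sum(c for c, _ in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(d for _, d in self.chains)


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a ``"CLS xx:x/yy:y"`` lipid name into class and chains."""
    if not isinstance(name, str) or not name.strip():
        raise FormatError("empty lipid name")
    m = _LIPID_RE.match(name)
    if m is None:
        raise FormatError(f"lipid name {name!r} does not follow the 'CLS xx:x/yy:y' scheme")
    chains = tuple(
        (int(c), int(d))
        for c, d in (chain.split(":") for chain in m.group("chains").split("/"))
    )
    return LipidSpecies(lipid_class=m.group("cls"), chains=chains)


# ---------------------------------------------------------------------------
# matrix preparation


def dedupe_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Resolve duplicate feature names, keeping the reading with the highest
    total abundance across samples."""
    if not matrix.index.has_duplicates:
        return matrix
    totals = matrix.sum(axis=1)
    order = np.argsort(-totals.to_numpy(), kind="stable")
    kept = matrix.iloc[order].groupby(level=0, sort=False).head(1)
    return kept.loc[sorted(kept.index)]


def _check_groups(matrix: pd.DataFrame, groups: pd.Series) -> pd.Series:
    groups = pd.Series(groups)
    missing = [c for c in matrix.columns if c not in groups.index]
    if missing:
        raise ValidationError(f"samples without a group label: {missing}")
    return groups.loc[matrix.columns]


def median_log2_normalize(
    matrix: pd.DataFrame, groups: pd.Series, reference_group: str = "young"
) -> pd.DataFrame:
    """log2(value / per-feature median of the reference group), all samples.

    Features whose reference median is not strictly positive are excluded
    with a warning (log of a non-positive center is undefined).
    """
    groups = _check_groups(matrix, groups)
    ref_cols = matrix.columns[groups.to_numpy() == reference_group]
    if len(ref_cols) == 0:
        raise ValidationError(f"no samples in reference group {reference_group!r}")
    med = matrix[ref_cols].median(axis=1)
    bad = med <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} features dropped: non-positive reference median"
        )
    kept = matrix.loc[~bad]
    return np.log2(kept.div(med[~bad], axis=0))


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        diff = (tri - y) / special.polygamma(2, x)
        x = x - diff
        if abs(diff) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log residual variances.

    If sigma_g^2 ~ s0^2 * d0 / chi^2_d0 and s_g^2 | sigma_g^2 is a scaled
    chi^2_d, then e_g = log s_g^2 - digamma(d/2) + log(d/2) has mean
    log s0^2 + digamma(d0/2) - log(d0/2) and variance trigamma(d/2) +
    trigamma(d0/2); matching the sample mean and variance of e_g yields the
    prior. Excess variance <= 0 means no detectable spread between feature
    variances: d0 = inf and s0^2 from the mean alone.
    """
    pos = s2[s2 > 0]
    if len(pos) == 0:
        raise ValidationError("all residual variances are zero; nothing to moderate")
    e = np.log(pos) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    if len(e) < 2:
        return np.inf, float(np.exp(e_mean))
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s02 = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s02


def moderated_t(
    matrix: pd.DataFrame,
    groups: pd.Series,
    group_order: tuple[str, str] = ("young", "aged"),
    d0: float | None = None,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t test per feature.

    ``matrix`` must already be on a log2 scale. ``group_order`` is
    (reference, treatment); logFC = mean(treatment) - mean(reference).
    Passing ``d0`` overrides the estimated prior degrees of freedom
    (0 disables shrinkage, inf fixes the variance at the prior).
    Returns a DataFrame indexed by feature with columns
    ``log_fc, t, p, adj_p, significant`` and attrs ``d0``, ``s0_sq``.
    """
    groups = _check_groups(matrix, groups)
    ref, trt = group_order
    a = matrix.loc[:, groups.to_numpy() == ref].to_numpy(dtype=float)
    b = matrix.loc[:, groups.to_numpy() == trt].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError(f"need >=2 samples per group, got {ref}:{n1}, {trt}:{n2}")
    df_resid = n1 + n2 - 2
    log_fc = b.mean(axis=1) - a.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    usable = s2 > 0
    if not usable.all():
        warnings.warn(f"{int((~usable).sum())} features with zero residual variance excluded")
    if d0 is None:
        d0_fit, s02 = _fit_variance_prior(s2[usable], df_resid)
    else:
        d0_fit = float(d0)
        s02 = _fit_variance_prior(s2[usable], df_resid)[1] if d0_fit > 0 else 0.0

    if np.isinf(d0_fit):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0_fit == 0:
        s2_post = s2.copy()
        df_total = df_resid
    else:
        s2_post = (d0_fit * s02 + df_resid * s2) / (d0_fit + df_resid)
        df_total = df_resid + d0_fit

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log_fc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame(
        {"log_fc": log_fc, "t": t, "p": p},
        index=matrix.index,
    ).loc[usable]
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["adj_p"] < alpha) & (out["log_fc"].abs() > fc_threshold)
    out.attrs["d0"] = d0_fit
    out.attrs["s0_sq"] = s02
    out.attrs["prior"] = "method-of-moments on log residual variances"
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def de_filter(results: pd.DataFrame, alpha: float = 0.05, fc_threshold: float = 1.0) -> pd.Index:
    """Features passing adjusted p < alpha AND |log2 FC| > fc_threshold."""
    keep = (results["adj_p"] < alpha) & (results["log_fc"].abs() > fc_threshold)
    return results.index[keep]


# ---------------------------------------------------------------------------
# lipid-set enrichment


def derive_lipid_sets(feature_names) -> dict[str, list[str]]:
    """Class sets and total-chain-length sets from parsed lipid names.

    Every distinct lipid class becomes a set ``class:<CLS>`` and every
    distinct total carbon count a set ``chain_length:<NN>``. Unparseable
    names are skipped with a warning.
    """
    sets: dict[str, list[str]] = {}
    skipped = []
    for name in feature_names:
        try:
            sp = parse_lipid_name(name)
        except FormatError:
            skipped.append(name)
            continue
        sets.setdefault(f"class:{sp.lipid_class}", []).append(name)
        sets.setdefault(f"chain_length:{sp.total_carbons}", []).append(name)
    if skipped:
        warnings.warn(f"{len(skipped)} feature names not parseable as lipids, e.g. {skipped[:3]}")
    return sets


def _enrichment_scores(weights: np.ndarray, members: np.ndarray) -> np.ndarray:
    """Weighted KS-style running-sum enrichment score, vectorized over sets.

    ``weights`` are |logFC| in rank order; ``members`` is a (k, N) boolean
    matrix of set membership. Along the ranking, hits advance a
    weight-normalized cumulative ``P_hit`` and misses advance the uniform
    ``P_miss``; the ES is the signed running-sum deviation ``P_hit - P_miss``
    at its maximal absolute excursion. A set containing every feature has no
    misses to contrast against and scores 0 by convention; a set whose
    weighted mass all sits in zero-weight features likewise scores 0.
    """
    members = np.atleast_2d(members)
    k, n = members.shape
    es = np.zeros(k)
    w_hit = weights[None, :] * members
    denom_hit = w_hit.sum(axis=1)
    n_miss = (~members).sum(axis=1)
    ok = (denom_hit > 0) & (n_miss > 0)
    if ok.any():
        p_hit = np.cumsum(w_hit[ok], axis=1) / denom_hit[ok, None]
        p_miss = np.cumsum(~members[ok], axis=1) / n_miss[ok, None]
        gap = p_hit - p_miss
        arg = np.argmax(np.abs(gap), axis=1)
        es[ok] = np.take_along_axis(gap, arg[:, None], axis=1).ravel()
    return es


def lsea(
    results: pd.DataFrame,
    sets: dict[str, list[str]] | None = None,
    n_perm: int = 10_000,
    min_size: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation lipid-set enrichment on moderated-t results.

    Features are ranked by log2 fold change, descending, ties broken by
    feature name for determinism. ``sets`` defaults to class and
    chain-length sets derived from the feature names. Deterministic given
    ``seed``. Returns one row per set: ``set, size, es, p, adj_p, tested``.
    """
    if sets is None:
        sets = derive_lipid_sets(results.index)
    # rank by log2 FC descending, ties broken by feature name
    ranked = results.iloc[
        np.lexsort((results.index.to_numpy().astype(str), -results["log_fc"].to_numpy()))
    ]
    weights = np.abs(ranked["log_fc"].to_numpy(dtype=float))
    pos = {name: i for i, name in enumerate(ranked.index)}
    n = len(ranked)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for set_name in sorted(sets):
        members = [f for f in sets[set_name] if f in pos]
        size = len(members)
        indicator = np.zeros(n, dtype=bool)
        indicator[[pos[f] for f in members]] = True
        if size < min_size:
            rows.append(
                {"set": set_name, "size": size, "es": np.nan, "p": np.nan, "tested": False}
            )
            continue
        es = float(_enrichment_scores(weights, indicator)[0])
        # membership permutations: random placements of an equal-sized set
        perm = np.tile(indicator, (n_perm, 1))
        perm = rng.permuted(perm, axis=1)
        es_perm = _enrichment_scores(weights, perm)
        p = (1.0 + np.sum(np.abs(es_perm) >= abs(es) - 1e-12)) / (1.0 + n_perm)
        rows.append({"set": set_name, "size": size, "es": es, "p": p, "tested": True})
    out = pd.DataFrame(rows).set_index("set")
    tested = out["tested"].to_numpy()
    adj = np.full(len(out), np.nan)
    if tested.any():
        adj[tested] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["adj_p"] = adj
    return out.reset_index()
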