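"""Relative quantification of qPCR data by the ddCt method.

Per sample, the target gene's threshold cycle is normalized against a
reference gene: ``dCt = Ct_target - Ct_reference``. Groups are compared as
``ddCt = mean dCt(experimental) - mean dCt(control)`` and expressed as a
fold change ``FC = 2**(-ddCt)``: a gene whose transcript doubles in the
experimental group gains one fewer cycle, dCt drops by 1, ddCt = -1 and
FC = 2. Technical replicates are collapsed by arithmetic mean first; noisy
triplicates (SD > 0.5 cycles) are flagged with a warning but never dropped,
since no exclusion rule is part of the protocol.

The module also carries, as package data, the published fly-aging worked
example: two tissue tables of (gene, ddCt, fold change) pairs that the
fold-change operator must reproduce at printed precision. The printed ddCt
values are themselves rounded to three decimals, so recomputed fold changes
can legitimately differ from the printed ones by one unit in the last
printed digit; :func:`verify_printed_fold_changes` reports that deviation
per row.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import compare_two, stars
from .errors import DegenerateDataError, DomainError, ValidationError

__all__ = [
    "QPCR_COLUMNS",
    "DdctResult",
    "collapse_replicates",
    "ddct",
    "ddct_table",
    "fold_change_from_ddct",
    "load_printed_fly_tables",
    "verify_printed_fold_changes",
]

QPCR_COLUMNS = ("sample_id", "group", "gene", "replicate", "ct")

#: technical replicate spread (cycles) above which a warning is raised
REPLICATE_SD_WARN = 0.5


@dataclass
class DdctResult:
    gene: str
    delta_ct_control: float
    delta_ct_experimental: float
    ddct: float
    fold_change: float
    p_value: float = float("nan")
    stars: str = ""


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"qPCR table missing columns {missing}")
    if not np.isfinite(table["ct"]).all():
        raise ValidationError("qPCR table contains non-finite Ct values")
    return table


def collapse_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (sample, group, gene); flags noisy technical replicates."""
    _validate(table)
    g = table.groupby(["sample_id", "group", "gene"], sort=True)["ct"]
    means = g.mean().reset_index()
    sds = g.std(ddof=1)
    noisy = sds[sds > REPLICATE_SD_WARN]
    for (sample, _, gene), sd in noisy.items():
        warnings.warn(
            f"technical replicates for sample {sample!r}, gene {gene!r} "
            f"spread SD={sd:.2f} cycles (> {REPLICATE_SD_WARN})"
        )
    return means


def fold_change_from_ddct(value: float) -> float:
    """``2**(-ddCt)``; the exponential inverse of the cycle difference."""
    if not math.isfinite(value):
        raise DomainError(f"ddCt must be finite, got {value!r}")
    return 2.0 ** (-value)


def ddct(
    table: pd.DataFrame,
    gene: str,
    reference_gene: str,
    control_group: str,
    experimental_group: str,
    compute_p: bool = True,
) -> DdctResult:
    """ddCt and fold change for one gene between two groups.

    Group dCt means are taken over per-sample dCt values (technical
    replicates collapsed first). When ``compute_p`` is set, an unpaired
    pooled-variance t test on the per-sample dCt values supplies the
    p-value and star annotation.
    """
    collapsed = collapse_replicates(table)
    dcts: dict[str, np.ndarray] = {}
    for grp in (control_group, experimental_group):
        sub = collapsed[collapsed["group"] == grp].pivot(
            index="sample_id", columns="gene", values="ct"
        )
        if gene not in sub.columns or sub[gene].isna().any():
            raise ValidationError(f"group {grp!r}: gene {gene!r} missing for some samples")
        if reference_gene not in sub.columns or sub[reference_gene].isna().any():
            raise ValidationError(
                f"group {grp!r}: reference gene {reference_gene!r} missing for some samples"
            )
        dcts[grp] = (sub[gene] - sub[reference_gene]).to_numpy()
    d_ctrl = float(np.mean(dcts[control_group]))
    d_exp = float(np.mean(dcts[experimental_group]))
    dd = d_exp - d_ctrl
    p, star = float("nan"), ""
    if compute_p and len(dcts[control_group]) >= 2 and len(dcts[experimental_group]) >= 2:
        try:
            res = compare_two(dcts[control_group], dcts[experimental_group], test="t_unpaired")
            p, star = res.p_value, stars(res.p_value)
        except DegenerateDataError:
            pass  # noiseless dCt values: a t statistic is undefined
    return DdctResult(
        gene=gene,
        delta_ct_control=d_ctrl,
        delta_ct_experimental=d_exp,
        ddct=dd,
        fold_change=fold_change_from_ddct(dd),
        p_value=p,
        stars=star,
    )


def ddct_table(
    table: pd.DataFrame,
    reference_gene: str,
    control_group: str,
    experimental_group: str,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """ddCt results for every target gene in the table (or a chosen subset)."""
    _validate(table)
    if genes is None:
        genes = sorted(set(table["gene"]) - {reference_gene})
    rows = [
        ddct(table, g, reference_gene, control_group, experimental_group) for g in genes
    ]
    return pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "ddct": [r.ddct for r in rows],
            "fold_change": [r.fold_change for r in rows],
            "p": [r.p_value for r in rows],
            "stars": [r.stars for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# published worked example


def load_printed_fly_tables() -> pd.DataFrame:
    """The published fly-aging ddCt tables (flight muscle and cardiac tissue).

    Columns: tissue, gene, ddct, fold_change_printed (string, preserving the
    printed decimals), significant (0/1 as marked in the source tables).
    """
    with resources.files("mitomorph.data").joinpath("fly_ddct_tables.csv").open() as fh:
        return pd.read_csv(fh, dtype={"fold_change_printed": str})


def verify_printed_fold_changes(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute each printed fold change from its ddCt and compare.

    Adds ``fold_change_computed``, ``decimals``, ``ulp_error`` (absolute
    difference in units of the last printed digit after rounding) and
    ``reproduced`` (ulp_error <= 1). The one-ULP allowance absorbs the
    rounding of the printed ddCt column itself.
    """
    if table is None:
        table = load_printed_fly_tables()
    out = table.copy()
    decimals = out["fold_change_printed"].str.split(".").str[1].str.len().fillna(0).astype(int)
    computed = out["ddct"].map(fold_change_from_ddct)
    printed = out["fold_change_printed"].astype(float)
    ulp = 10.0 ** (-decimals)
    scale = 10.0 ** decimals.to_numpy()
    rounded = np.round(computed.to_numpy() * scale) / scale
    out["fold_change_computed"] = computed
    out["decimals"] = decimals
    out["ulp_error"] = np.abs(rounded - printed.to_numpy()) / ulp
    out["reproduced"] = out["ulp_error"] <= 1.0 + 1e-9
    return out
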