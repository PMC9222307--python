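"""Variant-table analytics: OR adjustment, direction split, quartiles, regression.

A variant table is a pandas DataFrame with columns ``id``, ``variant_type``
(``SNP`` or ``indel``), ``raf`` (risk allele frequency, which may be minor or
major) and ``or_raw`` (the reported case/control odds ratio, possibly < 1).
:func:`annotate` derives ``or_adjusted`` (all effects mapped to >= 1 via 1/OR)
and ``direction`` (whether the allele is enriched in cases or controls).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REQUIRED_COLUMNS",
    "VARIANT_TYPES",
    "QuartileStats",
    "SummaryStats",
    "DirectionSplit",
    "adjust_or",
    "annotate",
    "filter_snps",
    "split_by_direction",
    "quartile_partition",
    "regress_raf_or",
    "summarize_raf_or",
    "compare_raf_means",
]

REQUIRED_COLUMNS = ("id", "variant_type", "raf", "or_raw")
VARIANT_TYPES = ("SNP", "indel")


@dataclass(frozen=True)
class QuartileStats:
    """OLS fit of adjusted OR on RAF within one quartile of the table."""

    quartile: int
    n: int
    slope: float
    intercept: float
    r: float


@dataclass(frozen=True)
class SummaryStats:
    mean_raf: float
    sd_raf: float
    mean_or: float
    sd_or: float
    n: int


class DirectionSplit(NamedTuple):
    case_enriched: pd.DataFrame
    control_enriched: pd.DataFrame
    ties: pd.DataFrame


def adjust_or(or_raw):
    """Map an odds ratio to the >= 1 scale: OR if OR >= 1, else 1/OR.

    Accepts scalars or arrays; idempotent.
    """
    arr = np.asarray(or_raw, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("odds ratios must be > 0")
    out = np.where(arr >= 1.0, arr, 1.0 / arr)
    return float(out) if np.isscalar(or_raw) or arr.ndim == 0 else out


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    bad_types = set(table["variant_type"]) - set(VARIANT_TYPES)
    if bad_types:
        raise ValueError(f"unknown variant_type tokens: {sorted(bad_types)}")


def annotate(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with derived ``or_adjusted`` and ``direction`` columns.

    ``direction`` is ``case_enriched`` for or_raw > 1, ``control_enriched``
    for or_raw < 1 and ``tie`` for or_raw == 1 exactly (ties are flagged, not
    silently assigned to a side).
    """
    _validate(table)
    out = table.copy()
    out["or_adjusted"] = adjust_or(out["or_raw"].to_numpy()) if len(out) else np.nan
    out["direction"] = np.select(
        [out["or_raw"] > 1.0, out["or_raw"] < 1.0],
        ["case_enriched", "control_enriched"],
        default="tie",
    )
    return out


def filter_snps(table: pd.DataFrame) -> pd.DataFrame:
    """Drop indel rows, preserving order; kept/dropped counts in ``.attrs``."""
    _validate(table)
    kept = table[table["variant_type"] == "SNP"].copy()
    kept.attrs["n_kept"] = len(kept)
    kept.attrs["n_dropped"] = len(table) - len(kept)
    return kept


def split_by_direction(table: pd.DataFrame) -> DirectionSplit:
    """Partition into case-enriched (OR > 1) and control-enriched (OR < 1) rows.

    Rows with or_raw == 1 exactly fit neither direction and are returned as a
    third ``ties`` frame.
    """
    ann = annotate(table)
    return DirectionSplit(
        case_enriched=ann[ann["direction"] == "case_enriched"],
        control_enriched=ann[ann["direction"] == "control_enriched"],
        ties=ann[ann["direction"] == "tie"],
    )


def quartile_partition(table: pd.DataFrame, key: str = "or_adjusted") -> pd.Series:
    """Assign each record a quartile 1-4 by ascending `key`.

    Boundaries fall at ranks ceil(n/4), ceil(n/2) and ceil(3n/4), so the
    lowest quartile absorbs any remainder (n = 57 gives sizes 15/14/14/14).
    Ties on the key are broken by ``id`` lexicographically so the assignment
    is deterministic.
    """
    if key not in ("or_adjusted", "raf"):
        raise ValueError(f"key must be 'or_adjusted' or 'raf', got {key!r}")
    tab = annotate(table) if key == "or_adjusted" and key not in table.columns else table
    n = len(tab)
    if n < 4:
        raise ValueError(f"need at least 4 records to form quartiles, got {n}")
    order = tab.sort_values([key, "id"], kind="mergesort").index
    ranks = pd.Series(np.arange(1, n + 1), index=order)
    bounds = [int(np.ceil(n / 4)), int(np.ceil(n / 2)), int(np.ceil(3 * n / 4))]
    labels = np.searchsorted(bounds, ranks.to_numpy(), side="left") + 1
    return pd.Series(labels, index=order, name="quartile").reindex(tab.index)


def regress_raf_or(records: pd.DataFrame, quartile: int = 0) -> QuartileStats:
    """OLS of adjusted OR on RAF over the given records (one quartile, usually).

    Returns slope (OR units per frequency unit), intercept and Pearson r.
    A constant adjusted OR gives slope 0 and r 0; constant RAF is an error
    (the regression is undefined).
    """
    tab = annotate(records) if "or_adjusted" not in records.columns else records
    n = len(tab)
    if n < 3:
        raise ValueError(f"need at least 3 records to regress, got {n}")
    x = tab["raf"].to_numpy(dtype=float)
    y = tab["or_adjusted"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("regression undefined: zero variance in raf")
    if np.ptp(y) == 0:
        return QuartileStats(quartile=quartile, n=n, slope=0.0,
                             intercept=float(y[0]), r=0.0)
    fit = stats.linregress(x, y)
    return QuartileStats(quartile=quartile, n=n, slope=float(fit.slope),
                         intercept=float(fit.intercept), r=float(fit.rvalue))


def summarize_raf_or(table: pd.DataFrame) -> SummaryStats:
    """Mean and sample SD (n-1 denominator) of RAF and adjusted OR."""
    tab = annotate(table) if "or_adjusted" not in table.columns else table
    n = len(tab)
    if n < 2:
        raise ValueError(f"need at least 2 records for a sample SD, got {n}")
    raf = tab["raf"].to_numpy(dtype=float)
    oradj = tab["or_adjusted"].to_numpy(dtype=float)
    return SummaryStats(
        mean_raf=float(raf.mean()), sd_raf=float(raf.std(ddof=1)),
        mean_or=float(oradj.mean()), sd_or=float(oradj.std(ddof=1)), n=n,
    )


def compare_raf_means(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
    """Welch two-sample t-test on RAF between two variant tables.

    Returns (t statistic, two-sided p).  Two degenerate samples with equal
    means count as no difference (t = 0, p = 1).
    """
    xa = a["raf"].to_numpy(dtype=float)
    xb = b["raf"].to_numpy(dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("each table needs at least 2 records")
    if np.ptp(xa) == 0 and np.ptp(xb) == 0:
        return (0.0, 1.0) if xa.mean() == xb.mean() else (float("inf"), 0.0)
    t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return float(t), float(p)
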