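"""Per-disc measurement table and the group/grade statistical battery.

One row per disc with nine measures: {T2 mapping, T2w signal, Dixon water %}
x {whole disc, nucleus, nucleus/annulus ratio}.  Athletic groups are compared
to the sedentary referent and degeneration grades 2-4 to grade 1 with
unpaired two-sided t-tests (Welch by default); all measure pairs get Pearson
correlations.  Significance tiers: * p<0.05, dagger p<0.01, ddagger p<0.001.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phantom import GRADES, GROUPS

logger = logging.getLogger(__name__)

MEASURE_COLUMNS = (
    "t2_whole",
    "t2_nucleus",
    "t2_ratio",
    "t2w_whole",
    "t2w_nucleus",
    "t2w_ratio",
    "dixon_whole",
    "dixon_nucleus",
    "dixon_ratio",
)
ID_COLUMNS = ("disc_id", "subject_id", "level", "group", "pfirrmann_grade")

TIER_NS = "ns"
TIERS = ((0.001, "‡"), (0.01, "†"), (0.05, "*"))


def significance_tier(p: float) -> str:
    if not np.isfinite(p):
        return TIER_NS
    for threshold, mark in TIERS:
        if p < threshold:
            return mark
    return TIER_NS


@dataclass
class ComparisonResult:
    measure: str
    contrast: str
    mean_ref: float
    sd_ref: float
    n_ref: int
    mean_other: float
    sd_other: float
    n_other: int
    t: float
    p: float
    tier: str


def validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in MEASURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"disc table lacks measure columns: {missing}")
    grades = set(table["pfirrmann_grade"].unique())
    if not grades <= set(GRADES):
        raise ValueError(f"unexpected grades {grades - set(GRADES)}")


def _aggregate(table: pd.DataFrame, by: str, aggregate: str) -> pd.DataFrame:
    """Observation unit: discs (default) or subject means within cells."""
    if aggregate == "disc":
        return table
    if aggregate == "subject":
        keys = ["subject_id", by]
        return table.groupby(keys, as_index=False)[list(MEASURE_COLUMNS)].mean()
    raise ValueError("aggregate must be 'disc' or 'subject'")


def _ttest(ref: np.ndarray, other: np.ndarray, measure: str, contrast: str, equal_var: bool):
    ref = ref[np.isfinite(ref)]
    other = other[np.isfinite(other)]
    if len(ref) < 2 or len(other) < 2:
        logger.warning("comparison %s / %s: empty or singleton cell, skipped", measure, contrast)
        return None
    import warnings

    with warnings.catch_warnings():
        # degenerate cells (identical or near-identical samples) are legal
        # inputs here and are resolved to t=0, p=1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(other, ref, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):  # identical zero-variance samples
        t, p = 0.0, 1.0
    return ComparisonResult(
        measure,
        contrast,
        float(ref.mean()),
        float(ref.std(ddof=1)),
        len(ref),
        float(other.mean()),
        float(other.std(ddof=1)),
        len(other),
        t,
        p,
        significance_tier(p),
    )


def compare_to_referent(
    table: pd.DataFrame,
    measure: str,
    referent_group: str = "sedentary",
    equal_var: bool = False,
    aggregate: str = "disc",
) -> Dict[str, Optional[ComparisonResult]]:
    """Unpaired t-test of each non-referent group against the referent."""
    validate_table(table)
    tab = _aggregate(table, "group", aggregate)
    ref = tab.loc[tab["group"] == referent_group, measure].to_numpy(dtype=float)
    out: Dict[str, Optional[ComparisonResult]] = {}
    for group in [g for g in GROUPS if g != referent_group]:
        other = tab.loc[tab["group"] == group, measure].to_numpy(dtype=float)
        out[group] = _ttest(ref, other, measure, f"{group} vs {referent_group}", equal_var)
    return out


def compare_to_grade1(
    table: pd.DataFrame,
    measure: str,
    equal_var: bool = False,
    aggregate: str = "disc",
) -> Dict[int, Optional[ComparisonResult]]:
    """Unpaired t-test of grades 2-4 against grade-1 discs."""
    validate_table(table)
    tab = _aggregate(table, "pfirrmann_grade", aggregate)
    ref = tab.loc[tab["pfirrmann_grade"] == 1, measure].to_numpy(dtype=float)
    out: Dict[int, Optional[ComparisonResult]] = {}
    for grade in (2, 3, 4):
        other = tab.loc[tab["pfirrmann_grade"] == grade, measure].to_numpy(dtype=float)
        out[grade] = _ttest(ref, other, measure, f"grade {grade} vs grade 1", equal_var)
    return out


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r (two-sided p, tiers) over the nine measures.

    Pairwise-complete observations; zero-variance columns yield NaN and a
    logged warning.  Returns a tidy frame with one row per ordered pair.
    """
    validate_table(table)
    if len(table) < 3:
        raise ValueError("need at least 3 rows for correlations")
    rows = []
    for a, b in itertools.product(MEASURE_COLUMNS, MEASURE_COLUMNS):
        x = table[a].to_numpy(dtype=float)
        y = table[b].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        zero_var = len(x) > 0 and (np.std(x) == 0 or np.std(y) == 0)
        if len(x) < 3 or zero_var:
            if zero_var:
                logger.warning("correlation %s ~ %s: zero variance, skipped", a, b)
            r, p = np.nan, np.nan
        elif a == b:
            r, p = 1.0, 0.0
        else:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", sps.NearConstantInputWarning)
                res = sps.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {"measure_a": a, "measure_b": b, "n": len(x), "r": r, "p": p,
             "tier": significance_tier(p) if np.isfinite(p) else TIER_NS}
        )
    return pd.DataFrame(rows)


def _cell_label(mean: float, sd: float, tier: str) -> str:
    mark = "" if tier == TIER_NS else f" {tier}"
    return f"{mean:.1f} ({sd:.1f}){mark}"


def summarize_by(
    table: pd.DataFrame,
    by: str,
    referent,
    equal_var: bool = False,
    aggregate: str = "disc",
) -> pd.DataFrame:
    """Cell mean/SD/n per measure per group (or grade), with significance
    marks against the referent cell."""
    validate_table(table)
    tab = _aggregate(table, by, aggregate)
    cells = sorted(tab[by].unique(), key=lambda v: (v != referent, v)) if by == "group" else sorted(
        tab[by].unique()
    )
    if by == "group":
        order = [g for g in GROUPS if g in set(cells)]
        cells = order
    compare = compare_to_referent if by == "group" else compare_to_grade1
    rows = []
    for measure in MEASURE_COLUMNS:
        comp = compare(table, measure, equal_var=equal_var, aggregate=aggregate)
        row: Dict[str, object] = {"measure": measure}
        for cell in cells:
            vals = tab.loc[tab[by] == cell, measure].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                row[f"{cell}_mean"] = np.nan
                row[f"{cell}_sd"] = np.nan
                row[f"{cell}_n"] = 0
                row[f"{cell}_tier"] = ""
                continue
            if by == "group":
                res = comp.get(cell) if cell != referent else None
            else:
                res = comp.get(cell) if cell != referent else None
            tier = res.tier if res is not None else ""
            row[f"{cell}_mean"] = float(vals.mean())
            row[f"{cell}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            row[f"{cell}_n"] = len(vals)
            row[f"{cell}_tier"] = tier
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_tables(
    table: pd.DataFrame,
    referent_group: str = "sedentary",
    equal_var: bool = False,
    aggregate: str = "disc",
) -> Dict[str, pd.DataFrame]:
    """Group table, grade table and correlation grid for a disc table."""
    return {
        "by_group": summarize_by(table, "group", referent_group, equal_var, aggregate),
        "by_grade": summarize_by(table, "pfirrmann_grade", 1, equal_var, aggregate),
        "correlations": correlation_matrix(table),
    }
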