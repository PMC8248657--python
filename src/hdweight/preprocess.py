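"""Cleaning of the longitudinal visit table and per-subject weight change.

The raw table holds one row per subject-visit.  Cleaning removes rows with
missing analysis values and rows carrying boxplot (Tukey-fence) outliers in
selected factors; consolidation then reduces each subject to a single record
with the percentage weight change

    delta_w = (w_f - w_b) / w_b * 100

between the baseline weight w_b and the weight w_f at the last follow-up
(largest visit sequence number).  Subjects lacking a baseline or lacking any
follow-up after cleaning are excluded and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scheme import FACTORS

log = logging.getLogger(__name__)

#: Factors screened for boxplot outliers by default: the score columns in
#: which the raw data shows implausible extreme values.
DEFAULT_OUTLIER_FACTORS: tuple[str, ...] = (
    "tfcscore", "indepscl", "irascore", "motscore", "depscore",
)

#: Columns a row must have non-missing to enter the analysis.
ANALYSIS_COLUMNS: tuple[str, ...] = ("subjid", "visit_type", "visit_seq",
                                     "weight_kg", *FACTORS)


class DataError(ValueError):
    """Structurally invalid subject data (duplicate baseline, bad weight)."""


@dataclass
class CleaningReport:
    """Row/subject accounting of one preprocessing pass."""

    rows_in: int = 0
    rows_dropped_missing: int = 0
    rows_dropped_outlier: int = 0
    subjects_in: int = 0
    subjects_excluded: int = 0
    subjects_retained: int = 0


def remove_missing(table: pd.DataFrame) -> pd.DataFrame:
    """Drop every row with a missing value in any analysis column."""
    cols = [c for c in ANALYSIS_COLUMNS if c in table.columns]
    missing = [c for c in ANALYSIS_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"table lacks required column(s): {missing}")
    return table.dropna(subset=cols).copy()


def remove_outliers(table: pd.DataFrame,
                    factors: tuple[str, ...] = DEFAULT_OUTLIER_FACTORS) -> pd.DataFrame:
    """Drop rows outside the Tukey fences of any named factor.

    Fences are Q1 - 1.5*IQR and Q3 + 1.5*IQR with quartiles computed once on
    the input table (linear interpolation), not iteratively re-estimated.
    """
    keep = np.ones(len(table), dtype=bool)
    for factor in factors:
        if factor not in table.columns:
            raise KeyError(f"unknown outlier factor {factor!r}")
        col = table[factor].astype(float).to_numpy()
        q1, q3 = np.nanpercentile(col, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        with np.errstate(invalid="ignore"):
            keep &= ~((col < lo) | (col > hi))
    return table.loc[keep].copy()


def compute_weight_change(table: pd.DataFrame,
                          factors_from: str = "last_followup",
                          report: CleaningReport | None = None) -> pd.DataFrame:
    """Collapse the visit table to one record per subject with ``delta_w``.

    For every subject, w_b is the Baseline weight and w_f the weight of the
    follow-up with the largest ``visit_seq``; the record's factor values come
    from that last follow-up visit (or the baseline visit with
    ``factors_from='baseline'``).  Subjects without a baseline or without any
    follow-up are excluded and logged.

    Raises :class:`DataError` on duplicate baseline rows or non-positive
    baseline weight, naming the subject.
    """
    if factors_from not in ("last_followup", "baseline"):
        raise ValueError(f"factors_from must be 'last_followup' or 'baseline'")
    records = []
    excluded = 0
    factor_cols = [c for c in FACTORS if c in table.columns]
    for subjid, sub in table.groupby("subjid", sort=False):
        base = sub[sub["visit_type"] == "Baseline"]
        fups = sub[sub["visit_type"] == "FollowUp"]
        if len(base) > 1:
            raise DataError(f"subject {subjid!r} has {len(base)} baseline rows")
        if len(base) == 0 or len(fups) == 0:
            excluded += 1
            continue
        w_b = float(base["weight_kg"].iloc[0])
        if w_b <= 0:
            raise DataError(f"subject {subjid!r} has non-positive baseline weight {w_b}")
        last = fups.loc[fups["visit_seq"].idxmax()]
        w_f = float(last["weight_kg"])
        delta_w = (w_f - w_b) / w_b * 100.0
        source = base.iloc[0] if factors_from == "baseline" else last
        rec = {"subjid": subjid,
               "group": sub["group"].iloc[0] if "group" in sub.columns else "",
               "delta_w": delta_w}
        for c in factor_cols:
            rec[c] = source[c]
        records.append(rec)
    if excluded:
        log.info("excluded %d subject(s) lacking a baseline or any follow-up", excluded)
    if report is not None:
        report.subjects_excluded = excluded
        report.subjects_retained = len(records)
    cols = ["subjid", "group", "delta_w", *factor_cols]
    return pd.DataFrame(records, columns=cols)


def preprocess(table: pd.DataFrame,
               outlier_factors: tuple[str, ...] = DEFAULT_OUTLIER_FACTORS,
               factors_from: str = "last_followup") -> tuple[pd.DataFrame, CleaningReport]:
    """Full cleaning pipeline: missing values, outliers, weight change.

    Returns the consolidated subject records and a :class:`CleaningReport`
    with the row/subject accounting of each stage.
    """
    rep = CleaningReport(rows_in=len(table),
                         subjects_in=table["subjid"].nunique())
    no_missing = remove_missing(table)
    rep.rows_dropped_missing = len(table) - len(no_missing)
    clean = remove_outliers(no_missing, outlier_factors)
    rep.rows_dropped_outlier = len(no_missing) - len(clean)
    records = compute_weight_change(clean, factors_from=factors_from, report=rep)
    # subjects can also vanish entirely during row cleaning
    rep.subjects_excluded = rep.subjects_in - rep.subjects_retained
    return records, rep
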