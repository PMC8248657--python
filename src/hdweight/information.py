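"""Dependence between the weight category and clinical factors.

Chi-square tests of independence on the factor-by-weight-category
contingency table, plug-in conditional entropy H(Y|X), and mutual
information I(X;Y) = H(Y) - H(Y|X), in bits (log base 2).  Joint dependence
of a set of factors is measured through the exact composite variable (the
tuple of the factors' categories), not a chain-rule approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DependenceReport:
    factor: str
    mutual_information: float   # bits
    conditional_entropy: float  # bits
    chi2: float
    df: int
    p_value: float


def contingency_table(dataset: pd.DataFrame, factor_a: str, factor_b: str) -> pd.DataFrame:
    """Cross-tabulated counts of two categorical columns."""
    for f in (factor_a, factor_b):
        if f not in dataset.columns:
            raise KeyError(f"unknown factor {f!r}")
    return pd.crosstab(dataset[factor_a], dataset[factor_b])


def chi_square_independence(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test on a contingency table (no continuity correction).

    Rows or columns whose margin is zero are dropped with a warning before
    testing.  Returns (chi2, df, p_value).
    """
    counts = np.asarray(table, dtype=float)
    if counts.sum() == 0:
        raise ValueError("contingency table is empty")
    row_ok = counts.sum(axis=1) > 0
    col_ok = counts.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns before the chi-square test",
                      stacklevel=2)
        counts = counts[row_ok][:, col_ok]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("chi-square test needs at least a 2x2 table")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of an empirical count vector (0 log 0 := 0)."""
    counts = counts[counts > 0].astype(float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _composite(dataset: pd.DataFrame, given: str | Sequence[str]) -> pd.Series:
    if isinstance(given, str):
        if given not in dataset.columns:
            raise KeyError(f"unknown factor {given!r}")
        return dataset[given]
    cols = list(given)
    for c in cols:
        if c not in dataset.columns:
            raise KeyError(f"unknown factor {c!r}")
    # the exact tuple variable, encoded as integer codes (identity is all
    # that entropy/chi-square computations need)
    codes, _ = pd.factorize(pd.Series(list(zip(*(dataset[c] for c in cols))),
                                      index=dataset.index))
    return pd.Series(codes, index=dataset.index, name="+".join(cols))


def conditional_entropy(dataset: pd.DataFrame, target: str,
                        given: str | Sequence[str]) -> float:
    """Plug-in H(target | given) in bits: sum_x p(x) H(Y | X = x)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if target not in dataset.columns:
        raise KeyError(f"unknown factor {target!r}")
    x = _composite(dataset, given)
    y = dataset[target]
    n = len(dataset)
    h = 0.0
    for _, sub in y.groupby(x.to_numpy()):
        p_x = len(sub) / n
        h += p_x * _entropy(sub.value_counts().to_numpy())
    return h


def mutual_information(dataset: pd.DataFrame, target: str,
                       given: str | Sequence[str]) -> float:
    """Plug-in I(target; given) = H(target) - H(target | given), in bits.

    ``given`` may be one factor or a set of factors; in the latter case the
    conditioning variable is the exact tuple of their categories.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    h_y = _entropy(dataset[target].value_counts().to_numpy())
    return h_y - conditional_entropy(dataset, target, given)


def dependence_report(dataset: pd.DataFrame, target: str = "wtCat",
                      factors: Sequence[str] | None = None,
                      combos: Sequence[Sequence[str]] = ()) -> pd.DataFrame:
    """Per-factor (and per-combination) dependence on the target.

    Returns one row per factor/combination with mutual information,
    conditional entropy, and the chi-square test of independence (the test
    is run on the exact composite variable for combinations).
    """
    from .scheme import FACTORS

    if factors is None:
        factors = [f for f in FACTORS if f in dataset.columns and f != target]
    reports: list[DependenceReport] = []
    entries: list[str | Sequence[str]] = list(factors) + [tuple(c) for c in combos]
    for entry in entries:
        name = entry if isinstance(entry, str) else "+".join(entry)
        x = _composite(dataset, entry)
        table = pd.crosstab(x, dataset[target])
        chi2, df, p = chi_square_independence(table)
        mi = mutual_information(dataset, target, entry)
        ce = conditional_entropy(dataset, target, entry)
        reports.append(DependenceReport(factor=name, mutual_information=mi,
                                        conditional_entropy=ce, chi2=chi2,
                                        df=df, p_value=p))
    return pd.DataFrame([r.__dict__ for r in reports])
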