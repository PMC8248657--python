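"""Seeded synthetic longitudinal cohorts with plantable factor/weight dependencies.

The generator emulates the structure of an annual observational HD study:
each subject contributes one baseline visit and 3-5 annual follow-ups, with
body weight and a panel of clinical factor scores recorded at every visit.
Factor scores are drawn category-first from configurable ordinal marginals
and then placed uniformly inside the category's raw interval, so the
downstream categorization recovers the drawn category exactly.  Weight
follows a multiplicative random-walk drift; "planted" rules force chosen
antecedent categories on a stratum of subjects and solve the final
follow-up weight so that the percentage weight change lands in a chosen
weight category with a specified confidence.  Missing factor cells are
completely at random; outliers can be injected beyond the Tukey fences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scheme import FACTORS, WTCAT, CategorizationScheme, default_scheme

#: Exact, ordered cohort CSV columns.
COHORT_COLUMNS: tuple[str, ...] = (
    "subjid", "group", "visit_type", "visit_seq", "weight_kg", *FACTORS,
)


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class FormatError(ValueError):
    """A cohort file does not have the required layout."""


#: Illustrative ordinal marginals per factor (codes in ascending order).
#: Roughly unimodal, skewed toward the healthy end, as expected for a
#: premanifest cohort.
DEFAULT_MARGINALS: dict[str, tuple[float, ...]] = {
    "age": (0.10, 0.20, 0.25, 0.22, 0.15, 0.08),
    "mmsetotal": (0.70, 0.18, 0.09, 0.03),
    "indepscl": (0.02, 0.08, 0.30, 0.60),
    "fiscore": (0.02, 0.05, 0.13, 0.30, 0.50),
    "tfcscore": (0.03, 0.12, 0.35, 0.50),
    "motscore": (0.45, 0.45, 0.07, 0.02, 0.01),
    "exfscore": (0.35, 0.30, 0.20, 0.10, 0.05),
    "aptscore": (0.35, 0.30, 0.20, 0.10, 0.05),
    "irascore": (0.35, 0.30, 0.20, 0.10, 0.05),
    "depscore": (0.35, 0.30, 0.20, 0.10, 0.05),
    "psyscore": (0.35, 0.30, 0.20, 0.10, 0.05),
    "sdmt1": (0.55, 0.20, 0.15, 0.10),
}


@dataclass(frozen=True)
class PlantedRule:
    """A forced antecedent -> weight-category dependency.

    ``antecedent`` is a set of (factor, category-code) pairs; every subject
    in the planted stratum receives those categories, and any subject whose
    factors match the full antecedent (planted or by chance) ends with a
    weight change in ``consequent_category`` with probability
    ``target_confidence``.
    """

    antecedent: frozenset[tuple[str, int]]
    consequent_category: int
    target_confidence: float = 0.95
    stratum_fraction: float = 0.15

    def __post_init__(self) -> None:
        factors = [f for f, _ in self.antecedent]
        if len(factors) != len(set(factors)):
            raise ConfigurationError("planted antecedent factors must be distinct")
        if not 0.0 < self.target_confidence <= 1.0:
            raise ConfigurationError("target_confidence must lie in (0, 1]")
        if not 0.0 < self.stratum_fraction <= 1.0:
            raise ConfigurationError("stratum_fraction must lie in (0, 1]")
        if not -3 <= self.consequent_category <= 3:
            raise ConfigurationError("consequent weight category must be in -3..+3")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator."""

    n_subjects: int = 1000
    group: str = "pMan"
    followup_range: tuple[int, int] = (3, 5)
    baseline_weight_mean: float = 75.0   # kg
    baseline_weight_sd: float = 12.0     # kg
    annual_drift_sd: float = 2.0         # percent per year
    factor_marginals: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS))
    planted_rules: tuple[PlantedRule, ...] = ()
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        lo, hi = self.followup_range
        if not (1 <= lo <= hi <= 10):
            raise ConfigurationError("followup_range must lie within [1, 10]")
        for name, rate in (("missing_rate", self.missing_rate),
                           ("outlier_rate", self.outlier_rate)):
            if not 0.0 <= rate < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        for factor, probs in self.factor_marginals.items():
            p = np.asarray(probs, dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"marginal for {factor!r} is not a probability vector")
        total = sum(r.stratum_fraction for r in self.planted_rules)
        if total > 1.0:
            raise ConfigurationError("planted stratum fractions exceed the cohort")


def _validate_against_scheme(config: GeneratorConfig, scheme: CategorizationScheme) -> None:
    for factor, probs in config.factor_marginals.items():
        if factor not in scheme.bins:
            raise ConfigurationError(f"marginal given for unknown factor {factor!r}")
        if len(probs) != len(scheme.bins[factor]):
            raise ConfigurationError(
                f"marginal for {factor!r} has {len(probs)} entries, "
                f"scheme declares {len(scheme.bins[factor])} categories")
    for rule in config.planted_rules:
        for factor, code in rule.antecedent:
            if factor not in scheme.bins or code not in scheme.codes(factor):
                raise ConfigurationError(
                    f"planted antecedent {factor}={code} is outside the scheme")
        if rule.consequent_category not in scheme.codes(WTCAT):
            raise ConfigurationError(
                f"planted consequent category {rule.consequent_category} unknown")


def _category_midpoint(scheme: CategorizationScheme, factor: str, code: int,
                       clip: float = 35.0) -> float:
    lo, hi = scheme.raw_interval(factor, code)
    lo = max(lo, -clip)
    hi = min(hi, clip)
    return (lo + hi) / 2.0


def generate_cohort(config: GeneratorConfig,
                    scheme: CategorizationScheme | None = None) -> pd.DataFrame:
    """Generate a longitudinal visit table for one study group.

    Returns a DataFrame with :data:`COHORT_COLUMNS`: one baseline row
    (``visit_seq`` 0) plus k annual follow-up rows per subject, k drawn
    uniformly from ``followup_range``.  Deterministic given the config seed.
    """
    if scheme is None:
        scheme = default_scheme()
    _validate_against_scheme(config, scheme)
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    lo_k, hi_k = config.followup_range
    n_followups = rng.integers(lo_k, hi_k + 1, size=n)

    # subject-level factor categories, planted strata forced
    codes_by_factor: dict[str, np.ndarray] = {}
    for factor in FACTORS:
        probs = np.asarray(config.factor_marginals.get(
            factor, DEFAULT_MARGINALS[factor]), dtype=float)
        codes = np.asarray(scheme.codes(factor))
        codes_by_factor[factor] = codes[rng.choice(len(probs), size=n, p=probs)]

    stratum = np.full(n, -1, dtype=int)
    order = rng.permutation(n)
    pos = 0
    for ri, rule in enumerate(config.planted_rules):
        m = int(round(rule.stratum_fraction * n))
        stratum[order[pos:pos + m]] = ri
        pos += m
    for ri, rule in enumerate(config.planted_rules):
        mask = stratum == ri
        for factor, code in rule.antecedent:
            codes_by_factor[factor][mask] = code

    # raw values: uniform integer within each category's raw interval
    raw_by_factor: dict[str, np.ndarray] = {}
    for factor in FACTORS:
        vals = np.empty(n)
        for code in scheme.codes(factor):
            mask = codes_by_factor[factor] == code
            if not mask.any():
                continue
            lo, hi = scheme.raw_interval(factor, code)
            vals[mask] = np.floor(rng.uniform(lo, hi, size=mask.sum()))
        raw_by_factor[factor] = vals

    # weight trajectories: baseline normal, i.i.d. multiplicative annual drift
    w_base = np.clip(rng.normal(config.baseline_weight_mean,
                                config.baseline_weight_sd, size=n), 40.0, None)
    max_k = int(n_followups.max())
    drift = rng.normal(0.0, config.annual_drift_sd / 100.0, size=(n, max_k))
    growth = np.cumprod(1.0 + drift, axis=1)
    weights = np.column_stack([w_base, w_base[:, None] * growth])  # (n, max_k+1)

    # planted consequents: any subject matching a full antecedent ends with a
    # weight change in the consequent category with the target confidence
    forced = np.zeros(n, dtype=bool)
    for rule in config.planted_rules:
        match = np.ones(n, dtype=bool)
        for factor, code in rule.antecedent:
            match &= codes_by_factor[factor] == code
        match &= ~forced
        hit = match & (rng.random(n) < rule.target_confidence)
        dw_mid = _category_midpoint(scheme, WTCAT, rule.consequent_category)
        idx = np.nonzero(hit)[0]
        weights[idx, n_followups[idx]] = w_base[idx] * (1.0 + dw_mid / 100.0)
        # the complement must not land in the consequent category by accident
        miss = np.nonzero(match & ~hit)[0]
        for i in miss:
            dw_nat = (weights[i, n_followups[i]] / w_base[i] - 1.0) * 100.0
            if scheme.code_for(WTCAT, dw_nat) == rule.consequent_category:
                weights[i, n_followups[i]] = w_base[i]
        forced |= match

    # assemble long table
    rows_per_subject = n_followups + 1
    total = int(rows_per_subject.sum())
    subj_idx = np.repeat(np.arange(n), rows_per_subject)
    seq = np.concatenate([np.arange(k + 1) for k in n_followups])
    table = pd.DataFrame({
        "subjid": np.char.add("S", np.char.zfill(
            subj_idx.astype(str), len(str(n)))),
        "group": config.group,
        "visit_type": np.where(seq == 0, "Baseline", "FollowUp"),
        "visit_seq": seq,
        "weight_kg": np.round(weights[subj_idx, seq], 2),
    })
    for factor in FACTORS:
        if factor == "age":
            # age increments annually; earlier visits floor at the adult minimum
            last_age = raw_by_factor["age"][subj_idx]
            table[factor] = np.maximum(last_age - (n_followups[subj_idx] - seq), 18)
        else:
            table[factor] = raw_by_factor[factor][subj_idx]

    if config.missing_rate > 0:
        mask = rng.random((total, len(FACTORS))) < config.missing_rate
        for j, factor in enumerate(FACTORS):
            table.loc[mask[:, j], factor] = np.nan

    if config.outlier_rate > 0:
        table = inject_outliers(table, config.outlier_rate,
                                config.outlier_magnitude,
                                seed=int(rng.integers(2**31)))
    return table


def inject_outliers(table: pd.DataFrame, rate: float, magnitude: float = 5.0,
                    seed: int = 0) -> pd.DataFrame:
    """Displace a seeded random subset of factor cells beyond the Tukey fences.

    Each selected cell is moved above Q3 + 1.5*IQR of its (input) column by
    ``magnitude`` times the column's IQR (or 1 raw unit when the IQR is 0).
    Returns a new table; the input is unmodified.
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigurationError("outlier rate must lie in [0, 1)")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    for factor in FACTORS:
        col = out[factor].astype(float)
        present = col.notna().to_numpy()
        q1, q3 = np.nanpercentile(col.to_numpy(dtype=float), [25, 75])
        iqr = q3 - q1
        hit = present & (rng.random(len(out)) < rate)
        out.loc[hit, factor] = q3 + 1.5 * iqr + magnitude * max(iqr, 1.0)
    return out


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV with the canonical column order."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"cohort table lacks required column(s): {missing}")
    table.loc[:, COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, checking the required columns are present."""
    table = pd.read_csv(path, dtype={"subjid": str})
    for col in COHORT_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"cohort file {path} is missing column {col!r}")
    return table[list(COHORT_COLUMNS)]
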