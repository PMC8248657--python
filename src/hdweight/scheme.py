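"""Expert-knowledge categorization of clinical scores into ordinal codes.

Raw clinical scores (functional capacity, independence, psychiatric
inventories, cognitive tests) and the percentage weight change ``delta_w``
are mapped onto small ordinal scales agreed with clinical domain experts.
Each factor has an ordered list of intervals on its raw scale; each interval
carries an integer category code and a severity label.  The weight-change
variable ``wtCat`` spans -3 (very severe loss, more than 20% of body weight)
through 0 (stable, within 5%) to +3 (very severe gain), with gain categories
mirroring the loss breakpoints symmetrically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Clinical factor columns, in canonical cohort-file order.
FACTORS: tuple[str, ...] = (
    "age",
    "mmsetotal",
    "indepscl",
    "fiscore",
    "tfcscore",
    "motscore",
    "exfscore",
    "aptscore",
    "irascore",
    "depscore",
    "psyscore",
    "sdmt1",
)

#: Name of the weight-change category variable.
WTCAT = "wtCat"


class CategorizationError(ValueError):
    """A raw value falls outside every interval declared for its factor."""


@dataclass(frozen=True)
class CategoryBin:
    """One interval of a factor's raw scale with its ordinal code.

    ``lo``/``hi`` bound the interval; ``lo_incl``/``hi_incl`` state whether
    each endpoint belongs to it.  The default is the half-open convention
    [lo, hi) used by every factor except ``wtCat``, whose boundary values
    belong to the more severe (larger magnitude) side.
    """

    lo: float
    hi: float
    code: int
    label: str = ""
    lo_incl: bool = True
    hi_incl: bool = False

    def contains(self, value: float) -> bool:
        above = value > self.lo or (self.lo_incl and value == self.lo)
        below = value < self.hi or (self.hi_incl and value == self.hi)
        return above and below


@dataclass
class CategorizationScheme:
    """Per-factor interval tables mapping raw scores to ordinal codes."""

    bins: dict[str, list[CategoryBin]] = field(default_factory=dict)
    #: declared raw range per factor, used for validation and for bounding
    #: open-ended intervals when sampling raw values from a category.
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for factor, fbins in self.bins.items():
            codes = [b.code for b in fbins]
            if len(codes) != len(set(codes)):
                raise ValueError(f"duplicate category codes for factor {factor!r}")

    @property
    def factors(self) -> list[str]:
        return list(self.bins)

    def code_for(self, factor: str, value: float) -> int:
        """Ordinal code of ``value`` on ``factor``'s raw scale."""
        try:
            fbins = self.bins[factor]
        except KeyError:
            raise KeyError(f"unknown factor {factor!r}") from None
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise CategorizationError(f"missing value for factor {factor!r}")
        for b in fbins:
            if b.contains(value):
                return b.code
        raise CategorizationError(
            f"value {value!r} of factor {factor!r} lies outside every declared interval"
        )

    def raw_interval(self, factor: str, code: int) -> tuple[float, float]:
        """Closed-open representative interval [lo, hi) of a category.

        Open-ended bins are clipped to the factor's declared range.  Any raw
        value drawn uniformly from the returned interval categorizes back to
        ``code`` (the round-trip property the synthetic planter relies on).
        """
        for b in self.bins[factor]:
            if b.code == code:
                lo_r, hi_r = self.ranges.get(factor, (-math.inf, math.inf))
                lo = b.lo if math.isfinite(b.lo) else lo_r
                hi = b.hi if math.isfinite(b.hi) else hi_r
                if not b.lo_incl:
                    # shift strictly inside an open lower endpoint
                    lo = math.nextafter(lo, math.inf)
                return (lo, hi)
        raise KeyError(f"factor {factor!r} has no category {code}")

    def codes(self, factor: str) -> list[int]:
        return [b.code for b in self.bins[factor]]

    def labels(self, factor: str) -> dict[int, str]:
        return {b.code: b.label for b in self.bins[factor]}

    def validate(self) -> None:
        """Check that each factor's intervals are disjoint and cover its range."""
        for factor, fbins in self.bins.items():
            lo_r, hi_r = self.ranges.get(factor, (-math.inf, math.inf))
            probe_points: list[float] = []
            for b in fbins:
                for edge in (b.lo, b.hi):
                    if math.isfinite(edge):
                        probe_points += [edge, math.nextafter(edge, -math.inf),
                                         math.nextafter(edge, math.inf)]
                if math.isfinite(b.lo) and math.isfinite(b.hi):
                    probe_points.append((b.lo + b.hi) / 2)
            probe_points += [lo_r] if math.isfinite(lo_r) else []
            probe_points += [hi_r] if math.isfinite(hi_r) else []
            for x in probe_points:
                if not (lo_r <= x <= hi_r):
                    continue
                hits = [b.code for b in fbins if b.contains(x)]
                if len(hits) != 1:
                    raise ValueError(
                        f"factor {factor!r}: value {x} matched {len(hits)} intervals"
                    )

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "ranges": {f: list(r) for f, r in self.ranges.items()},
            "bins": {
                f: [
                    {
                        "lo": b.lo if math.isfinite(b.lo) else str(b.lo),
                        "hi": b.hi if math.isfinite(b.hi) else str(b.hi),
                        "code": b.code,
                        "label": b.label,
                        "lo_incl": b.lo_incl,
                        "hi_incl": b.hi_incl,
                    }
                    for b in fbins
                ]
                for f, fbins in self.bins.items()
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CategorizationScheme":
        payload = json.loads(text)
        bins = {
            f: [
                CategoryBin(
                    lo=float(d["lo"]),
                    hi=float(d["hi"]),
                    code=int(d["code"]),
                    label=d.get("label", ""),
                    lo_incl=bool(d.get("lo_incl", True)),
                    hi_incl=bool(d.get("hi_incl", False)),
                )
                for d in fbins
            ]
            for f, fbins in payload["bins"].items()
        }
        ranges = {f: (float(r[0]), float(r[1])) for f, r in payload["ranges"].items()}
        return cls(bins=bins, ranges=ranges)


def _severity_bins(edges_labels: Iterable[tuple[float, float, int, str]]) -> list[CategoryBin]:
    return [CategoryBin(lo, hi, code, label) for lo, hi, code, label in edges_labels]


def default_scheme() -> CategorizationScheme:
    """The expert categorization used throughout the analysis.

    Integer-scored inventories (exfscore, aptscore, irascore, depscore,
    psyscore) share the layout 0 / 1-4 / 5-8 / 9-12 / >12.  Cognitive tests
    (mmsetotal, sdmt1) are reverse-scored: lower raw values mean worse
    performance, hence higher severity codes.  The raw value 26 of sdmt1,
    which falls between the printed 0-25 and 27-34 ranges, is absorbed by
    the lower (more severe) range.  wtCat boundaries at exactly -20/-10/-5 %
    belong to the more severe loss category; gains mirror losses.
    """
    inf = math.inf
    inv = lambda: _severity_bins([
        (0, 1, 0, "normal"),
        (1, 5, 1, "mild"),
        (5, 9, 2, "moderate"),
        (9, 13, 3, "severe"),
        (13, inf, 4, "very severe"),
    ])
    bins = {
        "age": _severity_bins([
            (18, 30, 0, "<30"),
            (30, 40, 1, "30-39"),
            (40, 50, 2, "40-49"),
            (50, 60, 3, "50-59"),
            (60, 70, 4, "60-69"),
            (70, inf, 5, ">=70"),
        ]),
        "mmsetotal": _severity_bins([
            (25, inf, 0, "normal"),
            (20, 25, 1, "mild"),
            (10, 20, 2, "moderate"),
            (0, 10, 3, "severe"),
        ]),
        "indepscl": _severity_bins([
            (0, 41, 0, "severe"),
            (41, 81, 1, "moderate"),
            (81, 96, 2, "mild"),
            (96, inf, 3, "normal"),
        ]),
        "fiscore": _severity_bins([
            (0, 6, 0, "very severe"),
            (6, 11, 1, "severe"),
            (11, 16, 2, "moderate"),
            (16, 21, 3, "mild"),
            (21, inf, 4, "normal"),
        ]),
        "tfcscore": _severity_bins([
            (0, 6, 0, "severe"),
            (6, 9, 1, "moderate"),
            (9, 13, 2, "mild"),
            (13, inf, 3, "normal"),
        ]),
        "motscore": _severity_bins([
            (0, 1, 0, "normal"),
            (1, 32, 1, "mild"),
            (32, 63, 2, "moderate"),
            (63, 94, 3, "severe"),
            (94, inf, 4, "very severe"),
        ]),
        "exfscore": inv(),
        "aptscore": inv(),
        "irascore": inv(),
        "depscore": inv(),
        "psyscore": inv(),
        "sdmt1": _severity_bins([
            (43, inf, 0, "normal"),
            (35, 43, 1, "mild"),
            (27, 35, 2, "moderate"),
            (0, 27, 3, "severe"),
        ]),
        WTCAT: [
            CategoryBin(-inf, -20, -3, "very severe loss", hi_incl=True),
            CategoryBin(-20, -10, -2, "severe loss", lo_incl=False, hi_incl=True),
            CategoryBin(-10, -5, -1, "moderate loss", lo_incl=False, hi_incl=True),
            CategoryBin(-5, 5, 0, "stable", lo_incl=False, hi_incl=False),
            CategoryBin(5, 10, 1, "moderate gain"),
            CategoryBin(10, 20, 2, "severe gain"),
            CategoryBin(20, inf, 3, "very severe gain"),
        ],
    }
    ranges = {
        "age": (18.0, 100.0),
        "mmsetotal": (0.0, 30.0),
        "indepscl": (0.0, 100.0),
        "fiscore": (0.0, 25.0),
        "tfcscore": (0.0, 13.0),
        "motscore": (0.0, 124.0),
        "exfscore": (0.0, 16.0),
        "aptscore": (0.0, 16.0),
        "irascore": (0.0, 16.0),
        "depscore": (0.0, 16.0),
        "psyscore": (0.0, 16.0),
        "sdmt1": (0.0, 110.0),
        WTCAT: (-100.0, 200.0),
    }
    return CategorizationScheme(bins=bins, ranges=ranges)


def categorize(records: pd.DataFrame, scheme: CategorizationScheme | None = None) -> pd.DataFrame:
    """Transform consolidated subject records into the categorical knowledge base.

    ``records`` carries one row per subject with raw factor values and the
    percentage weight change in a ``delta_w`` column.  Returns a DataFrame of
    integer codes with columns ``subjid``, ``group``, the factor columns
    present in the input, and ``wtCat`` derived from ``delta_w``.

    Raises :class:`CategorizationError` if any value falls outside its
    factor's declared intervals (the error names factor and value).
    """
    if scheme is None:
        scheme = default_scheme()
    out = pd.DataFrame(index=records.index)
    for meta in ("subjid", "group"):
        if meta in records.columns:
            out[meta] = records[meta]
    for factor in scheme.factors:
        if factor == WTCAT:
            continue
        if factor not in records.columns:
            continue
        out[factor] = [
            scheme.code_for(factor, v) for v in records[factor].astype(float)
        ]
    if "delta_w" in records.columns:
        out[WTCAT] = [scheme.code_for(WTCAT, v) for v in records["delta_w"].astype(float)]
    code_cols = [c for c in out.columns if c not in ("subjid", "group")]
    out[code_cols] = out[code_cols].astype(np.int64)
    return out


def category_density(dataset: pd.DataFrame, factor: str,
                     scheme: CategorizationScheme | None = None,
                     by_group: bool = False) -> pd.DataFrame | pd.Series:
    """Normalised per-category frequencies of a categorized factor.

    With ``by_group`` the frequencies are computed within each ``group``
    label separately (each group's frequencies sum to 1).  Categories with
    zero observations are reported as 0 when a scheme declares them.
    """
    if factor not in dataset.columns:
        raise KeyError(f"unknown factor {factor!r}")
    if len(dataset) == 0:
        raise ValueError("cannot compute category density of an empty dataset")
    if scheme is not None:
        cats = sorted(scheme.codes(factor))
    else:
        cats = sorted(dataset[factor].unique())

    def _freq(col: pd.Series) -> pd.Series:
        counts = col.value_counts().reindex(cats, fill_value=0)
        return counts / counts.sum()

    if by_group and "group" in dataset.columns:
        return dataset.groupby("group")[factor].apply(_freq).unstack(fill_value=0.0)
    return _freq(dataset[factor])
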