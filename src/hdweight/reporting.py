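"""Human-readable exports of mined rules and antecedent histograms."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .rules import ClassRule, antecedent_histogram, rules_from_frame, rules_to_frame

_METRIC_COLUMNS = ("support", "confidence", "lift", "conviction", "chi2",
                   "p_value", "strength")


def export_rule_report(rules: Iterable[ClassRule], path, format: str = "csv") -> None:
    """Write a rule table (CSV or JSON) plus a min/max metrics summary.

    The JSON rendering round-trips through :func:`load_rule_report`; the CSV
    rendering appends a summary block as ``# key=value`` comment lines.
    Infinite conviction/strength serialize as the token ``inf``.
    """
    frame = rules_to_frame(rules)
    summary = {}
    if len(frame):
        for col in _METRIC_COLUMNS:
            summary[f"min_{col}"] = float(frame[col].min())
            summary[f"max_{col}"] = float(frame[col].max())
    path = Path(path)
    if format == "csv":
        with open(path, "w") as fh:
            frame.to_csv(fh, index=False)
            for key, value in summary.items():
                fh.write(f"# {key}={value}\n")
    elif format == "json":
        payload = {"rules": frame.to_dict(orient="records"), "summary": summary}
        path.write_text(json.dumps(payload, indent=1, default=str))
    else:
        raise ValueError(f"unknown rule report format {format!r}")


def load_rule_report(path) -> list[ClassRule]:
    """Read back a JSON rule report written by :func:`export_rule_report`."""
    payload = json.loads(Path(path).read_text())
    frame = pd.DataFrame(payload["rules"],
                         columns=rules_to_frame([]).columns)
    return rules_from_frame(frame) if len(frame) else []


def export_histogram_report(rules: Iterable[ClassRule], path) -> pd.DataFrame:
    """Tidy per-item antecedent counts: columns factor, category, count."""
    hist = antecedent_histogram(rules)
    rows = [{"factor": item.factor, "category": item.category, "count": count}
            for item, count in sorted(hist.items())]
    frame = pd.DataFrame(rows, columns=["factor", "category", "count"])
    frame.to_csv(path, index=False)
    return frame
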