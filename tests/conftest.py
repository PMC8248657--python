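import numpy as np
import pandas as pd
import pytest

import hdweight as hw
from hdweight.scheme import FACTORS


def make_visit_rows(subjid, weights, factor_value=2.0, group="pMan"):
    """One baseline plus follow-ups with the given weights; constant factors."""
    rows = []
    for seq, w in enumerate(weights):
        row = {"subjid": subjid, "group": group,
               "visit_type": "Baseline" if seq == 0 else "FollowUp",
               "visit_seq": seq, "weight_kg": w}
        for f in FACTORS:
            row[f] = 30.0 if f == "age" else factor_value
        rows.append(row)
    return rows


@pytest.fixture(scope="session")
def small_cohort():
    return hw.generate_cohort(hw.GeneratorConfig(n_subjects=100, seed=7))


@pytest.fixture(scope="session")
def planted_cohort():
    rule = hw.PlantedRule(
        antecedent=frozenset({("tfcscore", 1), ("irascore", 4)}),
        consequent_category=-3, target_confidence=0.95, stratum_fraction=0.15)
    return hw.generate_cohort(
        hw.GeneratorConfig(n_subjects=2000, planted_rules=(rule,), seed=11))


@pytest.fixture(scope="session")
def planted_kb(planted_cohort):
    records, _ = hw.preprocess(planted_cohort)
    return hw.categorize(records)


@pytest.fixture(scope="session")
def scheme():
    return hw.default_scheme()
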