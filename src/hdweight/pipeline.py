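"""End-to-end orchestration: generate -> preprocess -> categorize -> mine -> som -> info.

The two study groups (premanifest and family control) run as independent
pipeline instances distinguished by the ``group`` column; one global seed
deterministically derives every per-group, per-stage random stream.  A run
manifest records the record accounting (rows in, rows dropped, subjects
retained, rules before/after pruning) and the parameter echo.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import information, reporting, rules as rm, som as som_mod
from .preprocess import DEFAULT_OUTLIER_FACTORS, preprocess as preprocess_cohort
from .scheme import WTCAT, categorize, default_scheme
from .synthetic import GeneratorConfig, PlantedRule, generate_cohort, write_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "hdweight_out"
    groups: tuple[str, ...] = ("pMan", "fCont")
    input_path: str | None = None          # read a cohort CSV instead of generating
    generator: dict[str, Any] = field(default_factory=dict)
    outlier_factors: tuple[str, ...] = DEFAULT_OUTLIER_FACTORS
    factors_from: str = "last_followup"
    consequents: tuple[int, ...] = (-3, -2)
    min_confidence: float = 0.9
    min_len: int = 2
    max_len: int = 5
    min_support: float = 0.01
    prune_redundant: bool = True
    run_som: bool = True
    som: dict[str, Any] = field(default_factory=dict)
    run_info: bool = True
    info_combos: tuple[tuple[str, ...], ...] = ()

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        return cls.from_mapping(payload)

    @classmethod
    def from_mapping(cls, payload: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown pipeline config key(s): {sorted(unknown)}")
        kwargs = dict(payload)
        for key in ("groups", "outlier_factors", "consequents"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "info_combos" in kwargs:
            kwargs["info_combos"] = tuple(tuple(c) for c in kwargs["info_combos"])
        return cls(**kwargs)


def _generator_config(config: PipelineConfig, group: str, seed: int) -> GeneratorConfig:
    kwargs = dict(config.generator)
    planted = []
    for spec in kwargs.pop("planted_rules", []):
        planted.append(PlantedRule(
            antecedent=frozenset((f, int(c)) for f, c in spec["antecedent"].items()),
            consequent_category=int(spec["consequent_category"]),
            target_confidence=float(spec.get("target_confidence", 0.95)),
            stratum_fraction=float(spec.get("stratum_fraction", 0.15))))
    kwargs.setdefault("n_subjects", 1000)
    if "followup_range" in kwargs:
        kwargs["followup_range"] = tuple(kwargs["followup_range"])
    return GeneratorConfig(group=group, planted_rules=tuple(planted),
                           seed=seed, **kwargs)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every enabled stage for each group and write all artifacts.

    Returns the run manifest (also written to ``<out_dir>/manifest.json``).
    Re-running with an identical config reproduces identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = default_scheme()
    manifest: dict[str, Any] = {"seed": config.seed,
                                "config": dataclasses.asdict(config),
                                "groups": {}}
    if config.input_path:
        from .synthetic import read_cohort
        full_table = read_cohort(config.input_path)
    else:
        full_table = None

    for gi, group in enumerate(config.groups):
        gdir = out_dir / group
        gdir.mkdir(exist_ok=True)
        group_seed = config.seed * 1000 + gi
        if full_table is not None:
            table = full_table[full_table["group"] == group].reset_index(drop=True)
        else:
            table = generate_cohort(_generator_config(config, group, group_seed),
                                    scheme)
            write_cohort(table, gdir / "cohort.csv")

        records, report = preprocess_cohort(table, config.outlier_factors,
                                            config.factors_from)
        records.to_csv(gdir / "records.csv", index=False)
        kb = categorize(records, scheme)
        kb.to_csv(gdir / "kb.csv", index=False)

        gman: dict[str, Any] = {
            "rows_in": report.rows_in,
            "rows_dropped_missing": report.rows_dropped_missing,
            "rows_dropped_outlier": report.rows_dropped_outlier,
            "subjects_in": report.subjects_in,
            "subjects_excluded": report.subjects_excluded,
            "subjects_retained": report.subjects_retained,
            "rules": {},
        }
        all_rules: list[rm.ClassRule] = []
        for cat in config.consequents:
            mined = rm.mine_class_rules(
                kb, rm.Item(WTCAT, cat),
                min_confidence=config.min_confidence, min_len=config.min_len,
                max_len=config.max_len, min_support=config.min_support)
            pruned = rm.eliminate_redundant(mined) if config.prune_redundant else mined
            gman["rules"][str(cat)] = {"mined": len(mined), "retained": len(pruned)}
            reporting.export_rule_report(pruned, gdir / f"rules_wtCat{cat}.csv", "csv")
            reporting.export_rule_report(pruned, gdir / f"rules_wtCat{cat}.json", "json")
            all_rules.extend(pruned)
        reporting.export_histogram_report(all_rules, gdir / "antecedent_histogram.csv")

        if config.run_som and len(kb) >= 16:
            som_cfg = som_mod.SOMConfig(seed=group_seed + 1, **config.som)
            model = som_mod.train_som(kb, som_cfg)
            som_mod.count_plot(model, kb).to_csv(gdir / "som_counts.csv", index=False)
            som_mod.codes_profile(model).to_csv(gdir / "som_codes.csv", index=False)
            som_mod.node_class_distribution(model, kb).to_csv(
                gdir / "som_class_distribution.csv")
            (gdir / "som_model.json").write_text(
                json.dumps(model.to_json_dict(), indent=1))
            gman["som_quantization_error"] = model.qe_trace[-1]

        if config.run_info:
            info = information.dependence_report(
                kb, target=WTCAT, combos=config.info_combos)
            info.to_csv(gdir / "dependence.csv", index=False)

        manifest["groups"][group] = gman

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
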