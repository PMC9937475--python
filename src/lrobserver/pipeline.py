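"""End-to-end experiment orchestration: fit on construction cohorts,
evaluate on a held-out test cohort, emit model and report documents.

Cohort sources are either CSV paths or ``simulate:`` recipe references
(``simulate:adni_like`` / ``simulate:miriad_like``), so the full experiment
runs with no external data.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import (
    CohortTable,
    Group,
    MeasureSpec,
    NAMED_MEASURES,
    concat_cohorts,
    load_cohort_csv,
)
from .densities import fit_gaussian
from .errors import ComparabilityError, ConfigError
from .morphometry import asymmetry_summary, format_p, mean_percent_asymmetry
from .observer import LRObserverModel, classify, save_model
from .roc import (
    ClassificationReport,
    auc_confidence_interval,
    binormal_az,
    empirical_roc,
    evaluate_at_zero_threshold,
)
from .cohort import Region
from . import synthetic

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    train_ad_path: str
    train_nc_path: str
    test_path: str
    measures: list[str] = field(default_factory=lambda: ["mtl", "hippocampus"])
    density_backend: str = "gaussian"
    output_dir: str = "lrobserver_out"
    seed: int = synthetic.DEFAULT_SEED
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.measures:
            raise ConfigError("at least one measure is required")
        unknown = [m for m in self.measures if m not in NAMED_MEASURES]
        if unknown:
            raise ConfigError(f"unknown measure name(s) {unknown}; "
                              f"known: {sorted(NAMED_MEASURES)}")
        if self.density_backend != "gaussian":
            raise ConfigError("only the gaussian backend is supported by run_experiment")

    @staticmethod
    def from_file(path: str | Path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return RunConfig(**doc)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


def _resolve_source(source: str, seed: int) -> CohortTable:
    if source.startswith("simulate:"):
        name = source.removeprefix("simulate:")
        recipe = synthetic.default_recipe(name, seed=seed)
        return synthetic.generate_cohort(recipe)
    path = Path(source)
    if not path.exists():
        raise ConfigError(f"cohort source not found: {source}")
    return load_cohort_csv(path)


def load_train_cohort(config: RunConfig) -> CohortTable:
    """The construction cohort: either one source with both groups, or an
    AD source and an NC source merged."""
    if config.train_ad_path == config.train_nc_path:
        return _resolve_source(config.train_ad_path, config.seed)
    ad = _resolve_source(config.train_ad_path, config.seed)
    nc = _resolve_source(config.train_nc_path, config.seed + 1)
    return concat_cohorts(
        [ad.filter_group(Group.AD), nc.filter_group(Group.NC)], provenance="train"
    )


def run_experiment(config: RunConfig) -> dict:
    """Fit, evaluate and summarize; returns (and writes) the report document.

    For each measure: Gaussian densities fitted per group on the construction
    cohort, model JSON written, binormal Az computed, and on the test cohort
    the empirical ROC (with AUC and Hanley-McNeil CI) plus the y=0
    sensitivity/specificity report.  A hippocampal asymmetry summary of the
    construction cohort is included.  All randomness derives from config.seed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    train = load_train_cohort(config)
    test = _resolve_source(config.test_path, config.seed + 2)
    logger.info(
        "train cohort: %d subjects %s; test cohort: %d subjects %s; seed=%d; backend=%s",
        len(train), {g.value: n for g, n in train.group_counts().items() if n},
        len(test), {g.value: n for g, n in test.group_counts().items() if n},
        config.seed, config.density_backend,
    )

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "backend": config.density_backend,
        "train_provenance": train.provenance,
        "test_provenance": test.provenance,
        "n_train": {g.value: n for g, n in train.group_counts().items()},
        "n_test": {g.value: n for g, n in test.group_counts().items()},
        "measures": {},
    }

    for name in config.measures:
        measure = NAMED_MEASURES[name]
        logger.info("measure %s: fitting on %d train subjects", name, len(train))
        f_d = fit_gaussian(train.measure_values(measure, Group.AD))
        f_n = fit_gaussian(train.measure_values(measure, Group.NC))
        model = LRObserverModel(normal_density=f_n, diseased_density=f_d, measure=measure)
        model_path = out_dir / f"model_{name}.json"
        save_model(model, model_path, provenance=train.provenance)

        scores = [classify(model, rec).y for rec in test]
        labels = [rec.group for rec in test]
        curve = empirical_roc(scores, labels)
        ci = auc_confidence_interval(curve)
        cls = evaluate_at_zero_threshold(model, test)
        pd.DataFrame({"fpr": curve.fpr, "tpr": curve.tpr}).to_csv(
            out_dir / f"roc_{name}.csv", index=False
        )
        report["measures"][name] = {
            "model_file": model_path.name,
            "mu_nc": f_n.mu, "sigma_nc": f_n.sigma,
            "mu_ad": f_d.mu, "sigma_ad": f_d.sigma,
            "binormal_az": binormal_az(f_n, f_d),
            "test_auc": curve.auc,
            "test_auc_ci95": list(ci),
            "classification": cls.as_dict(),
        }

    summaries = asymmetry_summary(train, Region.HIPPOCAMPUS)
    report["hippocampal_asymmetry"] = {
        g.value: {
            "n": s.n,
            "mean_left_mm3": s.mean_left,
            "mean_right_mm3": s.mean_right,
            "mean_diff_mm3": s.mean_diff,
            "sd_diff_mm3": s.sd_diff,
            "percent_asymmetry": s.percent_asymmetry,
            "pearson_r": s.pearson_r,
            "p_value_display": format_p(s.p_value),
        }
        for g, s in summaries.items()
    }
    report["hippocampal_asymmetry"]["mean_percent_asymmetry"] = mean_percent_asymmetry(
        summaries
    )

    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def improvement_over_baseline(
    report_a: ClassificationReport, report_b: ClassificationReport
) -> float:
    """Balanced-accuracy gain of a over b, in percentage points.

    Equals the mean of the sensitivity and specificity gains.  Both reports
    must come from the same test cohort (identical class counts).
    """
    if (report_a.n_pos, report_a.n_neg) != (report_b.n_pos, report_b.n_neg):
        raise ComparabilityError(
            "reports have different class counts; not the same test cohort"
        )
    return 100.0 * (report_a.balanced_accuracy - report_b.balanced_accuracy)
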