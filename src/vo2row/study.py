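"""End-to-end two-part study orchestration.

Part 1 (development): fit sex-specific VO2max prediction equations by
stepwise regression on the development cohorts and report in-sample
agreement between measured VO2max and the fitted values.  Part 2
(external validation): apply equations — the frozen published ones or
the freshly fitted ones — to the held-out validation cohorts and report
agreement between measured and predicted values, including a
Kolmogorov–Smirnov comparison of the two distributions.

Cohorts are either loaded from CSV files or synthesised; the initial
pools are split by matched random hold-out allocation.  All randomness
flows from a single top-level seed split into named substreams
(generation and allocation, per sex), so each stage can be re-run in
isolation and the whole study is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

from . import __version__
from .agreement import AgreementReport, MethodPairs, build_agreement_report
from .allocation import AllocationResult, allocate_matched, split_cohort
from .cohort import Cohort, read_cohort
from .regression import (
    CANDIDATE_ORDER,
    PredictionEquation,
    RegressionFit,
    frozen_equation,
    predict_cohort,
    stepwise_ols,
)
from .simulate import CohortSpec, generate_cohort

__all__ = [
    "StudyConfig",
    "StudyReport",
    "prepare_cohorts",
    "run_part1",
    "run_part2",
    "run_study",
    "render_report",
]

log = logging.getLogger(__name__)

SEXES = ("male", "female")

#: published initial pool sizes per sex (before hold-out allocation)
DEFAULT_POOL_SIZES = {"male": 119, "female": 96}


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to re-run a study bit-identically.

    ``cohorts`` maps each sex to either a :class:`CohortSpec` (synthetic
    input) or a CSV path (real input).  When omitted, default synthetic
    pools of 119 boys and 96 girls are generated with the reference
    moments and R²-calibrated noise, seeded from ``seed``.
    """

    seed: int = 0
    cohorts: Optional[Mapping[str, Union[CohortSpec, str, Path]]] = None
    k: int = 13
    alpha: float = 0.05
    matching_vars: tuple[str, ...] = ("lean_body_mass", "fat_pct")
    max_iter: int = 10_000
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10
    candidates: tuple[str, ...] = CANDIDATE_ORDER
    equation_source: str = "frozen-published"  # or "fit-from-development"
    sel_variant: str = "limit-se"

    def __post_init__(self) -> None:
        if self.equation_source not in ("frozen-published", "fit-from-development"):
            raise ValueError(
                f"equation_source must be 'frozen-published' or "
                f"'fit-from-development', got {self.equation_source!r}"
            )

    def echo(self) -> dict:
        """JSON-native description sufficient to re-run the study."""
        sources = {}
        for sex in SEXES:
            src = (self.cohorts or {}).get(sex)
            if src is None:
                sources[sex] = {"kind": "default-synthetic"}
            elif isinstance(src, CohortSpec):
                d = dataclasses.asdict(src)
                d["predictor_moments"] = {
                    k: list(v) for k, v in d["predictor_moments"].items()
                }
                sources[sex] = {"kind": "synthetic", "spec": d}
            else:
                sources[sex] = {"kind": "file", "path": str(src)}
        return {
            "seed": self.seed,
            "cohorts": sources,
            "k": self.k,
            "alpha": self.alpha,
            "matching_vars": list(self.matching_vars),
            "max_iter": self.max_iter,
            "alpha_enter": self.alpha_enter,
            "alpha_remove": self.alpha_remove,
            "candidates": list(self.candidates),
            "equation_source": self.equation_source,
            "sel_variant": self.sel_variant,
        }


def _substream_seeds(seed: int) -> dict[str, int]:
    """Named integer sub-seeds derived from the top-level seed."""
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("generate-male", "generate-female", "allocate-male", "allocate-female")
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % 2**31)
        for name, child in zip(names, children)
    }


def prepare_cohorts(
    config: StudyConfig,
) -> dict[str, tuple[Cohort, Cohort, AllocationResult]]:
    """Obtain per-sex (development, validation, allocation) triples."""
    seeds = _substream_seeds(config.seed)
    out = {}
    for sex in SEXES:
        src = (config.cohorts or {}).get(sex)
        if src is None:
            src = CohortSpec(sex=sex, n=DEFAULT_POOL_SIZES[sex])
        if isinstance(src, CohortSpec):
            if src.seed is None:
                src = dataclasses.replace(src, seed=seeds[f"generate-{sex}"])
            pool = generate_cohort(src, label=f"{sex}-pool")
        else:
            pool = read_cohort(src, label=f"{sex}-pool")
        alloc = allocate_matched(
            pool,
            k=config.k,
            matching_vars=config.matching_vars,
            alpha=config.alpha,
            seed=seeds[f"allocate-{sex}"],
            max_iter=config.max_iter,
        )
        dev, val = split_cohort(pool, alloc)
        out[sex] = (dev, val, alloc)
    return out


def _fit_development(config: StudyConfig, dev: Cohort, sex: str) -> RegressionFit:
    return stepwise_ols(
        dev,
        response="vo2max_measured",
        candidates=config.candidates,
        alpha_enter=config.alpha_enter,
        alpha_remove=config.alpha_remove,
        sex=sex,
    )


def _agreement(measured, predicted, label, sel_variant) -> AgreementReport:
    pairs = MethodPairs(measured=measured, predicted=predicted, label=label)
    return build_agreement_report(pairs, sel_variant=sel_variant)


def run_part1(
    config: StudyConfig,
    cohorts: Optional[dict[str, tuple[Cohort, Cohort, AllocationResult]]] = None,
) -> tuple[dict[str, RegressionFit], dict[str, AgreementReport]]:
    """Equation development with in-sample (internal) validation.

    Per sex: stepwise fit on the development cohort, then an agreement
    report of measured VO2max against the model's in-sample fitted
    values.  A stepwise run that selects nothing yields the
    intercept-only fit with a warning.
    """
    cohorts = cohorts or prepare_cohorts(config)
    fits, reports = {}, {}
    for sex in SEXES:
        dev, _, _ = cohorts[sex]
        if len(dev) < 10:
            raise ValueError(f"development cohort for {sex} has <10 records")
        fit = _fit_development(config, dev, sex)
        if not fit.selected:
            log.warning("stepwise selected no predictors for %s; intercept-only", sex)
            fitted = np.full(len(dev), fit.equation.intercept)
        else:
            fitted = predict_cohort(fit.equation, dev)
        fits[sex] = fit
        reports[sex] = _agreement(
            dev.values("vo2max_measured"), fitted, f"{sex}-development",
            config.sel_variant,
        )
    return fits, reports


def run_part2(
    config: StudyConfig,
    equations: Mapping[str, PredictionEquation],
    cohorts: Optional[dict[str, tuple[Cohort, Cohort, AllocationResult]]] = None,
) -> dict[str, AgreementReport]:
    """External validation of supplied equations on the hold-out cohorts."""
    cohorts = cohorts or prepare_cohorts(config)
    reports = {}
    for sex in SEXES:
        _, val, _ = cohorts[sex]
        eq = equations[sex]
        if eq.sex != sex:
            raise ValueError(f"equation for sex {eq.sex!r} applied to {sex} cohort")
        predicted = predict_cohort(eq, val)
        reports[sex] = _agreement(
            val.values("vo2max_measured"), predicted, f"{sex}-validation",
            config.sel_variant,
        )
    return reports


@dataclass(frozen=True)
class StudyReport:
    """JSON-native record of a complete two-part study run."""

    per_sex: dict
    config: dict
    version: str

    def to_dict(self) -> dict:
        return {"per_sex": self.per_sex, "config": self.config, "version": self.version}

    @classmethod
    def from_dict(cls, payload: dict) -> "StudyReport":
        return cls(
            per_sex=payload["per_sex"],
            config=payload["config"],
            version=payload["version"],
        )


def _fit_dict(fit: RegressionFit) -> dict:
    return {
        "equation": {
            "sex": fit.equation.sex,
            "intercept": fit.equation.intercept,
            "terms": [[n, c] for n, c in fit.equation.terms],
            "provenance": fit.equation.provenance,
        },
        "r": fit.r,
        "r_squared": fit.r_squared,
        "f_statistic": fit.f_statistic,
        "df": list(fit.df),
        "p_value": fit.p_value,
        "residual_sd": fit.residual_sd,
        "selected": list(fit.selected),
        "candidate_pool": list(fit.candidate_pool),
        "n": fit.n,
    }


def _pairs_dict(cohort: Cohort, predicted: np.ndarray) -> dict:
    return {
        "athlete_id": list(cohort.ids()),
        "measured": [float(v) for v in cohort.values("vo2max_measured")],
        "predicted": [float(v) for v in predicted],
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Run both parts end to end and assemble the structured report."""
    cohorts = prepare_cohorts(config)
    fits, dev_reports = run_part1(config, cohorts)
    if config.equation_source == "frozen-published":
        equations = {sex: frozen_equation(sex) for sex in SEXES}
    else:
        equations = {sex: fits[sex].equation for sex in SEXES}
    val_reports = run_part2(config, equations, cohorts)

    per_sex = {}
    for sex in SEXES:
        dev, val, alloc = cohorts[sex]
        fit = fits[sex]
        dev_pred = (
            predict_cohort(fit.equation, dev)
            if fit.selected
            else np.full(len(dev), fit.equation.intercept)
        )
        val_pred = predict_cohort(equations[sex], val)
        per_sex[sex] = {
            "development_fit": _fit_dict(fit),
            "development_report": dev_reports[sex].to_dict(),
            "validation_report": val_reports[sex].to_dict(),
            "validation_equation_provenance": equations[sex].provenance,
            "allocation": alloc.to_dict(),
            "development_pairs": _pairs_dict(dev, dev_pred),
            "validation_pairs": _pairs_dict(val, val_pred),
            "n_development": len(dev),
            "n_validation": len(val),
        }
    return StudyReport(
        per_sex=per_sex,
        config=config.echo() | {"substream_seeds": _substream_seeds(config.seed)},
        version=__version__,
    )


def _table_csv(report: StudyReport, stage: str) -> str:
    """Table-shaped CSV (rows = statistic names, columns = sexes)."""
    from .agreement import REPORT_ROW_LABELS

    key = f"{stage}_report"
    lines = ["statistic,male,female"]
    cols = {}
    for sex in SEXES:
        d = report.per_sex[sex][key]
        ciloa_low = d["ciloa_low"]
        ciloa_high = d["ciloa_high"]
        cols[sex] = (
            d["measured_mean"], d["measured_sd"], d["predicted_mean"],
            d["predicted_sd"], d["grand_mean"], d["grand_sd"], d["icc"],
            d["icc_ci_low"], d["icc_ci_high"], d["anova_f"], d["sem"],
            d["cv_pct"], d["mean_diff"], d["sd_diff"], d["loa_low"],
            d["loa_high"], d["loa_width"], d["sel"],
            f"{ciloa_low[0]:.4f} to {ciloa_low[1]:.4f}",
            f"{ciloa_high[0]:.4f} to {ciloa_high[1]:.4f}",
            d["rc"], d["ks_d"], d["ks_p"],
        )
    for i, label in enumerate(REPORT_ROW_LABELS):
        male, female = cols["male"][i], cols["female"][i]
        fmt = lambda v: v if isinstance(v, str) else f"{v:.6g}"
        lines.append(f'"{label}",{fmt(male)},{fmt(female)}')
    return "\n".join(lines) + "\n"


def _bland_altman_csv(report: StudyReport, sex: str, stage: str) -> str:
    """Per-athlete plot data: mean of methods vs difference, plus limits."""
    pairs = report.per_sex[sex][f"{stage}_pairs"]
    stats = report.per_sex[sex][f"{stage}_report"]
    lines = ["athlete_id,mean,diff,mean_diff,loa_low,loa_high"]
    for aid, m, p in zip(pairs["athlete_id"], pairs["measured"], pairs["predicted"]):
        lines.append(
            f"{aid},{(m + p) / 2:.6f},{p - m:.6f},"
            f"{stats['mean_diff']:.6f},{stats['loa_low']:.6f},{stats['loa_high']:.6f}"
        )
    return "\n".join(lines) + "\n"


def render_report(report: StudyReport, outdir: str | Path) -> list[Path]:
    """Write the report as JSON, table-shaped CSVs, plot data and a run log.

    Output is deterministic (no timestamps), so re-rendering the same
    report is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    path = outdir / "report.json"
    path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    written.append(path)

    for stage in ("development", "validation"):
        path = outdir / f"table_{stage}.csv"
        path.write_text(_table_csv(report, stage))
        written.append(path)
        for sex in SEXES:
            path = outdir / f"bland_altman_{stage}_{sex}.csv"
            path.write_text(_bland_altman_csv(report, sex, stage))
            written.append(path)

    log_lines = [f"vo2row {report.version}", f"seed: {report.config['seed']}"]
    for name, s in report.config.get("substream_seeds", {}).items():
        log_lines.append(f"substream {name}: {s}")
    for sex in SEXES:
        alloc = report.per_sex[sex]["allocation"]
        log_lines.append(
            f"{sex}: allocation accepted after {alloc['iterations_used']} "
            f"iteration(s); p-values "
            + ", ".join(f"{v}={p:.4f}" for v, p in alloc["matching_pvalues"].items())
        )
        log_lines.append(
            f"{sex}: validation equation provenance: "
            f"{report.per_sex[sex]['validation_equation_provenance']}"
        )
    path = outdir / "run_log.txt"
    path.write_text("\n".join(log_lines) + "\n")
    written.append(path)
    return written
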