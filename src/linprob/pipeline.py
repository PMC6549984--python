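"""Configuration, table ingestion and the end-to-end analysis pipeline.

The recommended workflow for general use: fit by OLS with the corrected
covariance, check the number of fitted values outside ``[-1, 1]`` against
its model-based expectation, inspect whether the out-of-range rows form an
identifiable subgroup and whether excluding them moves the conclusions,
then (when covariates have missing entries) run the extreme-assignment
sensitivity analysis, and compare coefficient ratios against a logistic
fit.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, interpret, model, sensitivity
from .exceptions import LinprobError, ValidationError

logger = logging.getLogger("linprob")

DEFAULT_NA_TOKENS = ("", "NA", ".")


@dataclass
class AnalysisConfig:
    """Declarative description of a full analysis run."""

    input_path: str
    outcome: str
    covariates: list
    coding: str = "zero_one"
    add_intercept: bool = True
    fitter: str = "ols"
    fit_ml: bool = False
    ci_level: float = 0.95
    sensitivity_levels: dict = field(default_factory=dict)
    max_full_factorial: int = 8
    pair_mode: str = "numeric"
    max_pairs: int = 1_000_000
    output_dir: str | None = None
    seed: int = 0
    na_tokens: tuple = DEFAULT_NA_TOKENS

    @classmethod
    def from_file(cls, path: str, **overrides) -> "AnalysisConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path!r} must hold a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def read_table(path: str, na_tokens=DEFAULT_NA_TOKENS) -> pd.DataFrame:
    """Read a delimited text table (comma or tab, inferred from extension)."""
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"input file not found: {path}")
    sep = "\t" if p.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(
        p, sep=sep, na_values=list(na_tokens), keep_default_na=False
    )


def load_dataset(config: AnalysisConfig) -> model.BinaryDataset:
    table = read_table(config.input_path, config.na_tokens)
    missing_cols = [
        c for c in [config.outcome, *config.covariates] if c not in table.columns
    ]
    if missing_cols:
        raise ValidationError(
            f"columns not found in {config.input_path}: {missing_cols} "
            f"(header has {list(table.columns)})"
        )
    return model.make_dataset(
        table,
        outcome_name=config.outcome,
        covariate_names=list(config.covariates),
        coding=config.coding,
        add_intercept=config.add_intercept,
    )


def _fit(data: model.BinaryDataset, fitter: str) -> model.LpmFit:
    if fitter == "ols":
        return model.fit_ols(data)
    if fitter == "wls":
        return model.fit_wls(data)
    if fitter == "ml":
        return model.fit_ml(data)
    raise ValidationError(f"unknown fitter {fitter!r}")


def _subgroup_profile(data: model.BinaryDataset, rows: np.ndarray) -> list:
    return [
        {
            "row": int(i),
            **{
                name: float(data.X[i, j])
                for j, name in enumerate(data.column_names)
                if data.column_meta[j] != model.CONSTANT
            },
        }
        for i in rows
    ]


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Execute the full workflow and return the JSON-serialisable bundle.

    Stages that fail stop their dependents but the bundle still reports
    which stage failed and why.
    """
    bundle: dict = {"config": {
        "input": config.input_path,
        "outcome": config.outcome,
        "covariates": list(config.covariates),
        "coding": config.coding,
        "fitter": config.fitter,
        "seed": config.seed,
    }}

    data = load_dataset(config)
    bundle["ingestion"] = {
        "n_rows": data.n,
        "n_dropped_missing_outcome": data.n_dropped_outcome,
        "n_missing_cells": int(data.missing_mask.sum()),
        "column_kinds": dict(zip(data.column_names, data.column_meta)),
    }
    had_missing = data.has_missing
    fit_data = data.complete_cases() if had_missing else data
    if had_missing:
        logger.info(
            "base fit on %d complete cases of %d rows", fit_data.n, data.n
        )

    fit = _fit(fit_data, config.fitter)
    bundle["fit"] = fit.summary_dict(config.ci_level)

    # out-of-range diagnostic
    try:
        diag = diagnostics.variance_out_of_range(
            fit,
            fit_data,
            pair_mode=config.pair_mode,
            max_pairs=config.max_pairs,
            seed=config.seed,
        )
        section = diag.summary_dict()
        section["subgroup_profile"] = _subgroup_profile(
            fit_data, diag.out_of_range_rows
        )
        if diag.out_of_range_rows.size:
            keep = np.setdiff1d(np.arange(fit_data.n), diag.out_of_range_rows)
            import dataclasses as _dc

            refit = model.fit_ols(
                _dc.replace(
                    fit_data,
                    y=fit_data.y[keep],
                    X=fit_data.X[keep],
                    missing_mask=fit_data.missing_mask[keep],
                )
            )
            section["refit_excluding_out_of_range"] = {
                "n": int(keep.size),
                "coefficients": {
                    name: float(b)
                    for name, b in zip(refit.column_names, refit.beta_hat)
                },
                "delta_from_full_fit": {
                    name: float(b - b0)
                    for name, b, b0 in zip(
                        refit.column_names, refit.beta_hat, fit.beta_hat
                    )
                },
            }
        bundle["diagnostic"] = section
    except LinprobError as exc:
        bundle["diagnostic"] = {"error": f"{type(exc).__name__}: {exc}"}

    if config.fit_ml:
        try:
            ml = model.fit_ml(fit_data)
            eff = model.efficiency_gap(fit_data, fit.beta_hat)
            bundle["ml"] = ml.summary_dict(config.ci_level)
            bundle["efficiency"] = {
                "inflation_diagonal": np.diag(eff.inflation).tolist(),
                "var_ols_diagonal": np.diag(eff.var_ols).tolist(),
                "var_ml_approx_diagonal": np.diag(eff.var_ml_approx).tolist(),
                "bound_scalar": eff.bound_scalar,
            }
        except LinprobError as exc:
            bundle["ml"] = {"error": f"{type(exc).__name__}: {exc}"}

    if had_missing:
        try:
            design = sensitivity.build_design(
                data,
                user_levels=config.sensitivity_levels or None,
                max_full_factorial=config.max_full_factorial,
            )
            report = sensitivity.run_sensitivity(data, design)
            effects = sensitivity.missingness_main_effects(report, design)
            report.missingness_main_effects = effects
            bundle["sensitivity"] = {
                "variables": list(design.variables),
                "levels": {k: list(v) for k, v in design.levels.items()},
                "design_kind": design.design_kind,
                "defining_contrast": design.defining_contrast,
                "n_patterns": len(design.patterns),
                "table": report.to_frame().to_dict(orient="index"),
                "max_abs_difference": {
                    name: float(d)
                    for name, d in zip(
                        report.column_names, report.max_abs_difference
                    )
                },
                "missingness_main_effects": effects.to_dict(orient="index"),
            }
        except LinprobError as exc:
            bundle["sensitivity"] = {"error": f"{type(exc).__name__}: {exc}"}

    try:
        logit_beta, _ = interpret.fit_logistic(fit_data)
        comp = interpret.compare_ratios(fit, logit_beta)
        bundle["ratio_comparison"] = {
            "lpm": comp.lpm_coefficients.tolist(),
            "logistic": comp.logit_coefficients.tolist(),
            "names": list(comp.names),
            "max_relative_discrepancy": None
            if np.isnan(comp.max_relative_discrepancy)
            else float(comp.max_relative_discrepancy),
        }
    except LinprobError as exc:
        bundle["ratio_comparison"] = {"error": f"{type(exc).__name__}: {exc}"}

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(bundle, indent=2))
        (outdir / "report.txt").write_text(render_text(bundle))
    return bundle


def render_text(bundle: dict) -> str:
    """Human-readable rendering; every number comes from the JSON bundle."""
    lines = ["linear-in-probability analysis report", "=" * 40]
    ing = bundle.get("ingestion", {})
    lines.append(
        f"rows: {ing.get('n_rows')} "
        f"(dropped for missing outcome: {ing.get('n_dropped_missing_outcome')}; "
        f"missing covariate cells: {ing.get('n_missing_cells')})"
    )
    fit = bundle.get("fit", {})
    if "coefficients" in fit:
        lines.append("")
        lines.append(f"[fit: {fit['method']}]  n = {fit['n']}")
        lines.append(f"{'term':<20}{'estimate':>12}{'se':>12}{'z':>10}")
        for name, row in fit["coefficients"].items():
            se = "." if row["se"] is None else f"{row['se']:.4g}"
            z = "." if row["z"] is None else f"{row['z']:.3f}"
            lines.append(f"{name:<20}{row['estimate']:>12.5g}{se:>12}{z:>10}")
    diag = bundle.get("diagnostic", {})
    if diag:
        lines.append("")
        lines.append("[out-of-range diagnostic]")
        if "error" in diag:
            lines.append(f"  failed: {diag['error']}")
        else:
            lines.append(
                f"  observed R = {diag['r_observed']}, "
                f"predicted lambda = {diag['lambda_hat']:.3f}"
            )
            lines.append(
                f"  var(R): independent {diag['var_r_independent']:.3f}, "
                f"full {diag['var_r_full']:.3f}, "
                f"Poisson lower bound {diag['var_r_poisson_bound']:.3f}"
            )
            lines.append(
                "  adequacy: doubt cast on the model"
                if diag.get("doubt_cast")
                else "  adequacy: consistent with chance"
            )
            if diag.get("refit_excluding_out_of_range"):
                deltas = diag["refit_excluding_out_of_range"]["delta_from_full_fit"]
                worst = max(deltas, key=lambda k: abs(deltas[k]))
                lines.append(
                    f"  refit excluding out-of-range rows: largest coefficient "
                    f"shift {deltas[worst]:+.4g} ({worst})"
                )
    sens = bundle.get("sensitivity")
    if sens:
        lines.append("")
        lines.append("[missing-value sensitivity]")
        if "error" in sens:
            lines.append(f"  failed: {sens['error']}")
        else:
            lines.append(
                f"  {sens['n_patterns']} patterns ({sens['design_kind']}) over "
                f"{', '.join(sens['variables'])}"
            )
            for name, d in sens["max_abs_difference"].items():
                lines.append(f"  max |difference| {name:<20} {d:.5g}")
    comp = bundle.get("ratio_comparison")
    if comp:
        lines.append("")
        lines.append("[logistic ratio comparison]")
        if "error" in comp:
            lines.append(f"  failed: {comp['error']}")
        else:
            md = comp["max_relative_discrepancy"]
            lines.append(
                "  max relative ratio discrepancy: "
                + ("undefined" if md is None else f"{md:.4g}")
            )
    return "\n".join(lines) + "\n"


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("linprob: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
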