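"""End-to-end scenario runner: generate -> filter -> fit -> evaluate -> render.

A scenario run is fully determined by its :class:`~fraxval.config.ScenarioConfig`
and one root seed; all randomness flows from that seed through named
substreams, so two runs with the same config and seed produce byte-identical
report bundles.  The bundle contains the three evaluation surfaces —

* a model x outcome AUC grid (with DeLong CIs and paired tests against the
  baseline score),
* reclassification tables and NRI for the base vs expanded model at the
  clinical thresholds (20% MOF, 3% hip),
* decile calibration tables with O/E ratios and calibration slopes,

plus an exclusion ledger and a run manifest reconciling row counts across
stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    CalibrationSummary,
    calibration_table,
    decile_partition,
    logistic_recalibration_slope,
)
from .cohort import generate_cohort, write_cohort
from .config import ScenarioConfig
from .discrimination import AUCEstimate, compare_auc_paired, compute_auc
from .filters import apply_filter
from .reclassification import (
    NRISummary,
    ReclassificationTable,
    build_reclass_table,
    compute_nri,
    nri_percent_report,
)
from .scoring import FittedModel, fit_logistic, predict, prepare_analysis_columns

__all__ = ["ScenarioResult", "run_scenario", "render_auc_table",
           "render_reclass_table", "render_calibration_table"]

_OUTCOME_COL = {"mof": "mof_event", "hip": "hip_event"}


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    seed: int
    ledger: dict[str, int]
    analytic_n: int
    fitted: dict[str, FittedModel]
    auc: list[AUCEstimate]
    auc_p_vs_base: dict[tuple[str, str], float]
    reclass: dict[str, tuple[ReclassificationTable, ReclassificationTable]]
    nri: dict[str, NRISummary]
    calibration: dict[str, CalibrationSummary]
    recalibration_slopes: dict[str, float]
    manifest: dict = field(default_factory=dict)

    def write(self, output_dir) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "exclusion_ledger.json", "w") as fh:
            json.dump(self.ledger, fh, indent=2)
            fh.write("\n")
        render_auc_table(self.auc, self.auc_p_vs_base).to_csv(
            out / "auc_table.csv", index=False)
        nri_payload = {}
        for outcome, (events, nonevents) in self.reclass.items():
            render_reclass_table(events, nonevents).to_csv(
                out / f"reclassification_{outcome}.csv", index=False)
            summary = self.nri[outcome]
            nri_payload[outcome] = {
                **{k: getattr(summary, k) for k in (
                    "threshold", "event_nri", "nonevent_nri",
                    "up_events", "down_events", "up_nonevents", "down_nonevents",
                    "n_events", "n_nonevents", "p_event", "p_nonevent")},
                "report": nri_percent_report(summary),
            }
        with open(out / "nri.json", "w") as fh:
            json.dump(nri_payload, fh, indent=2)
            fh.write("\n")
        for outcome, summary in self.calibration.items():
            render_calibration_table(summary).to_csv(
                out / f"calibration_{outcome}.csv", index=False)
            series = {
                "outcome": outcome,
                "decile": [r.decile for r in summary.rows],
                "predicted": [round(r.predicted, 6) for r in summary.rows],
                "observed": [round(r.observed, 6) for r in summary.rows],
            }
            with open(out / f"calibration_series_{outcome}.json", "w") as fh:
                json.dump(series, fh, indent=2)
                fh.write("\n")
        with open(out / "models.json", "w") as fh:
            fh.write("[\n")
            fh.write(",\n".join(m.to_json() for m in self.fitted.values()))
            fh.write("\n]\n")


def _model_key(spec_name: str, outcome: str) -> str:
    return f"{spec_name}:{outcome}"


def run_scenario(
    config: ScenarioConfig,
    seed: int | None = None,
    output_dir=None,
    write_cohort_csv: bool = False,
) -> ScenarioResult:
    """Run one scenario end to end; ``seed`` (if given) overrides the
    generator seed so one root seed drives the whole run."""
    gen_config = config.generator
    if seed is not None:
        sub = np.random.SeedSequence(seed).generate_state(1)
        gen_config = dataclasses.replace(gen_config, seed=int(sub[0] % 2**31))
    root_seed = seed if seed is not None else gen_config.seed

    cohort = generate_cohort(gen_config)
    policy = config.apply_scenario()
    analytic, ledger = apply_filter(cohort, policy, horizon=gen_config.horizon)
    analytic = prepare_analysis_columns(analytic)

    fitted: dict[str, FittedModel] = {}
    predictions: dict[str, pd.DataFrame] = {}
    auc_rows: list[AUCEstimate] = []
    auc_p: dict[tuple[str, str], float] = {}
    labels = {o: analytic[col].to_numpy(dtype=bool) for o, col in _OUTCOME_COL.items()}

    for spec in config.models:
        key = _model_key(spec.name, spec.outcome)
        model = fit_logistic(analytic, spec)
        fitted[key] = model
        pred = predict(model, analytic)
        predictions[key] = pred
        auc_rows.append(
            compute_auc(pred["predicted_probability"].to_numpy(),
                        labels[spec.outcome],
                        model=spec.name, outcome=spec.outcome))

    for spec in config.models:
        base_key = _model_key(config.base_model, spec.outcome)
        key = _model_key(spec.name, spec.outcome)
        if spec.name != config.base_model and base_key in predictions:
            cmp = compare_auc_paired(
                predictions[key]["predicted_probability"].to_numpy(),
                predictions[base_key]["predicted_probability"].to_numpy(),
                labels[spec.outcome])
            auc_p[(spec.name, spec.outcome)] = cmp.p_value

    reclass: dict[str, tuple[ReclassificationTable, ReclassificationTable]] = {}
    nri: dict[str, NRISummary] = {}
    calib: dict[str, CalibrationSummary] = {}
    recal_slopes: dict[str, float] = {}

    for outcome, threshold in config.thresholds.items():
        base_key = _model_key(config.base_model, outcome)
        exp_key = _model_key(config.expanded_model, outcome)
        if base_key in predictions and exp_key in predictions:
            events, nonevents = build_reclass_table(
                predictions[base_key], predictions[exp_key],
                labels[outcome], threshold, outcome=outcome)
            reclass[outcome] = (events, nonevents)
            nri[outcome] = compute_nri(events, nonevents)
        if base_key in predictions:
            if config.calibration_mode == "refit":
                p = predictions[base_key]["predicted_probability"].to_numpy()
            else:
                p = analytic["frax_score"].to_numpy(dtype=float)
            deciles = decile_partition(p)
            calib[outcome] = calibration_table(
                deciles, p, labels[outcome],
                outcome=outcome, model=config.base_model)
            recal_slopes[outcome], _ = logistic_recalibration_slope(
                p, labels[outcome])

    manifest = {
        "package": "fraxval",
        "version": __version__,
        "seed": root_seed,
        "scenario": config.scenario,
        "calibration_mode": config.calibration_mode,
        "generated_n": int(ledger["input_n"]),
        "analytic_n": int(ledger["output_n"]),
        "exclusions": {k: v for k, v in ledger.items()
                       if k not in ("input_n", "output_n")},
        "models": {key: m.n_fit for key, m in fitted.items()},
    }

    result = ScenarioResult(
        config=config,
        seed=root_seed,
        ledger=ledger,
        analytic_n=len(analytic),
        fitted=fitted,
        auc=auc_rows,
        auc_p_vs_base=auc_p,
        reclass=reclass,
        nri=nri,
        calibration=calib,
        recalibration_slopes=recal_slopes,
        manifest=manifest,
    )
    if output_dir is not None:
        result.write(output_dir)
        if write_cohort_csv:
            write_cohort(cohort, Path(output_dir) / "cohort.csv")
    return result


def render_auc_table(
    estimates: list[AUCEstimate],
    p_vs_base: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Model x outcome AUC grid on the percentage scale, 1 decimal, with CIs."""
    rows = []
    for est in estimates:
        row = {
            "model": est.model,
            "outcome": est.outcome,
            "n": est.n,
            "n_events": est.n_events,
            "auc_pct": round(100.0 * est.auc, 1),
            "auc_ci": f"{100 * est.auc:.1f} ({100 * est.ci_low:.1f}-{100 * est.ci_high:.1f})",
        }
        if p_vs_base is not None:
            p = p_vs_base.get((est.model, est.outcome))
            row["p_vs_base"] = "" if p is None else f"{p:.3g}"
        rows.append(row)
    columns = ["model", "outcome", "n", "n_events", "auc_pct", "auc_ci"]
    if p_vs_base is not None:
        columns.append("p_vs_base")
    return pd.DataFrame(rows, columns=columns)


def render_reclass_table(
    events: ReclassificationTable,
    nonevents: ReclassificationTable,
) -> pd.DataFrame:
    """Reclassification table with counts and row percentages (1 decimal)."""
    rows = []
    for table in (events, nonevents):
        pct = table.row_percentages()
        for i, base_cat in enumerate(("low", "high")):
            rows.append({
                "outcome": table.outcome,
                "event_status": table.event_status,
                "base_category": base_cat,
                "to_low": int(table.counts[i, 0]),
                "to_low_pct": round(float(pct[i, 0]), 1),
                "to_high": int(table.counts[i, 1]),
                "to_high_pct": round(float(pct[i, 1]), 1),
                "row_total": int(table.row_totals[i]),
            })
    return pd.DataFrame(rows)


def render_calibration_table(summary: CalibrationSummary) -> pd.DataFrame:
    """Decile calibration table: proportions to 3 decimals, O/E to 2."""
    rows = [
        {
            "decile": str(r.decile),
            "n": r.n,
            "observed": round(r.observed, 3),
            "predicted": round(r.predicted, 3),
            "oe_ratio": round(r.oe_ratio, 2) if r.oe_defined else "",
        }
        for r in summary.rows
    ]
    rows.append({
        "decile": "total",
        "n": sum(r.n for r in summary.rows),
        "observed": round(summary.overall_observed, 3),
        "predicted": round(summary.overall_predicted, 3),
        "oe_ratio": round(summary.overall_oe, 2),
    })
    return pd.DataFrame(rows)
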