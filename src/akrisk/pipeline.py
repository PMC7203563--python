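"""End-to-end orchestration: generate -> detect -> landmark -> model ->
validate, emitting report tables that mirror the analysis layout
(characteristics, 5-year outcomes, stepwise hazard ratios, model
comparison) plus calibration and decision-curve outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import renal, riskmodels, survival as sv, synth

logger = logging.getLogger(__name__)

ANALYSIS_DEFAULTS = {
    "egfr_stratum": "both",       # lt30 | ge30 | both
    "aki_criteria": "all",        # all | i | ii | iii
    "endpoint": "kf15",           # kf15 | decline30
    "threshold_max": 0.10,
    "acr_policy": "complete_case",
    "figures": True,
}

SCENARIO_KEYS = {f.name for f in dataclasses.fields(synth.ScenarioConfig)}


class ConfigSchemaError(ValueError):
    pass


def _effects_from_dict(d):
    def cause(key):
        if key not in d:
            raise ConfigSchemaError(f"true_effects missing key: {key}")
        c = d[key]
        if "baseline_rate" not in c:
            raise ConfigSchemaError(f"true_effects.{key} missing baseline_rate")
        return synth.CauseEffects(float(c["baseline_rate"]),
                                  {k: float(v) for k, v in c.get("loghr", {}).items()})
    return synth.TrueEffects(cause("kidney_failure"), cause("death"),
                             float(d.get("horizon_years", 5.0)))


def load_config(source):
    """Load a scenario + analysis configuration from YAML path / dict.

    Returns (ScenarioConfig, analysis_options). Unknown scenario keys raise
    a schema error listing them.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    scen = dict(raw.get("scenario", {}))
    unknown = set(scen) - SCENARIO_KEYS
    if unknown:
        raise ConfigSchemaError(f"unknown scenario keys: {sorted(unknown)}")
    if "true_effects" in scen and isinstance(scen["true_effects"], dict):
        scen["true_effects"] = _effects_from_dict(scen["true_effects"])
    for key in ("age_mix", "egfr_stage_mix", "aki_stage_mix"):
        if key in scen:
            scen[key] = tuple(scen[key])
    analysis = {**ANALYSIS_DEFAULTS, **raw.get("analysis", {})}
    bad = set(analysis) - set(ANALYSIS_DEFAULTS)
    if bad:
        raise ConfigSchemaError(f"unknown analysis keys: {sorted(bad)}")
    return synth.ScenarioConfig(**scen), analysis


def _config_hash(cfg: synth.ScenarioConfig, analysis):
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, frozenset):
            return sorted(o)
        if isinstance(o, (np.floating, np.integer)):
            return float(o)
        raise TypeError(type(o))
    blob = json.dumps({"scenario": dataclasses.asdict(cfg), "analysis": analysis},
                      sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def aki_config_for(analysis, base=None):
    base = base or renal.AKIConfig()
    which = analysis.get("aki_criteria", "all")
    if which == "all":
        return base
    if which in ("i", "ii", "iii"):
        return dataclasses.replace(base, criteria_enabled=frozenset({which}))
    raise ConfigSchemaError(f"unknown aki_criteria {which!r}")


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def _band(values, edges, labels):
    return pd.cut(values, edges, labels=labels, right=False).astype(str)


def characteristics_table(rows: pd.DataFrame):
    """Cohort characteristics split by 2-year AKI exposure."""
    df = rows.copy()
    df["age_band"] = _band(df["age_landmark"], [0, 60, 80, 200], ["<60", "60-79", ">=80"])
    df["egfr_band"] = _band(df["egfr_landmark"], [0, 30, 45, 60, 1000],
                            ["<30", "30-44", "45-59", ">=60"])
    out = []
    for var in ("age_band", "sex", "egfr_band", "proteinuria_cat", "diagnosis_cat"):
        for level, g in df.groupby(var, sort=True):
            n_aki = int((g["aki_2yr"] == 1).sum())
            n_no = int((g["aki_2yr"] == 0).sum())
            out.append({"variable": var, "level": level, "n": len(g),
                        "n_aki": n_aki, "n_no_aki": n_no,
                        "pct_of_aki": round(100 * n_aki / max((df["aki_2yr"] == 1).sum(), 1), 1),
                        "pct_of_no_aki": round(100 * n_no / max((df["aki_2yr"] == 0).sum(), 1), 1)})
    return pd.DataFrame(out)


def outcomes_table(rows: pd.DataFrame):
    """5-year outcome proportions by AKI exposure and strata."""
    df = rows.copy()
    df["egfr_band"] = _band(df["egfr_landmark"], [0, 30, 45, 60, 1000],
                            ["<30", "30-44", "45-59", ">=60"])
    df["age_band"] = _band(df["age_landmark"], [0, 60, 80, 200], ["<60", "60-79", ">=80"])
    strata = [("overall", pd.Series("all", index=df.index)),
              ("age_band", df["age_band"]), ("sex", df["sex"]),
              ("egfr_band", df["egfr_band"]),
              ("proteinuria", df["proteinuria_cat"])]
    out = []
    for varname, col in strata:
        for level in col.unique():
            sub = df[col == level]
            for aki in (1, 0):
                g = sub[sub["aki_2yr"] == aki]
                if len(g) == 0:
                    continue
                out.append({
                    "stratum": varname, "level": level, "aki_2yr": aki, "n": len(g),
                    "pct_kidney_failure": round(100 * (g["event"] == "kidney_failure").mean(), 1),
                    "pct_death": round(100 * (g["event"] == "death").mean(), 1),
                    "pct_alive": round(100 * (g["event"] == "censored").mean(), 1),
                })
    return pd.DataFrame(out)


def ladder_specs(rows: pd.DataFrame, exposure_col="aki_2yr"):
    """The stepwise covariate ladder: exposure alone, then + age/sex,
    + eGFR^-2, + proteinuria categories, + renal diagnosis."""
    def cat(col):
        counts = rows[col].value_counts()
        ref = counts.index[0]
        levels = tuple(counts.index)
        return sv.categorical(col, reference=ref, levels=levels)

    expo = sv.identity(exposure_col, name="aki")
    base = [expo]
    agesex = base + [sv.per10_centered("age_landmark", 70.0, name="age_per10"),
                     sv.identity("sex")]
    egfr = agesex + [sv.inverse_square("egfr_landmark", 30.0, name="egfr_inv2")]
    prot = egfr + [cat("proteinuria_cat")]
    diag = prot + [cat("diagnosis_cat")]
    return [("unadjusted", sv.CovariateSpec(base)),
            ("age_sex", sv.CovariateSpec(agesex)),
            ("age_sex_egfr", sv.CovariateSpec(egfr)),
            ("age_sex_egfr_proteinuria", sv.CovariateSpec(prot)),
            ("age_sex_egfr_proteinuria_diagnosis", sv.CovariateSpec(diag))]


def stepwise_hr_table(rows: pd.DataFrame, exposure_col="aki_2yr"):
    """Cause-specific AKI hazard ratios along the adjustment ladder, per
    eGFR stratum (one row per adjustment step)."""
    out = []
    for stratum, sub in (("lt30", rows[rows["egfr_landmark"] < 30]),
                         ("ge30", rows[rows["egfr_landmark"] >= 30])):
        if len(sub) == 0:
            continue
        for adj, spec in ladder_specs(sub, exposure_col):
            for cause in ("kidney_failure", "death"):
                if (sub["event"] == cause).sum() == 0:
                    continue
                try:
                    fit = sv.fit_cox_cause_specific(sub, spec, cause)
                except (ValueError, sv.ConvergenceError) as exc:
                    logger.warning("stepwise fit skipped (%s/%s/%s): %s",
                                   stratum, adj, cause, exc)
                    continue
                hr = fit.hazard_ratios().loc["aki"]
                out.append({"stratum": stratum, "adjustment": adj, "cause": cause,
                            "n": len(sub), "n_events": fit.n_events,
                            "hr": hr["hr"], "ci_lo": hr["hr_lo"], "ci_hi": hr["hr_hi"]})
    return pd.DataFrame(out)


def adjusted_aki_hr(rows: pd.DataFrame, stratum, cause, exposure_col="aki_2yr"):
    """Fully adjusted cause-specific AKI hazard ratio (top of the covariate
    ladder) in one eGFR stratum."""
    sub = (rows[rows["egfr_landmark"] >= 30] if stratum == "ge30"
           else rows[rows["egfr_landmark"] < 30])
    spec = ladder_specs(sub, exposure_col)[-1][1]
    fit = sv.fit_cox_cause_specific(sub, spec, cause)
    return float(np.exp(fit.coef_dict()["aki"])), fit


def model_comparison_table(rows: pd.DataFrame, acr_policy="complete_case",
                           threshold_max=0.10):
    """KFRE external validation versus refitted models with/without AKI on
    the eGFR >= 30 stratum (equations, slope, AUC, comparison p), plus calibration-bin and
    decision-curve data."""
    sub = rows[(rows["egfr_landmark"] >= 30) & rows["lnacr"].notna()].copy()
    if len(sub) < 50 or (sub["event"] == "kidney_failure").sum() < 5:
        raise ValueError("eGFR >= 30 stratum too small for model comparison")

    kfre = riskmodels.kfre_model()
    refit0 = riskmodels.refit_model(sub, include_aki=False, acr_policy=acr_policy)
    refit1 = riskmodels.refit_model(sub, include_aki=True, acr_policy=acr_policy)
    models = [kfre, refit0, refit1]

    y, determinate = ev.binary_outcome_5y(sub)
    preds, lps, aucs, cals = {}, {}, {}, {}
    for m in models:
        lps[m.name] = m.linear_predictor(sub)
        preds[m.name] = m.predict_risk(sub)
        aucs[m.name] = ev.auc(preds[m.name][determinate], y[determinate])
        cals[m.name] = ev.calibration(preds[m.name], lps[m.name], sub)

    _, _, _, p_kfre = ev.compare_auc(preds[refit0.name][determinate],
                                     preds[kfre.name][determinate], y[determinate])
    _, _, _, p_aki = ev.compare_auc(preds[refit1.name][determinate],
                                    preds[refit0.name][determinate], y[determinate])
    pvals = {kfre.name: p_kfre, refit0.name: p_aki, refit1.name: np.nan}

    table = pd.DataFrame([{
        "model": m.name,
        "equation": m.equation(),
        "calibration_slope": cals[m.name].slope,
        "slope_ci_lo": cals[m.name].slope_ci[0],
        "slope_ci_hi": cals[m.name].slope_ci[1],
        "auc": aucs[m.name],
        "p_vs_next": pvals[m.name],
    } for m in models])

    thresholds = np.arange(0.0, threshold_max + 0.0005, 0.001)
    dca = ev.decision_curve({m.name: preds[m.name][determinate] for m in models},
                            y[determinate], thresholds)
    calbins = pd.concat([c.bins.assign(model=name) for name, c in cals.items()],
                        ignore_index=True)
    return table, calbins, dca, models


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineRun:
    config: synth.ScenarioConfig
    analysis: dict
    seed: int
    out_dir: Path
    config_hash: str
    artifacts: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    landmark: pd.DataFrame = None


def _plain(obj):
    """Recursively convert numpy scalars / tuples for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def _write_json(path, obj):
    def default(o):
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, Path):
            return str(o)
        raise TypeError(type(o))
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)
        fh.write("\n")


def run_pipeline(config, out_dir, seed=None):
    """Execute all stages and emit tables, figures and a metrics summary.

    ``config`` may be a YAML path, a dict, or a ready ScenarioConfig (then
    default analysis options apply). ``seed`` overrides the scenario seed.
    """
    t0 = time.time()
    if isinstance(config, synth.ScenarioConfig):
        cfg, analysis = config, dict(ANALYSIS_DEFAULTS)
    else:
        cfg, analysis = load_config(config)
    if seed is not None:
        cfg = cfg.replace(seed=int(seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg, analysis)
    run = PipelineRun(cfg, analysis, cfg.seed, out, chash)

    # stage: generate
    cohort = synth.generate_cohort(cfg)
    data_dir = cohort.write(out / "data")
    run.artifacts["data"] = data_dir
    logger.info("generate: %d patients, %d lab rows (%.1fs)",
                len(cohort.patients), len(cohort.labs), time.time() - t0)

    # stage: detect + landmark (from the written CSVs, for re-entrancy)
    patients = pd.read_csv(data_dir / "patients.csv")
    labs = pd.read_csv(data_dir / "labs.csv")
    events = pd.read_csv(data_dir / "events.csv")
    akicfg = aki_config_for(analysis, cfg.aki_config)
    rows = renal.build_landmark_cohort(patients, labs, events, akicfg,
                                       landmark_day=cfg.observation_days,
                                       endpoint=analysis["endpoint"])
    rows.to_csv(out / "landmark_cohort.csv", index=False)
    run.artifacts["landmark_cohort"] = out / "landmark_cohort.csv"
    run.landmark = rows

    # config snapshot for reproducibility
    snap = dataclasses.asdict(cfg)
    snap["aki_config"]["criteria_enabled"] = sorted(
        cfg.aki_config.criteria_enabled)
    with open(out / "config_snapshot.yaml", "w") as fh:
        yaml.safe_dump({"scenario": _plain(snap), "analysis": analysis,
                        "config_hash": chash}, fh, sort_keys=True)

    # cumulative incidence and -ln(-ln S) curves by AKI exposure
    curve_rows = []
    for cause in ("kidney_failure", "death"):
        for grp, (ts, cif) in sv.aalen_johansen_cif(
                rows, cause, group_col="aki_2yr").items():
            curve_rows.append(pd.DataFrame(
                {"cause": cause, "aki_2yr": grp, "time_years": ts, "cif": cif}))
    if curve_rows:
        pd.concat(curve_rows, ignore_index=True).to_csv(
            out / "cif_curves.csv", index=False)
    ll_rows = []
    for grp, (ts, vals) in sv.loglog_survival(rows, "aki_2yr").items():
        ll_rows.append(pd.DataFrame(
            {"aki_2yr": grp, "time_years": ts, "neg_log_neg_log_s": vals}))
    if ll_rows:
        pd.concat(ll_rows, ignore_index=True).to_csv(
            out / "loglog_survival.csv", index=False)

    # stage: report tables
    t1 = characteristics_table(rows)
    t2 = outcomes_table(rows)
    t3 = stepwise_hr_table(rows)
    t1.to_csv(out / "table1_characteristics.csv", index=False)
    t2.to_csv(out / "table2_outcomes.csv", index=False)
    t3.to_csv(out / "table3_stepwise_hr.csv", index=False)
    run.tables.update({"table1": t1, "table2": t2, "table3": t3})

    metrics = {
        "config_hash": chash,
        "seed": cfg.seed,
        "n_patients": int(len(cohort.patients)),
        "n_landmark": int(len(rows)),
        "exclusions": rows.attrs.get("exclusions", {}),
        "aki_prevalence": float(rows["aki_2yr"].mean()) if len(rows) else np.nan,
        "pct_kidney_failure": float(100 * (rows["event"] == "kidney_failure").mean()),
        "pct_death": float(100 * (rows["event"] == "death").mean()),
    }

    # stage: model comparison (eGFR >= 30 only)
    if analysis["egfr_stratum"] in ("ge30", "both"):
        try:
            t4, calbins, dca, models = model_comparison_table(
                rows, analysis["acr_policy"], analysis["threshold_max"])
            t4.to_csv(out / "table4_models.csv", index=False)
            calbins.to_csv(out / "calibration_bins.csv", index=False)
            dca.to_csv(out / "decision_curve.csv", index=False)
            run.tables.update({"table4": t4, "calibration_bins": calbins,
                               "decision_curve": dca})
            for m in models:
                (out / f"model_{m.name}.json").write_text(m.to_json())
            metrics["models"] = {
                r["model"]: {"auc": r["auc"], "calibration_slope": r["calibration_slope"]}
                for r in t4.to_dict("records")}
            if analysis.get("figures", True):
                _figures(out, calbins, dca)
        except ValueError as exc:
            logger.warning("model comparison skipped: %s", exc)
            metrics["models"] = {"skipped": str(exc)}

    if not t3.empty:
        metrics["aki_hr"] = {
            f"{r['stratum']}:{r['adjustment']}:{r['cause']}": round(float(r["hr"]), 4)
            for r in t3.to_dict("records")}

    _write_json(out / "metrics.json", metrics)
    run.metrics = metrics
    run.artifacts["metrics"] = out / "metrics.json"
    logger.info("pipeline complete in %.1fs -> %s", time.time() - t0, out)
    return run


def _figures(out, calbins, dca):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, g in calbins.groupby("model"):
        ax.plot(g["mean_predicted"], g["observed_proportion"], "o-", label=name)
    lim = max(calbins[["mean_predicted", "observed_proportion"]].max().max(), 0.1)
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("Predicted 5-year risk")
    ax.set_ylabel("Observed proportion")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "calibration_plot.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, g in dca.groupby("model"):
        ax.plot(100 * g["threshold"], g["net_benefit"], label=name)
    ax.set_xlabel("Threshold probability (%)")
    ax.set_ylabel("Net benefit")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "decision_curve.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Subgroup / sensitivity suite
# ---------------------------------------------------------------------------

SUBGROUPS = ("criterion_iii_only", "stage1_only", "recurrent_only",
             "decline30_endpoint")


def subgroup_suite(run: PipelineRun, which):
    """Re-run the stepwise hazard-ratio table under a restricted AKI
    exposure or the 30%-decline endpoint; writes a parallel table."""
    if which not in SUBGROUPS:
        raise ValueError(f"unknown subgroup {which!r}")
    rows = run.landmark

    if which == "decline30_endpoint":
        data_dir = run.artifacts["data"]
        patients = pd.read_csv(data_dir / "patients.csv")
        labs = pd.read_csv(data_dir / "labs.csv")
        events = pd.read_csv(data_dir / "events.csv")
        akicfg = aki_config_for(run.analysis, run.config.aki_config)
        sub = renal.build_landmark_cohort(patients, labs, events, akicfg,
                                          landmark_day=run.config.observation_days,
                                          endpoint="decline30")
        expo = "aki_2yr"
    elif which == "criterion_iii_only":
        sub = rows.copy()
        expo = "aki_criterion_iii_only"
    elif which == "stage1_only":
        sub = rows[(rows["aki_2yr"] == 0) |
                   (rows["aki_stage_max"].fillna(0) == 1)].copy()
        expo = "aki_2yr"
    else:  # recurrent_only
        sub = rows[(rows["aki_2yr"] == 0) | (rows["aki_recurrent"] == 1)].copy()
        expo = "aki_recurrent"

    if len(sub) == 0 or sub[expo].sum() == 0:
        logger.warning("subgroup %s empty; skipped", which)
        return None
    table = stepwise_hr_table(sub, exposure_col=expo)
    path = run.out_dir / f"table3_{which}.csv"
    table.to_csv(path, index=False)
    run.tables[f"table3_{which}"] = table
    run.artifacts[f"table3_{which}"] = path
    return table
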