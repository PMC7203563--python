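"""Synthetic cohort generator.

Produces patient covariate tables, longitudinal creatinine series with
injected AKI spike episodes, and post-landmark competing-event times from
cause-specific exponential hazards, so the whole detection -> landmark ->
modelling -> validation chain is testable without any external data.

Conventions for the data-generating linear predictor (per cause):

======================  =====================================================
effect key              covariate it multiplies
======================  =====================================================
``aki``                 1 if exactly one detected AKI episode (single, not
                        recurrent), else 0 — so ``recurrent_aki`` is the
                        total contrast of recurrent AKI versus no AKI
``recurrent_aki``       1 if >= 2 detected episodes
``age_per10``           (age at landmark - 70) / 10
``male``                1 male / 0 female
``egfr_inv2``           (eGFR at landmark / 30)^-2 - 1
``lnacr``               ln(ACR mg/g) - ln(30)
======================  =====================================================
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import renal
from .renal import (AKIConfig, LabSeries, detect_aki, classify_recurrence,
                    egfr_ckdepi, DAYS_PER_YEAR)

DEFAULT_SEED = 20180915

AGE_BANDS = ((42.0, 60.0), (60.0, 80.0), (80.0, 92.0))       # <60, 60-79, >=80
EGFR_BANDS = ((16.0, 30.0), (30.0, 45.0), (45.0, 60.0), (60.0, 90.0))
STAGE_PEAK_RANGES = {1: (1.6, 1.9), 2: (2.1, 2.9), 3: (3.0, 4.0)}
EPISODE_SAMPLING_OFFSETS = (0, 1, 3, 7, 14, 21)

DIAGNOSIS_LEVELS = ("diabetes", "glomerulonephritis", "interstitial",
                    "multisystem", "polycystic", "vascular_htn",
                    "uncertain", "not_recorded")
DIAGNOSIS_PROBS = (0.163, 0.049, 0.093, 0.057, 0.021, 0.218, 0.141, 0.258)

EFFECT_KEYS = ("aki", "recurrent_aki", "age_per10", "male", "egfr_inv2", "lnacr")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CauseEffects:
    """Baseline hazard (events/year at the reference profile) and log
    hazard ratios for one cause."""

    baseline_rate: float
    loghr: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ConfigError("baseline_rate must be nonnegative")
        unknown = set(self.loghr) - set(EFFECT_KEYS)
        if unknown:
            raise ConfigError(f"unknown effect keys {sorted(unknown)}")


@dataclass(frozen=True)
class TrueEffects:
    kidney_failure: CauseEffects
    death: CauseEffects
    horizon_years: float = 5.0

    def __post_init__(self):
        if self.horizon_years <= 0:
            raise ConfigError("horizon must be positive")


def _default_effects():
    return TrueEffects(
        kidney_failure=CauseEffects(0.05, {
            "aki": np.log(1.35), "recurrent_aki": np.log(1.35),
            "age_per10": -0.10, "male": 0.22, "egfr_inv2": 1.0,
            "lnacr": 0.23}),
        death=CauseEffects(0.035, {
            "aki": np.log(1.89), "recurrent_aki": np.log(1.89),
            "age_per10": 0.55, "male": 0.25, "egfr_inv2": 0.25,
            "lnacr": 0.10}),
    )


def _check_mix(name, mix, k):
    mix = tuple(float(x) for x in mix)
    if len(mix) != k:
        raise ConfigError(f"{name} must have {k} entries")
    if any(x < 0 for x in mix):
        raise ConfigError(f"{name} entries must be nonnegative")
    if abs(sum(mix) - 1.0) > 1e-9:
        raise ConfigError(f"{name} must sum to 1 (got {sum(mix)})")
    return mix


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of a synthetic cohort scenario."""

    n_patients: int = 1000
    seed: int = DEFAULT_SEED
    age_mix: tuple = (0.22, 0.58, 0.20)                 # <60, 60-79, >=80
    male_frac: float = 0.54
    egfr_stage_mix: tuple = (0.36, 0.39, 0.15, 0.10)    # <30, 30-44, 45-59, >=60
    acr_log_mean: float = 4.0
    acr_log_sd: float = 1.5
    acr_missing_frac: float = 0.33
    visit_interval_days: float = 60.0
    noise_cv: float = 0.05
    aki_rate_per_year: float = 0.12
    #: optional log-linear dependence of episode intensity on ln ACR
    #: (centered at acr_log_mean) and diabetes, to induce confounding
    aki_conf_lnacr: float = 0.0
    aki_conf_diabetes: float = 0.0
    aki_stage_mix: tuple = (0.75, 0.15, 0.10)
    recovery_halflife_days: float = 15.0
    incomplete_recovery_frac: float = 0.30
    egfr_drift_per_year: float = 0.0
    post_landmark_labs: bool = False
    observation_days: int = renal.DEFAULT_LANDMARK_DAY
    aki_config: AKIConfig = AKIConfig()
    true_effects: TrueEffects = field(default_factory=_default_effects)

    def __post_init__(self):
        if self.n_patients < 0:
            raise ConfigError("n_patients must be nonnegative")
        for nm in ("male_frac", "acr_missing_frac", "incomplete_recovery_frac"):
            v = getattr(self, nm)
            if not 0 <= v <= 1:
                raise ConfigError(f"{nm} must be in [0, 1]")
        for nm in ("visit_interval_days", "noise_cv", "aki_rate_per_year",
                   "recovery_halflife_days", "acr_log_sd"):
            if getattr(self, nm) < 0:
                raise ConfigError(f"{nm} must be nonnegative")
        object.__setattr__(self, "age_mix", _check_mix("age_mix", self.age_mix, 3))
        object.__setattr__(self, "egfr_stage_mix",
                           _check_mix("egfr_stage_mix", self.egfr_stage_mix, 4))
        object.__setattr__(self, "aki_stage_mix",
                           _check_mix("aki_stage_mix", self.aki_stage_mix, 3))

    def replace(self, **kw):
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Low-level pieces
# ---------------------------------------------------------------------------

def creatinine_from_egfr_vec(egfr, age, sex, tol=0.01):
    """Vectorized bisection inverse of the CKD-EPI equation (µmol/L)."""
    egfr = np.asarray(egfr, float)
    age = np.asarray(age, float)
    sex = np.asarray(sex, float)
    lo = np.full(egfr.shape, 5.0)
    hi = np.full(egfr.shape, 5000.0)
    while np.max(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        above = egfr_ckdepi(mid, age, sex) > egfr
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    return 0.5 * (lo + hi)


def visit_days(rng, interval_days, span_days, jitter_frac=0.25):
    """Jittered regular test grid over [0, span]; day 0 always tested."""
    grid = np.arange(0.0, span_days + 1, interval_days)
    jitter = rng.uniform(-jitter_frac, jitter_frac, size=len(grid)) * interval_days
    days = np.round(grid + jitter).astype(int)
    days[0] = 0
    days = np.unique(np.clip(days, 0, span_days))
    return days


def inject_aki_episodes(series: LabSeries, schedule,
                        recovery_halflife_days=15.0,
                        window=(0, renal.DEFAULT_LANDMARK_DAY)):
    """Superimpose AKI creatinine spikes on a series.

    ``schedule`` is a list of dicts (or (day, stage) pairs) with keys:
    ``day``, ``stage`` and optionally ``peak_factor`` (defaults to the
    midpoint of the stage's range) and ``plateau`` (permanent multiplier
    toward which the spike decays; 1.0 = full recovery). Extra measurements
    are inserted at fixed offsets after each spike so detection has data.
    """
    norm = []
    for ep in schedule:
        if isinstance(ep, dict):
            day, stage = int(ep["day"]), int(ep["stage"])
            factor = float(ep.get("peak_factor") or
                           np.mean(STAGE_PEAK_RANGES[stage]))
            plateau = float(ep.get("plateau", 1.0))
        else:
            day, stage = int(ep[0]), int(ep[1])
            factor = float(np.mean(STAGE_PEAK_RANGES[stage]))
            plateau = 1.0
        if not window[0] <= day <= window[1]:
            raise ValueError(f"episode day {day} outside window {window}")
        norm.append((day, factor, plateau))
    if not norm:
        return series

    days = series.days.astype(float)
    scr = series.scr.copy()
    extra_days = []
    for day, _, _ in norm:
        for off in EPISODE_SAMPLING_OFFSETS:
            d = day + off
            if d <= window[1] and d not in series.days and d not in extra_days:
                extra_days.append(d)
    if extra_days:
        extra_days = np.asarray(sorted(extra_days), dtype=float)
        extra_scr = np.interp(extra_days, days, scr)
        days = np.concatenate([days, extra_days])
        scr = np.concatenate([scr, extra_scr])
        order = np.argsort(days)
        days, scr = days[order], scr[order]

    for day, factor, plateau in norm:
        after = days >= day
        decay = 2.0 ** (-(days[after] - day) / recovery_halflife_days)
        scr[after] *= plateau + (factor - plateau) * decay
    return LabSeries(series.patient_id, days.astype(int), scr)


def effect_linear_predictor(rows: pd.DataFrame, loghr: dict):
    """Data-generating linear predictor from landmark covariates (see module
    docstring for the transform conventions)."""
    lp = np.zeros(len(rows))
    for key, beta in loghr.items():
        if key == "aki":
            need = ["aki_2yr", "aki_recurrent"]
            _require(rows, need, key)
            x = rows["aki_2yr"].to_numpy(float) * (1 - rows["aki_recurrent"].to_numpy(float))
        elif key == "recurrent_aki":
            _require(rows, ["aki_recurrent"], key)
            x = rows["aki_recurrent"].to_numpy(float)
        elif key == "age_per10":
            _require(rows, ["age_landmark"], key)
            x = (rows["age_landmark"].to_numpy(float) - 70.0) / 10.0
        elif key == "male":
            _require(rows, ["sex"], key)
            x = rows["sex"].to_numpy(float)
        elif key == "egfr_inv2":
            _require(rows, ["egfr_landmark"], key)
            x = (rows["egfr_landmark"].to_numpy(float) / 30.0) ** -2 - 1.0
        elif key == "lnacr":
            _require(rows, ["lnacr"], key)
            vals = rows["lnacr"].to_numpy(float)
            if np.isnan(vals).any():
                raise ValueError("missing covariate: lnacr")
            x = vals - np.log(30.0)
        else:  # pragma: no cover - guarded by CauseEffects validation
            raise ValueError(f"unknown effect key {key!r}")
        lp += beta * x
    return lp


def _require(rows, cols, key):
    for c in cols:
        if c not in rows.columns:
            raise ValueError(f"missing covariate: {c} (needed for effect {key!r})")


def simulate_outcomes(rows: pd.DataFrame, effects: TrueEffects, seed):
    """Draw (event, time_years) for each row from cause-specific exponential
    hazards: latent times for kidney failure and death compete, with
    administrative censoring at the horizon."""
    rng = np.random.default_rng(seed)
    n = len(rows)
    out = rows.copy()
    times = {}
    for cause_name, ce in (("kidney_failure", effects.kidney_failure),
                           ("death", effects.death)):
        rate = ce.baseline_rate * np.exp(effect_linear_predictor(rows, ce.loghr))
        u = rng.uniform(size=n)
        with np.errstate(divide="ignore"):
            times[cause_name] = np.where(rate > 0, -np.log(u) / np.where(rate > 0, rate, 1.0),
                                         np.inf)
    t_kf, t_d = times["kidney_failure"], times["death"]
    t_min = np.minimum(t_kf, t_d)
    h = effects.horizon_years
    event = np.where(t_min >= h, "censored",
                     np.where(t_kf <= t_d, "kidney_failure", "death"))
    out["event"] = event
    out["time_years"] = np.where(t_min >= h, h, t_min)
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Generated artifact bundle: the three raw tables plus the generator's
    own landmark-truth table (detected exposure flags, landmark covariates
    and simulated outcomes) for diagnostics."""

    config: ScenarioConfig
    patients: pd.DataFrame
    labs: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir):
        import pathlib
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(outdir / "patients.csv", index=False)
        self.labs.to_csv(outdir / "labs.csv", index=False)
        self.events.to_csv(outdir / "events.csv", index=False)
        return outdir


def _sample_covariates(cfg: ScenarioConfig, rng):
    n = cfg.n_patients
    band = rng.choice(3, size=n, p=cfg.age_mix)
    lo = np.array([AGE_BANDS[b][0] for b in band])
    hi = np.array([AGE_BANDS[b][1] for b in band])
    age = rng.uniform(lo, hi)
    sex = (rng.uniform(size=n) < cfg.male_frac).astype(int)
    eband = rng.choice(4, size=n, p=cfg.egfr_stage_mix)
    elo = np.array([EGFR_BANDS[b][0] for b in eband])
    ehi = np.array([EGFR_BANDS[b][1] for b in eband])
    egfr0 = rng.uniform(elo, ehi)
    acr = np.exp(rng.normal(cfg.acr_log_mean, cfg.acr_log_sd, size=n))
    acr_missing = rng.uniform(size=n) < cfg.acr_missing_frac
    diagnosis = rng.choice(DIAGNOSIS_LEVELS, size=n, p=DIAGNOSIS_PROBS)
    diabetes = (rng.uniform(size=n) < 0.60).astype(int)
    sbp = np.round(rng.normal(140, 18, size=n), 0)
    dbp = np.round(rng.normal(78, 10, size=n), 0)
    return pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "age_years": np.round(age, 1),
        "sex": sex,
        "age_band": band, "egfr0": egfr0,
        "acr_true": acr, "acr_missing": acr_missing,
        "diagnosis": diagnosis, "diabetes": diabetes,
        "sbp": sbp, "dbp": dbp,
    })


def generate_cohort(config: ScenarioConfig) -> Cohort:
    """Generate a full synthetic cohort (deterministic given the config).

    Baseline creatinine is back-solved from the sampled eGFR through the
    CKD-EPI inverse; creatinine series follow a jittered regular test grid
    with multiplicative lognormal noise and injected AKI spikes; exposure
    flags are *detected* from the series (not copied from the schedule) and
    drive the simulated post-landmark competing-event times, which are
    written to the event registry as RRT-start / death days.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cov = _sample_covariates(cfg, rng)
    n = cfg.n_patients
    if n == 0:
        empty_labs = pd.DataFrame(columns=["patient_id", "day", "scr_umol_l"])
        empty_events = pd.DataFrame(columns=["patient_id", "rrt_day", "death_day"])
        return Cohort(cfg, _patients_table(cov), empty_labs, empty_events,
                      pd.DataFrame())

    age0 = cov["age_years"].to_numpy()
    sex = cov["sex"].to_numpy()
    base_scr = creatinine_from_egfr_vec(cov["egfr0"].to_numpy(), age0, sex)
    obs = cfg.observation_days
    sigma = np.sqrt(np.log1p(cfg.noise_cv ** 2))
    follow_days = int(round(5 * DAYS_PER_YEAR))

    lab_pid, lab_day, lab_scr = [], [], []
    truth_rows = []
    for i in range(n):
        days = visit_days(rng, cfg.visit_interval_days, obs)
        series = LabSeries(cov["patient_id"].iat[i], days,
                           np.full(len(days), base_scr[i]))
        # schedule AKI spikes (intensity optionally depends on ACR/diabetes)
        lam = cfg.aki_rate_per_year * np.exp(
            cfg.aki_conf_lnacr * (np.log(cov["acr_true"].iat[i]) - cfg.acr_log_mean)
            + cfg.aki_conf_diabetes * cov["diabetes"].iat[i])
        n_ep = rng.poisson(lam * obs / DAYS_PER_YEAR)
        schedule = []
        if n_ep > 0:
            cand = np.sort(rng.integers(40, max(41, obs - 90), size=n_ep))
            min_sep = max(60, cfg.aki_config.recurrence_gap_days + 30)
            chosen = []
            for d in cand:
                if not chosen or d - chosen[-1] >= min_sep:
                    chosen.append(int(d))
            for d in chosen:
                stage = int(rng.choice((1, 2, 3), p=cfg.aki_stage_mix))
                factor = rng.uniform(*STAGE_PEAK_RANGES[stage])
                incomplete = rng.uniform() < cfg.incomplete_recovery_frac
                plateau = 1.0 + 0.1 * (factor - 1.0) if incomplete else 1.0
                schedule.append({"day": d, "stage": stage,
                                 "peak_factor": factor, "plateau": plateau})
            series = inject_aki_episodes(series, schedule,
                                         cfg.recovery_halflife_days,
                                         window=(0, obs))
        scr = series.scr.copy()
        if cfg.egfr_drift_per_year > 0:
            frac = np.maximum(1.0 - cfg.egfr_drift_per_year * series.days
                              / (DAYS_PER_YEAR * cov["egfr0"].iat[i]), 0.25)
            scr = scr * frac ** (-1.0 / 1.209)
        if sigma > 0:
            scr = scr * np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=len(scr)))
        series = LabSeries(series.patient_id, series.days, scr)

        episodes = detect_aki(series, (0, obs), cfg.aki_config)
        aki_2yr, aki_rec, stage_max = classify_recurrence(episodes)
        lm_idx = np.nonzero(series.days <= obs)[0][-1]
        egfr_lm = egfr_ckdepi(series.scr[lm_idx],
                              age0[i] + series.days[lm_idx] / DAYS_PER_YEAR,
                              sex[i])
        truth_rows.append({
            "patient_id": cov["patient_id"].iat[i],
            "egfr_baseline_true": float(cov["egfr0"].iat[i]),
            "age_landmark": age0[i] + obs / DAYS_PER_YEAR,
            "sex": int(sex[i]),
            "egfr_landmark": float(egfr_lm),
            "lnacr": float(np.log(cov["acr_true"].iat[i])),
            "aki_2yr": aki_2yr, "aki_recurrent": aki_rec,
            "aki_stage_max": stage_max,
            "n_injected": len(schedule),
        })
        lab_pid.append(np.full(len(series), cov["patient_id"].iat[i]))
        lab_day.append(series.days)
        lab_scr.append(series.scr)

    truth = pd.DataFrame(truth_rows)
    truth = simulate_outcomes(truth, cfg.true_effects,
                              np.random.default_rng(cfg.seed + 1))

    # event registry: simulated kidney failure enters as RRT start
    ev_rows = []
    for r in truth.itertuples(index=False):
        day = obs + max(1, int(round(r.time_years * DAYS_PER_YEAR)))
        if r.event == "kidney_failure":
            ev_rows.append({"patient_id": r.patient_id, "rrt_day": day,
                            "death_day": np.nan})
        elif r.event == "death":
            ev_rows.append({"patient_id": r.patient_id, "rrt_day": np.nan,
                            "death_day": day})
    events = pd.DataFrame(ev_rows, columns=["patient_id", "rrt_day", "death_day"])

    if cfg.post_landmark_labs:
        ev_idx = events.set_index("patient_id") if len(events) else None
        for i in range(n):
            pid = cov["patient_id"].iat[i]
            end_day = obs + follow_days
            if ev_idx is not None and pid in ev_idx.index:
                r = ev_idx.loc[pid]
                for c in ("rrt_day", "death_day"):
                    if not pd.isna(r[c]):
                        end_day = min(end_day, int(r[c]))
            extra = visit_days(rng, cfg.visit_interval_days, end_day - obs - 1)[1:] + obs
            if len(extra) == 0:
                continue
            scr_e = np.full(len(extra), base_scr[i])
            if cfg.egfr_drift_per_year > 0:
                frac = np.maximum(1.0 - cfg.egfr_drift_per_year * extra
                                  / (DAYS_PER_YEAR * cov["egfr0"].iat[i]), 0.25)
                scr_e = scr_e * frac ** (-1.0 / 1.209)
            if sigma > 0:
                scr_e = scr_e * np.exp(rng.normal(-sigma ** 2 / 2, sigma,
                                                  size=len(scr_e)))
            lab_pid.append(np.full(len(extra), pid))
            lab_day.append(extra)
            lab_scr.append(scr_e)

    labs = pd.DataFrame({
        "patient_id": np.concatenate(lab_pid),
        "day": np.concatenate(lab_day).astype(int),
        "scr_umol_l": np.round(np.concatenate(lab_scr), 2),
    }).sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)

    return Cohort(cfg, _patients_table(cov), labs, events, truth)


def _patients_table(cov):
    acr = cov["acr_true"].where(~cov["acr_missing"], np.nan) if len(cov) else []
    return pd.DataFrame({
        "patient_id": cov.get("patient_id", []),
        "age_years": cov.get("age_years", []),
        "sex": cov.get("sex", []),
        "acr_mg_g": np.round(acr, 1) if len(cov) else [],
        "diagnosis": cov.get("diagnosis", []),
        "diabetes": cov.get("diabetes", []),
        "sbp": cov.get("sbp", []),
        "dbp": cov.get("dbp", []),
    })
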