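"""Clinical-algorithmic definitions: eGFR, AKI e-alert detection, outcome
adjudication and landmark cohort construction.

All creatinine values are serum creatinine in µmol/L; eGFR is in
mL/min/1.73 m². Days are integer days since a patient's entry into
follow-up. Event times are converted to years by dividing by 365.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UMOL_PER_MGDL = 88.4
#: creatinine above which stage 3 is assigned regardless of ratio (µmol/L)
STAGE3_ABSOLUTE_SCR = 353.6
DAYS_PER_YEAR = 365.25
DEFAULT_LANDMARK_DAY = 730


class PreLandmarkEvent(Exception):
    """Raised when a terminal event occurs before the landmark (the record
    must be excluded from the landmark cohort, not analysed)."""


# ---------------------------------------------------------------------------
# eGFR (CKD-EPI 2009 creatinine equation, race term omitted)
# ---------------------------------------------------------------------------

def egfr_ckdepi(scr_umol_l, age_years, sex):
    """CKD-EPI (2009) creatinine eGFR in mL/min/1.73 m².

    Parameters
    ----------
    scr_umol_l : float or array
        Serum creatinine in µmol/L (> 0).
    age_years : float or array
        Age in years (>= 18).
    sex : int or array
        1 = male, 0 = female.

    Notes
    -----
    The race coefficient is omitted (no race variable exists in the data
    model). Creatinine is converted internally at 1 mg/dL = 88.4 µmol/L.
    """
    scr = np.asarray(scr_umol_l, dtype=float)
    age = np.asarray(age_years, dtype=float)
    male = np.asarray(sex, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("scr and age must be positive")
    scr_mgdl = scr / UMOL_PER_MGDL
    kappa = np.where(male == 1, 0.9, 0.7)
    alpha = np.where(male == 1, -0.411, -0.329)
    ratio = scr_mgdl / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age
        * np.where(male == 1, 1.0, 1.018)
    )
    if egfr.ndim == 0:
        return float(egfr)
    return egfr


def creatinine_from_egfr(egfr, age_years, sex, tol=0.01):
    """Back-solve serum creatinine (µmol/L) from a target eGFR by bisection.

    ``egfr_ckdepi`` is strictly decreasing in creatinine, so bisection on
    [5, 5000] µmol/L converges; the result reproduces the target eGFR to
    well under 0.1 mL/min/1.73 m² at the default tolerance of 0.01 µmol/L.
    """
    if egfr <= 0:
        raise ValueError("egfr must be positive")
    lo, hi = 5.0, 5000.0
    if egfr_ckdepi(lo, age_years, sex) < egfr:
        raise ValueError(f"target eGFR {egfr} unattainable (too high)")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if egfr_ckdepi(mid, age_years, sex) > egfr:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Lab series and AKI configuration
# ---------------------------------------------------------------------------

@dataclass
class LabSeries:
    """One patient's time-ordered creatinine measurements.

    Exact duplicate (day, scr) points are dropped on construction so that
    re-inserting an identical measurement never changes detection results.
    Distinct values on the same day are rejected.
    """

    patient_id: object
    days: np.ndarray
    scr: np.ndarray

    def __init__(self, patient_id, days, scr):
        days = np.asarray(days, dtype=int)
        scr = np.asarray(scr, dtype=float)
        if days.shape != scr.shape:
            raise ValueError("days and scr must have equal length")
        if np.any(scr <= 0):
            raise ValueError("creatinine values must be positive")
        order = np.argsort(days, kind="stable")
        days, scr = days[order], scr[order]
        keep = np.ones(len(days), dtype=bool)
        for i in range(1, len(days)):
            if days[i] == days[i - 1]:
                if scr[i] == scr[i - 1]:
                    keep[i] = False
                else:
                    raise ValueError(
                        f"conflicting creatinine values on day {days[i]} "
                        f"for patient {patient_id}"
                    )
        self.patient_id = patient_id
        self.days = days[keep]
        self.scr = scr[keep]

    def __len__(self):
        return len(self.days)

    def egfr(self, age_at_entry_years, sex):
        """eGFR at each measurement, ageing the patient along the series."""
        ages = age_at_entry_years + self.days / DAYS_PER_YEAR
        return egfr_ckdepi(self.scr, ages, np.full(len(self), sex))


@dataclass(frozen=True)
class AKIConfig:
    """Thresholds and windows for the three-criterion AKI definition.

    Criterion (i): creatinine >= ratio_threshold x median of values 8-90
    days prior (91-365 days prior if that window is empty).
    Criterion (ii): >= ratio_threshold x lowest value within 7 days.
    Criterion (iii): rise > rapid_rise µmol/L above the lowest value within
    48 h.
    """

    ratio_threshold: float = 1.5
    medium_window: tuple = (8, 90)
    fallback_window: tuple = (91, 365)
    short_window: int = 7
    rapid_window: int = 2
    rapid_rise: float = 26.0
    criteria_enabled: frozenset = frozenset({"i", "ii", "iii"})
    #: triggers closer than this merge into a single episode; the source definition never
    #: states when triggers become distinct episodes, so this is configurable
    recurrence_gap_days: int = 30

    def __post_init__(self):
        if self.ratio_threshold <= 0 or self.rapid_rise <= 0:
            raise ValueError("thresholds must be positive")
        if not (self.rapid_window <= self.short_window
                < self.medium_window[0] <= self.medium_window[1]
                < self.fallback_window[0] <= self.fallback_window[1]):
            raise ValueError("lookback windows must be ordered and disjoint")
        if not self.criteria_enabled <= {"i", "ii", "iii"}:
            raise ValueError("criteria_enabled must be a subset of {i, ii, iii}")


@dataclass
class AKIEpisode:
    onset_day: int
    end_day: int
    trigger_criterion: str  # "i" | "ii" | "iii"
    peak_ratio: float
    stage: int

    def __post_init__(self):
        if self.onset_day > self.end_day:
            raise ValueError("onset_day must be <= end_day")


# ---------------------------------------------------------------------------
# AKI detection
# ---------------------------------------------------------------------------

def reference_creatinine(series: LabSeries, index_day: int, config: AKIConfig = AKIConfig()):
    """Reference creatinine values for the measurement at ``index_day``.

    Returns ``(ref_median, ref_min7, ref_min48)``; each is ``None`` when its
    lookback window holds no measurement. The median window is [8, 90] days
    prior, falling back to [91, 365] days prior when empty; the minima use
    (0, 7] and (0, 2] days prior.
    """
    pos = np.nonzero(series.days == index_day)[0]
    if len(pos) == 0:
        raise ValueError(f"no measurement on day {index_day}")
    delta = index_day - series.days  # days prior; positive = earlier

    lo, hi = config.medium_window
    in_med = (delta >= lo) & (delta <= hi)
    if in_med.any():
        ref_median = float(np.median(series.scr[in_med]))
    else:
        flo, fhi = config.fallback_window
        in_fb = (delta >= flo) & (delta <= fhi)
        ref_median = float(np.median(series.scr[in_fb])) if in_fb.any() else None

    in7 = (delta >= 1) & (delta <= config.short_window)
    ref_min7 = float(series.scr[in7].min()) if in7.any() else None
    in48 = (delta >= 1) & (delta <= config.rapid_window)
    ref_min48 = float(series.scr[in48].min()) if in48.any() else None
    return ref_median, ref_min7, ref_min48


def _stage(peak_ratio, peak_scr):
    if peak_ratio >= 3.0 or peak_scr >= STAGE3_ABSOLUTE_SCR:
        return 3
    if peak_ratio >= 2.0:
        return 2
    return 1


def detect_aki(series: LabSeries, window=(0, DEFAULT_LANDMARK_DAY),
               config: AKIConfig = AKIConfig()):
    """Detect AKI episodes in a creatinine series.

    A measurement triggers when any enabled criterion fires (the recorded
    criterion is the lowest-numbered satisfied one); consecutive triggers
    separated by fewer than ``recurrence_gap_days`` merge into one episode.
    The episode's peak ratio is the maximum creatinine over its triggers
    divided by the reference of the first trigger; staging is 3 at ratio
    >= 3 or creatinine >= 353.6 µmol/L, 2 at ratio in [2, 3), else 1.

    Detection starts at the second measurement (the first has no reference).
    """
    if len(series) == 0:
        return []
    start, end = window
    triggers = []  # (day, scr, criterion, reference)
    for i in range(1, len(series)):
        day = int(series.days[i])
        if day < start or day > end:
            continue
        scr = float(series.scr[i])
        ref_median, ref_min7, ref_min48 = reference_creatinine(series, day, config)
        crit = None
        ref = None
        if ("i" in config.criteria_enabled and ref_median is not None
                and scr >= config.ratio_threshold * ref_median):
            crit, ref = "i", ref_median
        elif ("ii" in config.criteria_enabled and ref_min7 is not None
                and scr >= config.ratio_threshold * ref_min7):
            crit, ref = "ii", ref_min7
        elif ("iii" in config.criteria_enabled and ref_min48 is not None
                and scr - ref_min48 > config.rapid_rise):
            crit, ref = "iii", ref_min48
        if crit is not None:
            triggers.append((day, scr, crit, ref))

    episodes = []
    current = None  # [onset, end, criterion, first_ref, peak_scr]
    for day, scr, crit, ref in triggers:
        if current is not None and day - current[1] < config.recurrence_gap_days:
            current[1] = day
            current[4] = max(current[4], scr)
        else:
            if current is not None:
                episodes.append(current)
            current = [day, day, crit, ref, scr]
    if current is not None:
        episodes.append(current)

    out = []
    for onset, endd, crit, ref, peak in episodes:
        ratio = peak / ref
        out.append(AKIEpisode(onset, endd, crit, ratio, _stage(ratio, peak)))
    return out


def classify_recurrence(episodes, config: AKIConfig = AKIConfig()):
    """Summarize a patient's episodes as (aki_2yr, aki_recurrent, stage_max)."""
    if not episodes:
        return 0, 0, None
    stage_max = max(e.stage for e in episodes)
    return 1, int(len(episodes) >= 2), stage_max


# ---------------------------------------------------------------------------
# Outcome adjudication
# ---------------------------------------------------------------------------

def _first_sustained_below(days, values, threshold, after_day, sustain_days=90):
    """First day d > after_day where values fall below ``threshold`` and stay
    below it through a confirmatory measurement at >= d + sustain_days (no
    intervening value at or above threshold). Returns None if never."""
    n = len(days)
    for i in range(n):
        if days[i] <= after_day or values[i] >= threshold:
            continue
        ok = None
        for j in range(i + 1, n):
            if values[j] >= threshold:
                ok = False
                break
            if days[j] >= days[i] + sustain_days:
                ok = True
                break
        if ok:
            return int(days[i])
    return None


def adjudicate_outcome(series: LabSeries, rrt_day, death_day, landmark_day,
                       age_years=None, sex=None, horizon_years=5.0,
                       egfr_threshold=15.0):
    """Adjudicate (event, time_years) for one patient from the landmark.

    Kidney failure occurs at the first post-landmark day where long-term RRT
    starts, or where eGFR drops below ``egfr_threshold`` and every subsequent
    eGFR through 90 further days stays below it (with a confirmatory
    measurement at >= 90 days). Death beforehand is the competing event;
    otherwise the patient is censored at ``horizon_years``. A death or RRT
    start at or before the landmark raises :class:`PreLandmarkEvent`.
    """
    if death_day is not None and death_day <= landmark_day:
        raise PreLandmarkEvent(f"death on day {death_day} precedes landmark")
    if rrt_day is not None and rrt_day <= landmark_day:
        raise PreLandmarkEvent(f"RRT on day {rrt_day} precedes landmark")

    horizon_day = landmark_day + int(round(horizon_years * DAYS_PER_YEAR))
    kf_day = None
    if rrt_day is not None:
        kf_day = int(rrt_day)
    if len(series) > 0 and age_years is not None:
        egfr = series.egfr(age_years, sex)
        sus = _first_sustained_below(series.days, egfr, egfr_threshold, landmark_day)
        if sus is not None and (kf_day is None or sus < kf_day):
            kf_day = sus

    if kf_day is not None and (death_day is None or kf_day <= death_day):
        if kf_day <= horizon_day:
            return "kidney_failure", (kf_day - landmark_day) / DAYS_PER_YEAR
    elif death_day is not None and death_day <= horizon_day:
        return "death", (death_day - landmark_day) / DAYS_PER_YEAR
    return "censored", horizon_years


def adjudicate_decline30(series: LabSeries, rrt_day, landmark_day,
                         death_day=None, age_years=None, sex=None,
                         horizon_years=5.0):
    """Alternative endpoint: sustained 30% eGFR decline from landmark, or RRT.

    Same 90-day sustainment rule as :func:`adjudicate_outcome`, with the
    absolute threshold replaced by 0.70 x the eGFR at the landmark (last
    measurement at or before it).
    """
    threshold = None
    if len(series) > 0 and age_years is not None:
        at_lm = series.days <= landmark_day
        if at_lm.any():
            idx = np.nonzero(at_lm)[0][-1]
            age_at = age_years + series.days[idx] / DAYS_PER_YEAR
            threshold = 0.70 * egfr_ckdepi(series.scr[idx], age_at, sex)
    if threshold is None:
        threshold = 0.0  # no landmark eGFR: only RRT can qualify
    return adjudicate_outcome(series, rrt_day, death_day, landmark_day,
                              age_years, sex, horizon_years,
                              egfr_threshold=threshold)


# ---------------------------------------------------------------------------
# Landmark cohort construction
# ---------------------------------------------------------------------------

def proteinuria_category(acr_mg_g):
    """KDIGO albuminuria category from ACR in mg/g (NaN -> not_tested)."""
    if acr_mg_g is None or (isinstance(acr_mg_g, float) and np.isnan(acr_mg_g)):
        return "not_tested"
    if acr_mg_g > 300:
        return "severe"
    if acr_mg_g >= 30:
        return "moderate"
    return "none_mild"


LANDMARK_COLUMNS = [
    "patient_id", "age_landmark", "sex", "egfr_landmark", "lnacr",
    "proteinuria_cat", "diagnosis_cat", "aki_2yr", "aki_recurrent",
    "aki_stage_max", "aki_criterion_iii_only", "event", "time_years",
]


def build_landmark_cohort(patients: pd.DataFrame, labs: pd.DataFrame,
                          events: pd.DataFrame,
                          config: AKIConfig = AKIConfig(),
                          landmark_day: int = DEFAULT_LANDMARK_DAY,
                          horizon_years: float = 5.0,
                          endpoint: str = "kf15"):
    """Assemble one analysis-ready row per patient surviving the landmark.

    Excludes patients who die, start RRT, or meet the sustained eGFR < 15
    rule on or before the landmark, and patients with no creatinine test in
    the observation window. AKI exposure flags are computed over days
    [0, landmark_day]; landmark eGFR comes from the last measurement at or
    before the landmark. ``endpoint`` selects the primary kidney-failure
    definition (``kf15``) or the 30% sustained-decline alternative
    (``decline30``).

    Returns a DataFrame with :data:`LANDMARK_COLUMNS`; exclusion counts are
    stored in ``df.attrs["exclusions"]`` and logged.
    """
    if endpoint not in ("kf15", "decline30"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    labs_by_pid = {pid: g for pid, g in labs.groupby("patient_id", sort=False)}
    ev = events.set_index("patient_id") if len(events) else pd.DataFrame()
    cfg_iii = replace(config, criteria_enabled=frozenset({"iii"}))

    rows = []
    excl = {"no_labs": 0, "pre_landmark_event": 0, "pre_landmark_kf": 0,
            "no_landmark_egfr": 0}
    for rec in patients.itertuples(index=False):
        pid = rec.patient_id
        g = labs_by_pid.get(pid)
        if g is None or len(g) == 0:
            excl["no_labs"] += 1
            continue
        series = LabSeries(pid, g["day"].to_numpy(), g["scr_umol_l"].to_numpy())
        rrt_day = death_day = None
        if pid in getattr(ev, "index", []):
            r = ev.loc[pid]
            rrt_day = None if pd.isna(r.get("rrt_day")) else int(r["rrt_day"])
            death_day = None if pd.isna(r.get("death_day")) else int(r["death_day"])

        at_lm = series.days <= landmark_day
        if not at_lm.any():
            excl["no_landmark_egfr"] += 1
            continue
        age0 = float(rec.age_years)
        sex = int(rec.sex)

        # pre-landmark sustained kidney failure -> not eligible
        pre_egfr = series.egfr(age0, sex)
        pre_kf = _first_sustained_below(series.days, pre_egfr, 15.0, -1)
        if pre_kf is not None and pre_kf <= landmark_day:
            excl["pre_landmark_kf"] += 1
            continue
        try:
            if endpoint == "kf15":
                event, time_years = adjudicate_outcome(
                    series, rrt_day, death_day, landmark_day, age0, sex,
                    horizon_years)
            else:
                event, time_years = adjudicate_decline30(
                    series, rrt_day, landmark_day, death_day, age0, sex,
                    horizon_years)
        except PreLandmarkEvent:
            excl["pre_landmark_event"] += 1
            continue

        episodes = detect_aki(series, (0, landmark_day), config)
        aki_2yr, aki_rec, stage_max = classify_recurrence(episodes, config)
        iii_only = int(bool(detect_aki(series, (0, landmark_day), cfg_iii)))

        lm_idx = np.nonzero(at_lm)[0][-1]
        lm_day = int(series.days[lm_idx])
        egfr_lm = egfr_ckdepi(series.scr[lm_idx], age0 + lm_day / DAYS_PER_YEAR, sex)

        acr = getattr(rec, "acr_mg_g", np.nan)
        acr = np.nan if acr is None or pd.isna(acr) else float(acr)
        rows.append({
            "patient_id": pid,
            "age_landmark": age0 + landmark_day / DAYS_PER_YEAR,
            "sex": sex,
            "egfr_landmark": float(egfr_lm),
            "lnacr": np.log(acr) if np.isfinite(acr) and acr > 0 else np.nan,
            "proteinuria_cat": proteinuria_category(acr if np.isfinite(acr) else np.nan),
            "diagnosis_cat": getattr(rec, "diagnosis", "not_recorded"),
            "aki_2yr": aki_2yr,
            "aki_recurrent": aki_rec,
            "aki_stage_max": stage_max,
            "aki_criterion_iii_only": iii_only,
            "event": event,
            "time_years": float(time_years),
        })

    n_excl = sum(excl.values())
    if n_excl:
        logger.info("landmark cohort: excluded %d patients (%s)", n_excl, excl)
    df = pd.DataFrame(rows, columns=LANDMARK_COLUMNS)
    df.attrs["exclusions"] = excl
    return df
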