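"""Discrimination, calibration and decision-curve evaluation of 5-year
risk predictions under competing risks.

The 5-year outcome used for AUC, calibration bins and decision curves is a
determinate binary status: kidney failure by 5 years versus event-free or
dead at 5 years (death before kidney failure counts as "no event",
consistent with the subdistribution prediction target). Subjects censored
before 5 years are indeterminate and excluded with a logged count; with
administrative-censoring-only synthetic cohorts every subject is
determinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import survival as sv

logger = logging.getLogger(__name__)


def binary_outcome_5y(rows: pd.DataFrame, horizon=5.0):
    """(outcome, determinate) arrays for the 5-year kidney-failure status."""
    ev = rows["event"].to_numpy()
    t = rows["time_years"].to_numpy(dtype=float)
    y = (ev == "kidney_failure") & (t <= horizon)
    determinate = (ev != "censored") | (t >= horizon)
    n_excl = int((~determinate).sum())
    if n_excl:
        logger.info("binary_outcome_5y: %d indeterminate subjects excluded", n_excl)
    return y.astype(int), determinate


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

def auc(predictions, outcomes):
    """Mann-Whitney concordance (ties counted 1/2) of predictions against a
    binary outcome."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires at least one event and one non-event")
    ranks = stats.rankdata(p)
    return (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def _delong_placements(pred, y):
    """Midrank placement values V10 (per event) and V01 (per non-event)."""
    x = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=int)
    pos, neg = x[y == 1], x[y == 0]
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    rank_all = stats.rankdata(allv)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return v10, v01


def compare_auc(pred_a, pred_b, outcomes):
    """DeLong paired test for the difference of two AUCs on identical
    subjects; returns (auc_a, auc_b, delta, p_value)."""
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if pred_a.shape != pred_b.shape or pred_a.shape != y.shape:
        raise ValueError("paired AUC comparison requires equal-length inputs "
                         "on identical subjects")
    auc_a, auc_b = auc(pred_a, y), auc(pred_b, y)
    v10a, v01a = _delong_placements(pred_a, y)
    v10b, v01b = _delong_placements(pred_b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / np.sqrt(var)
        p = 2 * stats.norm.sf(abs(z))
    return auc_a, auc_b, delta, p


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    bins: pd.DataFrame          # mean_predicted, observed_proportion, n
    slope: float
    slope_ci: tuple
    n: int


def calibration(predictions, linear_predictors, rows: pd.DataFrame,
                n_bins=10, observed="binary", horizon=5.0):
    """Calibration by tenths of predicted probability plus calibration slope.

    The slope is the coefficient of the model's linear predictor as the sole
    covariate in a Fine-Gray model for kidney failure (death competing) on
    ``rows``, with a Wald 95% CI. ``observed`` selects the per-bin observed
    proportion: determinate ``binary`` status or the ``aalen_johansen``
    5-year cumulative incidence.
    """
    pred = np.asarray(predictions, dtype=float)
    lp = np.asarray(linear_predictors, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictors must be finite")
    y, determinate = binary_outcome_5y(rows, horizon)

    n_distinct = len(np.unique(pred))
    bins_wanted = n_bins
    if n_distinct < n_bins:
        logger.warning("only %d distinct predictions; coarser binning", n_distinct)
        bins_wanted = max(2, n_distinct)
    binned = pd.qcut(pred, bins_wanted, labels=False, duplicates="drop")

    records = []
    for b in np.unique(binned):
        m = binned == b
        if observed == "binary":
            mm = m & determinate
            obs = float(y[mm].mean()) if mm.sum() else np.nan
        elif observed == "aalen_johansen":
            cif = sv.aalen_johansen_cif(rows[m], "kidney_failure")[None]
            obs = float(cif[1][-1]) if len(cif[1]) else 0.0
        else:
            raise ValueError(f"unknown observed mode {observed!r}")
        records.append({"bin": int(b), "mean_predicted": float(pred[m].mean()),
                        "observed_proportion": obs, "n": int(m.sum())})
    bins_df = pd.DataFrame(records)

    slope_rows = rows.copy()
    slope_rows["_lp"] = lp
    fit = sv.fit_fine_gray(slope_rows, sv.CovariateSpec([sv.identity("_lp")]),
                           "kidney_failure")
    slope = float(fit.coef[0])
    ci = (slope - 1.96 * float(fit.se[0]), slope + 1.96 * float(fit.se[0]))
    return CalibrationReport(bins_df, slope, ci, len(rows))


# ---------------------------------------------------------------------------
# Decision curve analysis
# ---------------------------------------------------------------------------

def decision_curve(predictions: dict, outcomes, thresholds=None):
    """Net benefit TP/n - (FP/n) * p_t/(1-p_t) at each threshold for each
    model, plus treat-all and treat-none reference strategies.

    ``predictions`` maps model name to a risk array; the default threshold
    grid is 0-10% in 0.1% steps. Thresholds must lie in [0, 0.99].
    """
    if thresholds is None:
        thresholds = np.arange(0.0, 0.1005, 0.001)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds < 0) or np.any(thresholds > 0.99):
        raise ValueError("thresholds must lie in [0, 0.99]")
    y = np.asarray(outcomes, dtype=int)
    n = len(y)
    prevalence = y.mean()

    rows = []
    for pt in thresholds:
        weight = pt / (1.0 - pt)
        rows.append({"threshold": pt, "model": "treat_all",
                     "tp": int(y.sum()), "fp": int(n - y.sum()), "n": n,
                     "net_benefit": prevalence - (1 - prevalence) * weight})
        rows.append({"threshold": pt, "model": "treat_none",
                     "tp": 0, "fp": 0, "n": n, "net_benefit": 0.0})
        for name, pred in predictions.items():
            pred = np.asarray(pred, dtype=float)
            treat = pred >= pt
            tp = int((treat & (y == 1)).sum())
            fp = int((treat & (y == 0)).sum())
            rows.append({"threshold": pt, "model": name, "tp": tp, "fp": fp,
                         "n": n, "net_benefit": tp / n - (fp / n) * weight})
    return pd.DataFrame(rows)
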