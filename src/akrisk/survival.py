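"""Partial-likelihood survival engine.

Fits cause-specific Cox models (competing events censored at their time)
and Fine-Gray subdistribution-hazard models (competing-event subjects kept
in later risk sets with inverse-probability-of-censoring weights) by
Newton-Raphson on the Efron-tie-corrected partial likelihood, plus
nonparametric Kaplan-Meier and Aalen-Johansen estimators.

Both model kinds share one likelihood kernel: the Fine-Gray risk-set sums
factorize as (subjects still under observation) + G(t-) x (cumulated
weighted competing-event subjects), so each Newton iteration is O(n p^2)
after a single sort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Covariate specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """One model term: a named pure transform of a source column.

    kinds:
      identity               x
      per10_centered         (x - center) / 10
      inverse_square         (x / scale) ** -2
      shift_scale            (x - shift) / scale
      categorical            reference-cell dummies for each non-reference level
    """

    name: str
    column: str
    kind: str = "identity"
    center: float = 70.0
    shift: float = 0.0
    scale: float = 1.0
    reference: object = None
    levels: tuple = ()

    def design(self, df: pd.DataFrame):
        x = df[self.column]
        if self.kind == "identity":
            return {self.name: x.to_numpy(dtype=float)}
        if self.kind == "per10_centered":
            return {self.name: (x.to_numpy(dtype=float) - self.center) / 10.0}
        if self.kind == "inverse_square":
            return {self.name: (x.to_numpy(dtype=float) / self.scale) ** -2}
        if self.kind == "shift_scale":
            return {self.name: (x.to_numpy(dtype=float) - self.shift) / self.scale}
        if self.kind == "categorical":
            levels = self.levels or tuple(sorted(x.dropna().unique()))
            cols = {}
            for lev in levels:
                if lev == self.reference:
                    continue
                cols[f"{self.name}[{lev}]"] = (x == lev).to_numpy(dtype=float)
            return cols
        raise ValueError(f"unknown term kind {self.kind!r}")


def identity(column, name=None):
    return Term(name or column, column, "identity")


def per10_centered(column, center=70.0, name=None):
    return Term(name or f"{column}_per10", column, "per10_centered", center=center)


def inverse_square(column, scale=30.0, name=None):
    return Term(name or f"{column}_inv2", column, "inverse_square", scale=scale)


def shift_scale(column, shift, scale, name=None):
    return Term(name or column, column, "shift_scale", shift=shift, scale=scale)


def categorical(column, reference, levels=(), name=None):
    return Term(name or column, column, "categorical",
                reference=reference, levels=tuple(levels))


@dataclass(frozen=True)
class CovariateSpec:
    terms: tuple

    def __init__(self, terms):
        object.__setattr__(self, "terms", tuple(terms))

    def build(self, df: pd.DataFrame):
        """Design matrix and column names; raises on missing values."""
        cols = {}
        for t in self.terms:
            if t.column not in df.columns:
                raise ValueError(f"missing covariate column {t.column!r}")
            if df[t.column].isna().any():
                raise ValueError(f"covariate {t.column!r} contains missing values")
            cols.update(t.design(df))
        names = list(cols)
        X = np.column_stack([cols[n] for n in names]) if names else np.empty((len(df), 0))
        return X, names


# ---------------------------------------------------------------------------
# Kaplan-Meier helpers
# ---------------------------------------------------------------------------

def kaplan_meier(time, event):
    """Right-continuous KM survival curve: returns (times, surv) step arrays
    over the distinct event times (surv value applies at t >= times[k])."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    te = t[e == 1]
    uniq = np.unique(te)
    n = len(t)
    at_risk = n - np.searchsorted(t, uniq, side="left")
    d = (np.searchsorted(te, uniq, side="right")
         - np.searchsorted(te, uniq, side="left"))
    surv = np.cumprod(1.0 - d / at_risk)
    return uniq, surv


def _step_eval(times, values, query, side="right", start=1.0):
    """Evaluate a step function at ``query``. side='right' gives the
    right-continuous value S(t); side='left' gives S(t-)."""
    idx = np.searchsorted(times, query, side=side) - 1
    out = np.where(idx >= 0, np.concatenate([[start], values])[idx + 1], start)
    return out


def censoring_survival(time, any_event):
    """KM estimate of the censoring distribution G (any_event=1 means an
    observed event of either cause; 0 means censoring)."""
    return kaplan_meier(time, 1 - np.asarray(any_event, dtype=int))


# ---------------------------------------------------------------------------
# Partial-likelihood kernel
# ---------------------------------------------------------------------------

def _prepare(time, d, comp, X, weights=None):
    """Sort ascending by time and precompute group structure."""
    time = np.asarray(time, dtype=float)
    d = np.asarray(d, dtype=int)
    comp = np.asarray(comp, dtype=int)
    order = np.argsort(time, kind="stable")
    t, d, comp, X = time[order], d[order], comp[order], np.asarray(X, float)[order]
    w = np.ones(len(t)) if weights is None else np.asarray(weights, float)[order]

    # censoring KM for IPCW (only needed when competing events present)
    if comp.any():
        ct, cs = censoring_survival(t, (d | comp))
        G_at = _step_eval(ct, cs, t, side="left")  # G(T_i -)
        if np.any(G_at[comp == 1] <= 0):
            raise ConvergenceError(
                "censoring survival G reaches 0 before a competing event; "
                "truncate follow-up")
        ginv = np.where(comp == 1, 1.0 / np.where(G_at > 0, G_at, 1.0), 0.0)
    else:
        ct, cs = np.array([]), np.array([])
        ginv = np.zeros(len(t))

    event_times = np.unique(t[d == 1])
    # index of first subject with t_j >= u (suffix start) and first with
    # t_j >= u for the strict-prefix boundary of the competing cumsum
    suf_start = np.searchsorted(t, event_times, side="left")
    grp_end = np.searchsorted(t, event_times, side="right")
    Gm = _step_eval(ct, cs, event_times, side="left") if comp.any() else np.ones(len(event_times))
    return t, d, comp, X, w, ginv, event_times, suf_start, grp_end, Gm


def _pl_derivs(beta, prep):
    """Log partial likelihood with gradient and Hessian under Efron tie
    handling. Risk-set sums are accumulated per event-time segment (exact
    small sums, then a short cumulative pass over ~#distinct event times),
    which keeps both cost and floating-point error low at large n."""
    t, d, comp, X, w, ginv, event_times, suf_start, grp_end, Gm = prep
    n, p = X.shape
    K = len(event_times)
    eta = X @ beta
    eta = np.clip(eta, -200, 200)
    r = w * np.exp(eta)
    rX = r[:, None] * X

    # suffix sums over subjects with t_j >= u, per event-time group:
    # segment k covers indices [suf_start[k], suf_start[k+1])
    seg = np.concatenate([suf_start, [n]])
    sqw = np.sqrt(r)[:, None] * X
    S0seg = np.add.reduceat(np.concatenate([r, [0.0]]), seg)[:K]
    S1seg = np.add.reduceat(np.vstack([rX, np.zeros((1, p))]), seg, axis=0)[:K]
    S2seg = np.empty((K, p, p))
    for k in range(K):
        Wk = sqw[seg[k]:seg[k + 1]]
        S2seg[k] = Wk.T @ Wk
    S0s = np.cumsum(S0seg[::-1])[::-1]
    S1s = np.cumsum(S1seg[::-1], axis=0)[::-1]
    S2s = np.cumsum(S2seg[::-1], axis=0)[::-1]

    # prefix sums over competing-event subjects with t_j < u, IPCW-scaled
    has_comp = bool(comp.any())
    if has_comp:
        b = comp * r * ginv
        bX = b[:, None] * X
        sqb = np.sqrt(b)[:, None] * X
        edges = np.concatenate([[0], suf_start])
        B0seg = np.add.reduceat(np.concatenate([b, [0.0]]), edges)[:K]
        B1seg = np.add.reduceat(np.vstack([bX, np.zeros((1, p))]), edges, axis=0)[:K]
        empty_seg = np.diff(edges) == 0  # reduceat yields arr[i], not 0, here
        B0seg[empty_seg] = 0.0
        B1seg[empty_seg] = 0.0
        B2seg = np.empty((K, p, p))
        for k in range(K):
            Wk = sqb[edges[k]:edges[k + 1]]
            B2seg[k] = Wk.T @ Wk if len(Wk) else np.zeros((p, p))
        B0 = np.cumsum(B0seg)
        B1 = np.cumsum(B1seg, axis=0)
        B2 = np.cumsum(B2seg, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for k in range(K):
        a, bnd = suf_start[k], grp_end[k]
        tied = slice(a, bnd)
        mask = d[tied] == 1
        idx = np.arange(a, bnd)[mask]
        dd = len(idx)
        S0, S1, S2 = S0s[k], S1s[k], S2s[k]
        if has_comp and B0[k] != 0:
            S0 = S0 + Gm[k] * B0[k]
            S1 = S1 + Gm[k] * B1[k]
            S2 = S2 + Gm[k] * B2[k]
        T0 = r[idx].sum()
        T1 = rX[idx].sum(axis=0)
        T2 = rX[idx].T @ X[idx]

        frac = np.arange(dd) / dd
        den = S0 - frac * T0
        if np.any(den <= 0):
            return -np.inf, grad, hess
        ll += eta[idx].sum() - np.log(den).sum()
        a0 = (1.0 / den).sum()
        a1 = (frac / den).sum()
        b0 = (1.0 / den ** 2).sum()
        b1 = (frac / den ** 2).sum()
        b2 = (frac ** 2 / den ** 2).sum()
        grad += X[idx].sum(axis=0) - (a0 * S1 - a1 * T1)
        outer = (b0 * np.outer(S1, S1)
                 - b1 * (np.outer(S1, T1) + np.outer(T1, S1))
                 + b2 * np.outer(T1, T1))
        hess -= (a0 * S2 - a1 * T2) - outer
    return ll, grad, hess


def _newton(prep, p, names, max_iter=100, tol=1e-8, bound=50.0):
    beta = np.zeros(p)
    ll, grad, hess = _pl_derivs(beta, prep)
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            break
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(info + 1e-8 * np.eye(p), grad)
        # step halving on non-improvement (tolerance relative to |ll|:
        # decreases at floating-point noise level are accepted)
        new = beta + step
        noise = 1e-9 * (1.0 + abs(ll))
        for _ in range(25):
            ll_new, g_new, h_new = _pl_derivs(new, prep)
            if ll_new >= ll - noise:
                break
            step *= 0.5
            new = beta + step
        beta, ll, grad, hess = new, ll_new, g_new, h_new
        if np.max(np.abs(beta)) > bound:
            raise ConvergenceError(
                "coefficient magnitude exceeded bound (monotone likelihood / "
                f"perfect separation?): {dict(zip(names, beta.round(2)))}")
    else:
        if np.linalg.norm(grad) >= tol:
            raise ConvergenceError("Newton-Raphson failed to converge")
    return beta, ll, grad, hess


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    """A fitted (cause-specific Cox or Fine-Gray) proportional-hazards model."""

    model_kind: str
    cause: str
    names: list
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    n_events: int
    baseline_times: np.ndarray      # distinct event times
    baseline_cumhaz: np.ndarray     # Breslow-type cumulative (sub)hazard
    spec: CovariateSpec = None

    def hazard_ratios(self):
        with np.errstate(over="ignore"):  # huge SEs in tiny strata -> inf CI
            hr = np.exp(self.coef)
            lo = np.exp(self.coef - 1.96 * self.se)
            hi = np.exp(self.coef + 1.96 * self.se)
        return pd.DataFrame({"coef": self.coef, "hr": hr,
                             "hr_lo": lo, "hr_hi": hi, "se": self.se},
                            index=self.names)

    def coef_dict(self):
        return dict(zip(self.names, self.coef))

    def linear_predictor(self, df):
        X, names = self.spec.build(df)
        if names != self.names:
            raise ValueError("design mismatch between fit and prediction data")
        return X @ self.coef

    def cumhaz_at(self, horizon):
        if len(self.baseline_times) == 0:
            return 0.0
        if horizon > self.baseline_times[-1]:
            logger.warning("horizon %.3g beyond last event time %.3g; using "
                           "last baseline value", horizon, self.baseline_times[-1])
        return float(_step_eval(self.baseline_times, self.baseline_cumhaz,
                                np.asarray([horizon]), start=0.0)[0])

    def to_json(self):
        return json.dumps({
            "model_kind": self.model_kind,
            "cause": self.cause,
            "names": list(self.names),
            "coef": list(self.coef),
            "se": list(self.se),
            "loglik": self.loglik,
            "n": self.n,
            "n_events": self.n_events,
            "baseline": [list(self.baseline_times), list(self.baseline_cumhaz)],
        }, indent=1)


def _check_design(X, names):
    if X.shape[1] == 0:
        raise ValueError("empty covariate specification")
    sd = X.std(axis=0)
    for nm, s in zip(names, sd):
        if s == 0:
            raise ValueError(f"zero-variance term {nm!r}")


def _fit(rows, spec, cause, model_kind, time_col="time_years", event_col="event"):
    X, names = spec.build(rows)
    _check_design(X, names)
    time = rows[time_col].to_numpy(dtype=float)
    ev = rows[event_col].to_numpy()
    d = (ev == cause).astype(int)
    if d.sum() == 0:
        raise ValueError(f"no events of cause {cause!r}")
    if model_kind == "fine_gray":
        comp = ((ev != cause) & (ev != "censored")).astype(int)
    else:
        comp = np.zeros(len(d), dtype=int)
    prep = _prepare(time, d, comp, X)
    beta, ll, grad, hess = _newton(prep, X.shape[1], names)
    info = -hess
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))

    # Breslow-type baseline cumulative (sub)hazard at the fitted beta,
    # anchored at the all-zero (reference) covariate profile
    t, dd, comp_s, Xs, w, ginv, event_times, suf_start, grp_end, Gm = prep
    r = np.exp(np.clip(Xs @ beta, -200, 200))
    S0s = np.concatenate([np.cumsum(r[::-1])[::-1], [0.0]])
    b = comp_s * r * ginv
    B0 = np.concatenate([[0.0], np.cumsum(b)])
    increments = []
    for k in range(len(event_times)):
        a, bnd = suf_start[k], grp_end[k]
        nd = int(dd[a:bnd].sum())
        S0 = S0s[a] + Gm[k] * B0[a]
        increments.append(nd / S0)
    cumhaz = np.cumsum(increments) if increments else np.array([])

    return SurvivalFit(model_kind, cause, names, beta, se, cov, ll,
                       len(rows), int(d.sum()), event_times,
                       np.asarray(cumhaz), spec)


def fit_cox_cause_specific(rows, spec: CovariateSpec, cause,
                           time_col="time_years", event_col="event"):
    """Cause-specific Cox model: events of other causes censored at their
    time; Efron tie correction; Newton convergence at gradient norm < 1e-8."""
    return _fit(rows, spec, cause, "cause_specific_cox", time_col, event_col)


def fit_fine_gray(rows, spec: CovariateSpec, cause,
                  time_col="time_years", event_col="event"):
    """Fine-Gray subdistribution-hazard model with Kaplan-Meier IPCW:
    competing-cause failures stay in later risk sets with weight
    G(t-)/G(T_i-)."""
    return _fit(rows, spec, cause, "fine_gray", time_col, event_col)


def predict_absolute_risk(fit: SurvivalFit, covariates: pd.DataFrame, horizon=5.0):
    """Absolute risk 1 - S0(horizon)^exp(LP) from a Fine-Gray fit, where
    S0 = exp(-baseline cumulative subdistribution hazard) is anchored at the
    reference (all transformed covariates zero) profile."""
    lp = fit.linear_predictor(covariates)
    H0 = fit.cumhaz_at(horizon)
    return 1.0 - np.exp(-H0) ** np.exp(lp)


# ---------------------------------------------------------------------------
# Nonparametric estimators
# ---------------------------------------------------------------------------

def aalen_johansen_cif(rows, cause, group_col=None, time_col="time_years",
                       event_col="event"):
    """Aalen-Johansen cumulative incidence of ``cause`` under competing
    risks, optionally stratified by ``group_col``.

    Returns ``{group: (times, cif)}`` step functions (``None`` key when
    unstratified); CIF(0) = 0 and each curve is nondecreasing.
    """
    def one(sub):
        t = sub[time_col].to_numpy(dtype=float)
        ev = sub[event_col].to_numpy()
        order = np.argsort(t, kind="stable")
        t, ev = t[order], ev[order]
        any_ev = ev != "censored"
        t_all = t[any_ev]
        t_cause = t[ev == cause]
        uniq = np.unique(t_all)
        n = len(t)
        at_risk = n - np.searchsorted(t, uniq, side="left")
        d_all = (np.searchsorted(t_all, uniq, side="right")
                 - np.searchsorted(t_all, uniq, side="left"))
        d_cause = (np.searchsorted(t_cause, uniq, side="right")
                   - np.searchsorted(t_cause, uniq, side="left"))
        # S(t-) just before each event time
        s_minus = np.concatenate([[1.0], np.cumprod(1.0 - d_all / at_risk)[:-1]])
        cif = np.cumsum(s_minus * d_cause / at_risk)
        return uniq, cif

    if group_col is None:
        return {None: one(rows)}
    result = {}
    for g, sub in rows.groupby(group_col):
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        result[g] = one(sub)
    return result


def loglog_survival(rows, group_col, time_col="time_years", event_col="event"):
    """Per-group -ln(-ln S(t)) curves from Kaplan-Meier survival (any event),
    for visual proportional-hazards assessment. Groups without events are
    omitted with a warning."""
    curves = {}
    for g, sub in rows.groupby(group_col):
        t = sub[time_col].to_numpy(dtype=float)
        e = (sub[event_col].to_numpy() != "censored").astype(int)
        if e.sum() == 0:
            logger.warning("group %r has no events; log(-log) curve omitted", g)
            continue
        times, surv = kaplan_meier(t, e)
        ok = (surv > 0) & (surv < 1)
        curves[g] = (times[ok], -np.log(-np.log(surv[ok])))
    if len(curves) < 2:
        logger.warning("fewer than 2 groups with events for log(-log) curves")
    return curves
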