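"""5-year absolute kidney-failure risk equations.

Houses the published 5-year four-variable KFRE exactly as printed and the
machinery to refit the same functional form (optionally with an AKI flag)
on a landmark cohort via a Fine-Gray subdistribution model, with the
baseline survival anchored at the reference profile (age 70, female,
eGFR 30, ACR 1 mg/g, no AKI) so refitted equations print in the same
algebraic shape: risk = 1 - S0^exp(LP).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import survival as sv

logger = logging.getLogger(__name__)

#: published 5-year KFRE baseline survival and coefficients
KFRE_S0 = 0.924
KFRE_COEFS = {
    "age": -0.2201,     # x (age/10 - 7.036)
    "sex": 0.2467,      # x (sex - 0.5642)
    "egfr": -0.5567,    # x (eGFR/5 - 7.222)
    "lnacr": 0.451,     # x (lnACR - 5.137)
}
KFRE_CENTERS = {"age": 7.036, "sex": 0.5642, "egfr": 7.222, "lnacr": 5.137}


def kfre_5yr(age, sex, egfr, acr):
    """Published 5-year KFRE risk, evaluated exactly as printed.

    Parameters are age in years, sex (1 male / 0 female), eGFR in
    mL/min/1.73 m² and ACR in mg/g (> 0). Accepts scalars or arrays.
    """
    acr_arr = np.asarray(acr, dtype=float)
    if np.any(~(acr_arr > 0)):
        raise ValueError("acr must be > 0 (resolve missing ACR upstream)")
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    egfr = np.asarray(egfr, dtype=float)
    lp = (KFRE_COEFS["age"] * (age / 10.0 - KFRE_CENTERS["age"])
          + KFRE_COEFS["sex"] * (sex - KFRE_CENTERS["sex"])
          + KFRE_COEFS["egfr"] * (egfr / 5.0 - KFRE_CENTERS["egfr"])
          + KFRE_COEFS["lnacr"] * (np.log(acr_arr) - KFRE_CENTERS["lnacr"]))
    risk = 1.0 - KFRE_S0 ** np.exp(lp)
    return float(risk) if risk.ndim == 0 else risk


@dataclass
class RiskModel:
    """A 5-year absolute-risk equation risk(x) = 1 - S0^exp(LP(x)).

    ``terms`` maps a printable term label to (coefficient, transform), where
    the transform is a tuple understood by :meth:`linear_predictor`:
    ("shift_scale", column, shift, scale).
    """

    name: str
    s0: float
    terms: list  # [(label, coef, ("shift_scale", column, shift, scale)), ...]
    fit: object = None  # underlying SurvivalFit for refitted models

    def __post_init__(self):
        if not 0 < self.s0 < 1:
            raise ValueError("baseline 5-year survival must be in (0, 1)")

    def linear_predictor(self, rows: pd.DataFrame):
        lp = np.zeros(len(rows))
        for label, coef, (kind, column, shift, scale) in self.terms:
            assert kind == "shift_scale"
            x = rows[column].to_numpy(dtype=float)
            if np.isnan(x).any():
                raise ValueError(f"missing values in {column!r} for model {self.name}")
            lp += coef * (x - shift) / scale
        return lp

    def predict_risk(self, rows: pd.DataFrame):
        return 1.0 - self.s0 ** np.exp(self.linear_predictor(rows))

    def equation(self):
        """Algebraic form of the model, one term per coefficient."""
        parts = []
        for label, coef, (_, column, shift, scale) in self.terms:
            if shift == 0 and scale == 1:
                expr = label
            elif scale == 1:
                expr = f"({label}−{shift:g})"
            else:
                expr = f"(({label}−{shift:g})/{scale:g})"
            parts.append(f"({coef:.6g} * {expr})")
        return f"1 − {self.s0:.4g}^exp({' + '.join(parts)})"

    def to_json(self):
        return json.dumps({"name": self.name, "s0": self.s0,
                           "terms": [[lab, coef, list(tr)]
                                     for lab, coef, tr in self.terms]}, indent=1)

    @classmethod
    def from_json(cls, text):
        d = json.loads(text)
        terms = [(lab, coef, tuple(tr)) for lab, coef, tr in d["terms"]]
        return cls(d["name"], d["s0"], terms)


def kfre_model():
    """The published KFRE expressed as a :class:`RiskModel` over landmark
    cohort columns (requires a ``lnacr`` column)."""
    return RiskModel("kfre_5yr", KFRE_S0, [
        ("age", KFRE_COEFS["age"], ("shift_scale", "age_landmark", 70.36, 10.0)),
        ("sex", KFRE_COEFS["sex"], ("shift_scale", "sex", KFRE_CENTERS["sex"], 1.0)),
        ("eGFR", KFRE_COEFS["egfr"], ("shift_scale", "egfr_landmark", 36.11, 5.0)),
        ("lnACR", KFRE_COEFS["lnacr"], ("shift_scale", "lnacr", KFRE_CENTERS["lnacr"], 1.0)),
    ])


def refit_spec(include_aki: bool):
    """Covariate transforms of the refitted models: (age-70)/10,
    (eGFR-30)/5, sex, lnACR, optionally the 2-year AKI flag."""
    terms = [
        sv.shift_scale("age_landmark", 70.0, 10.0, name="age_per10"),
        sv.shift_scale("egfr_landmark", 30.0, 5.0, name="egfr_per5"),
        sv.identity("sex"),
        sv.identity("lnacr"),
    ]
    if include_aki:
        terms.append(sv.identity("aki_2yr"))
    return sv.CovariateSpec(terms)


def refit_model(rows: pd.DataFrame, include_aki=False, horizon=5.0,
                acr_policy="complete_case"):
    """Refit the KFRE functional form on a landmark cohort by Fine-Gray
    regression (kidney failure, death competing), restricted to
    eGFR >= 30 mL/min/1.73 m² rows.

    Missing ACR handling follows ``acr_policy``: ``complete_case`` drops
    untested rows (count logged); ``impute_median`` substitutes the cohort
    median ACR.
    """
    sub = rows[rows["egfr_landmark"] >= 30].copy()
    n_missing = int(sub["lnacr"].isna().sum())
    if acr_policy == "complete_case":
        if n_missing:
            logger.info("refit: dropping %d rows with untested ACR", n_missing)
        sub = sub[sub["lnacr"].notna()]
    elif acr_policy == "impute_median":
        med = sub["lnacr"].median()
        sub["lnacr"] = sub["lnacr"].fillna(med)
    else:
        raise ValueError(f"unknown acr_policy {acr_policy!r}")
    if len(sub) == 0 or sub["lnacr"].isna().all():
        raise ValueError("no usable ACR values; see missing-ACR policy")

    spec = refit_spec(include_aki)
    fit = sv.fit_fine_gray(sub, spec, "kidney_failure")
    s0 = float(np.exp(-fit.cumhaz_at(horizon)))
    coefs = fit.coef_dict()
    terms = [
        ("age", coefs["age_per10"], ("shift_scale", "age_landmark", 70.0, 10.0)),
        ("eGFR", coefs["egfr_per5"], ("shift_scale", "egfr_landmark", 30.0, 5.0)),
        ("sex", coefs["sex"], ("shift_scale", "sex", 0.0, 1.0)),
        ("lnACR", coefs["lnacr"], ("shift_scale", "lnacr", 0.0, 1.0)),
    ]
    name = "refit_with_aki" if include_aki else "refit_without_aki"
    if include_aki:
        terms.append(("AKI2yr", coefs["aki_2yr"], ("shift_scale", "aki_2yr", 0.0, 1.0)))
    return RiskModel(name, s0, terms, fit=fit)


def evaluate_models(models, rows: pd.DataFrame):
    """Prediction table (patient_id, model, lp, risk); rows violating a
    model's domain (missing ACR) are excluded and counted in the log."""
    out = []
    for model in models:
        usable = rows
        if any(tr[1] == "lnacr" for _, _, tr in model.terms):
            bad = rows["lnacr"].isna()
            if bad.any():
                logger.info("evaluate_models: %s skipped %d rows without ACR",
                            model.name, int(bad.sum()))
            usable = rows[~bad]
        lp = model.linear_predictor(usable)
        out.append(pd.DataFrame({
            "patient_id": usable["patient_id"].to_numpy(),
            "model": model.name,
            "lp": lp,
            "risk": 1.0 - model.s0 ** np.exp(lp),
        }))
    if not out:
        return pd.DataFrame(columns=["patient_id", "model", "lp", "risk"])
    return pd.concat(out, ignore_index=True)
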