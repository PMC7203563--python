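"""Preset validation scenarios.

These encode the generating effect sizes used for parameter-recovery
validation: the AKI log hazard ratios are set to the adjusted estimates
being validated against, the remaining covariate effects are plausible
invented values, and baseline rates are tuned so that 5-year event
fractions land near the reference cohort's.
"""

from __future__ import annotations

import numpy as np

from .synth import CauseEffects, ScenarioConfig, TrueEffects


def _effects(kf_aki_hr, death_aki_hr, kf_base, death_base,
             kf_recurrent_hr=None, death_recurrent_hr=None):
    return TrueEffects(
        kidney_failure=CauseEffects(kf_base, {
            "aki": np.log(kf_aki_hr),
            "recurrent_aki": np.log(kf_recurrent_hr or kf_aki_hr),
            "age_per10": -0.10, "male": 0.22, "egfr_inv2": 1.0, "lnacr": 0.23}),
        death=CauseEffects(death_base, {
            "aki": np.log(death_aki_hr),
            "recurrent_aki": np.log(death_recurrent_hr or death_aki_hr),
            "age_per10": 0.55, "male": 0.25, "egfr_inv2": 0.25, "lnacr": 0.10}),
    )


def preserved_egfr_scenario(n_patients=20000, seed=1, **kw):
    """eGFR >= 30 stratum: AKI hazard ratios 1.35 (kidney failure) and
    1.89 (death)."""
    return ScenarioConfig(
        n_patients=n_patients, seed=seed,
        egfr_stage_mix=(0.0, 0.45, 0.30, 0.25),
        aki_rate_per_year=0.30, acr_missing_frac=0.25,
        true_effects=_effects(1.35, 1.89, 0.055, 0.050), **kw)


def low_egfr_scenario(n_patients=20000, seed=1, **kw):
    """eGFR < 30 stratum: AKI hazard ratios 1.05 (kidney failure) and
    1.43 (death)."""
    eff = TrueEffects(
        kidney_failure=CauseEffects(0.11, {
            "aki": np.log(1.05), "recurrent_aki": np.log(1.05),
            "age_per10": -0.10, "male": 0.22, "egfr_inv2": 0.35, "lnacr": 0.25}),
        death=CauseEffects(0.075, {
            "aki": np.log(1.43), "recurrent_aki": np.log(1.43),
            "age_per10": 0.55, "male": 0.25, "egfr_inv2": 0.10, "lnacr": 0.10}),
    )
    return ScenarioConfig(
        n_patients=n_patients, seed=seed,
        egfr_stage_mix=(1.0, 0.0, 0.0, 0.0),
        aki_rate_per_year=0.30, acr_missing_frac=0.25,
        true_effects=eff, **kw)


def recurrent_aki_scenario(n_patients=20000, seed=1, **kw):
    """eGFR >= 30 stratum with an elevated recurrent-AKI kidney-failure
    hazard ratio of 2.34 (recurrent versus no AKI) and a higher episode
    rate so recurrence is common enough to estimate."""
    return ScenarioConfig(
        n_patients=n_patients, seed=seed,
        egfr_stage_mix=(0.0, 0.45, 0.30, 0.25),
        aki_rate_per_year=0.40, acr_missing_frac=0.25,
        true_effects=_effects(1.35, 1.89, 0.045, 0.035,
                              kf_recurrent_hr=2.34, death_recurrent_hr=1.89),
        **kw)


def refit_scenario(n_patients=10000, seed=1, **kw):
    """Complete-ACR eGFR >= 30 scenario for refitting risk equations."""
    return ScenarioConfig(
        n_patients=n_patients, seed=seed,
        egfr_stage_mix=(0.0, 0.45, 0.30, 0.25),
        aki_rate_per_year=0.12, acr_missing_frac=0.0,
        true_effects=_effects(1.35, 1.89, 0.045, 0.035), **kw)
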