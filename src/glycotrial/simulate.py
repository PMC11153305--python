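"""Synthetic trial cohorts.

Generates cohorts shaped like a 12-month, two-arm primary-care trial in
type 2 diabetes: baseline demographics and laboratory values drawn from
configurable marginals, stratified permuted-block arm allocation,
longitudinal HbA1c and body-weight trajectories with a per-participant
random intercept and arm-specific shifts at 6 and 12 months, a caricature
general-practitioner prescribing policy that escalates or de-escalates
metformin in response to glycaemic control (so medication-change categories
emerge endogenously), OGTT curves whose insulin response scales with an
insulin-resistance parameter, and missing-at-random loss to follow-up.

The generator's defaults are the study conditions the package is documented
against; they are emulation targets for population moments, not a model of
care. Everything is deterministic given (config, seed).

`cohort_from_counts` is the complementary encoder: it constructs a minimal
cohort whose classification reproduces a prescribed table of per-arm
(medication action, HbA1c category) counts exactly, which is how published
contingency tables are turned back into testable inputs.
"""

from __future__ import annotations

from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .randomize import randomize, weight_stratum

MED_ACTIONS = ("stop", "lower", "stable", "raise", "add")

# canonical OGTT response shape: multiplicative excursion over fasting level,
# peaking at 30-60 min, typical of impaired glucose tolerance
_OGTT_TIMES = np.array([0.0, 30.0, 60.0, 90.0, 120.0])
_GLUCOSE_SHAPE = np.array([0.0, 0.5, 0.7, 0.4, 0.15])
_INSULIN_SHAPE = np.array([0.0, 1.5, 2.0, 1.6, 1.0])


class SimulationConfig(BaseModel):
    """Study conditions for the cohort generator."""

    model_config = ConfigDict(extra="forbid")

    n_participants: int = Field(default=100, ge=4)
    male_fraction: float = Field(default=0.5, ge=0, le=1)
    age_mean: float = 62.0
    age_sd: float = Field(default=8.0, gt=0)
    weight_mean: float = 100.0
    weight_sd: float = Field(default=15.0, gt=0)
    hba1c_mean: float = 52.2
    hba1c_sd: float = Field(default=9.3, gt=0)
    hba1c_floor: float = 20.0
    fasting_glucose_mean: float = 8.3
    fasting_glucose_sd: float = Field(default=1.9, gt=0)
    fasting_insulin_mean: float = 156.0
    fasting_insulin_sd: float = Field(default=87.7, gt=0)
    metformin_fraction: float = Field(default=0.94, ge=0, le=1)
    metformin_dose_probs: dict[int, float] = Field(
        default_factory=lambda: {500: 0.3, 1000: 0.4, 1500: 0.2, 2000: 0.1}
    )
    # arm-specific shifts relative to control at each follow-up month
    hba1c_effect: dict[int, float] = Field(default_factory=lambda: {6: -5.0, 12: -3.2})
    weight_effect: dict[int, float] = Field(default_factory=lambda: {6: -3.8, 12: -3.6})
    # follow-up = baseline + shift + intercept + noise, so these components
    # are the *change* variability on top of the baseline spread; sized so
    # follow-up SDs stay near the baseline SD (HbA1c tracks strongly within
    # person over 6-12 months, weight even more so)
    hba1c_intercept_sd: float = Field(default=4.0, ge=0)
    hba1c_resid_sd: float = Field(default=3.5, gt=0)
    weight_intercept_sd: float = Field(default=2.5, ge=0)
    weight_resid_sd: float = Field(default=1.5, gt=0)
    # fraction of HbA1c change tracking concurrent weight change (coupling)
    weight_hba1c_coupling: float = 0.5
    dropout_rate: dict[str, float] = Field(
        default_factory=lambda: {"FMD": 0.16, "control": 0.20}
    )
    compliance_prob: float = Field(default=0.6, ge=0, le=1)
    # GP prescribing-policy caricature
    escalation_threshold: float = 53.0
    deescalation_threshold: float = 48.0
    deescalation_weight_loss: float = 0.03
    policy_adherence: float = Field(default=0.8, ge=0, le=1)
    second_agent: str = "gliclazide"
    second_agent_dose: float = 80.0
    metformin_step: float = 500.0
    metformin_max: float = 3000.0
    ogtt: bool = False
    insulin_resistance_sd: float = Field(default=0.4, ge=0)
    # post-load insulin excursion scale, calibrated so the simulated
    # cohort-mean Matsuda index lands near 1.5 (insulin-resistant range)
    ogtt_insulin_scale: float = Field(default=2.5, gt=0)

    @model_validator(mode="after")
    def _check_probs(self):
        total = sum(self.metformin_dose_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("metformin_dose_probs must sum to 1")
        for arm, rate in self.dropout_rate.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"dropout rate for {arm} outside [0, 1]")
        return self


def generate_baseline(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one row per participant of baseline characteristics."""
    n = cfg.n_participants
    sex = np.where(rng.random(n) < cfg.male_fraction, "M", "F")
    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    weight = np.maximum(rng.normal(cfg.weight_mean, cfg.weight_sd, n), 45.0)
    hba1c = _truncated_normal(cfg.hba1c_mean, cfg.hba1c_sd, cfg.hba1c_floor, n, rng)
    # fasting analytes are right-skewed: lognormal with matched mean/SD
    glucose = _lognormal(cfg.fasting_glucose_mean, cfg.fasting_glucose_sd, n, rng)
    insulin = _lognormal(cfg.fasting_insulin_mean, cfg.fasting_insulin_sd, n, rng)
    on_met = rng.random(n) < cfg.metformin_fraction
    doses = np.array(sorted(cfg.metformin_dose_probs), dtype=float)
    probs = np.array([cfg.metformin_dose_probs[int(d)] for d in doses])
    met_dose = np.where(on_met, rng.choice(doses, size=n, p=probs), 0.0)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:04d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "weight_kg": weight,
            "weight_stratum": [weight_stratum(w) for w in weight],
            "hba1c_mmol_mol": hba1c,
            "fasting_glucose": glucose,
            "fasting_insulin": insulin,
            "metformin_dose": met_dose,
            "insulin_resistance": np.exp(rng.normal(0.0, cfg.insulin_resistance_sd, n)),
        }
    )


def _lognormal(mean, sd, n, rng):
    """Lognormal draw parameterised by its arithmetic mean and SD."""
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return np.exp(rng.normal(np.log(mean) - s2 / 2.0, np.sqrt(s2), n))


def _truncated_normal(mean, sd, floor, n, rng):
    out = rng.normal(mean, sd, n)
    while np.any(out <= floor):
        bad = out <= floor
        out[bad] = rng.normal(mean, sd, bad.sum())
    return out


def simulate_longitudinal_outcome(
    baseline: np.ndarray,
    is_fmd: np.ndarray,
    effects: Mapping[int, float],
    intercept_sd: float,
    resid_sd: float,
    rng: np.random.Generator,
    floor: float | None = None,
) -> dict[int, np.ndarray]:
    """Follow-up values: baseline + arm shift + random intercept + noise.

    The random intercept is shared across timepoints (within-participant
    correlation); the arm shift applies to intervention participants only,
    so the configured value is the true arm contrast at that timepoint.
    """
    n = len(baseline)
    intercept = rng.normal(0.0, intercept_sd, n) if intercept_sd > 0 else np.zeros(n)
    out = {}
    for t, shift in sorted(effects.items()):
        vals = baseline + intercept + np.where(is_fmd, shift, 0.0) + rng.normal(0.0, resid_sd, n)
        if floor is not None:
            vals = np.maximum(vals, floor)
        out[int(t)] = vals
    return out


def simulate_trajectories(
    participants: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator
) -> dict[int, pd.DataFrame]:
    """HbA1c and weight at 6 and 12 months, with coupled changes."""
    is_fmd = (participants["arm"] == "FMD").to_numpy()
    weights = simulate_longitudinal_outcome(
        participants["weight_kg"].to_numpy(), is_fmd, cfg.weight_effect,
        cfg.weight_intercept_sd, cfg.weight_resid_sd, rng, floor=40.0,
    )
    hba1c = simulate_longitudinal_outcome(
        participants["hba1c_mmol_mol"].to_numpy(), is_fmd, cfg.hba1c_effect,
        cfg.hba1c_intercept_sd, cfg.hba1c_resid_sd, rng, floor=cfg.hba1c_floor,
    )
    out = {}
    for t in sorted(cfg.hba1c_effect):
        # couple HbA1c change to the within-arm residual of concurrent weight
        # change (shared physiology); centring per arm keeps the configured
        # arm effect the true arm contrast
        dw = weights[t] - participants["weight_kg"].to_numpy()
        dw_resid = dw - np.where(is_fmd, dw[is_fmd].mean(), dw[~is_fmd].mean())
        coupled = np.maximum(
            hba1c[t] + cfg.weight_hba1c_coupling * dw_resid, cfg.hba1c_floor
        )
        out[t] = pd.DataFrame(
            {
                "participant_id": participants["participant_id"],
                "hba1c_mmol_mol": coupled,
                "weight_kg": weights[t],
            }
        )
    return out


def simulate_gp_policy(
    regimen_doses: Mapping[str, float],
    hba1c: float,
    weight_change_fraction: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """One guideline-caricature prescribing decision.

    Escalates (one metformin step, then a second agent) when HbA1c exceeds
    the escalation threshold; de-escalates (drop the second agent, then step
    metformin down to discontinuation) when HbA1c is below the
    de-escalation threshold with sufficient weight loss; otherwise leaves
    the regimen unchanged. Applied stochastically with the configured
    adherence probability.
    """
    doses = {k: v for k, v in regimen_doses.items() if v > 0}
    if rng.random() > cfg.policy_adherence:
        return doses
    met = doses.get("metformin", 0.0)
    if hba1c > cfg.escalation_threshold:
        if met < cfg.metformin_max:
            doses["metformin"] = min(met + cfg.metformin_step, cfg.metformin_max)
        elif cfg.second_agent not in doses:
            doses[cfg.second_agent] = cfg.second_agent_dose
    elif (
        hba1c < cfg.deescalation_threshold
        and weight_change_fraction <= -cfg.deescalation_weight_loss
    ):
        second = [d for d in doses if d != "metformin"]
        if second:
            del doses[second[0]]
        elif met > 0:
            new = met - cfg.metformin_step
            if new <= 0:
                doses.pop("metformin", None)
            else:
                doses["metformin"] = new
    return doses


def simulate_ogtt(
    fasting_glucose: float,
    fasting_insulin: float,
    insulin_resistance: float,
    rng: np.random.Generator,
    excursion_scale: float = 2.5,
) -> tuple[np.ndarray, np.ndarray]:
    """One 2-hour OGTT curve in SI units (glucose mmol/l, insulin pmol/l).

    Post-load excursions follow a smooth 30-60 min peak; the insulin
    excursion scales with the participant's insulin-resistance parameter,
    so more resistant participants mount larger insulin responses (and get
    lower sensitivity indices). The infinite-sensitivity limit
    (``insulin_resistance`` -> 0) is a flat insulin curve.
    """
    noise_g = rng.normal(1.0, 0.03, len(_OGTT_TIMES))
    noise_i = rng.normal(1.0, 0.05, len(_OGTT_TIMES))
    noise_g[0] = noise_i[0] = 1.0
    glucose = fasting_glucose * (1.0 + _GLUCOSE_SHAPE) * noise_g
    insulin = (
        fasting_insulin
        * (1.0 + excursion_scale * insulin_resistance * _INSULIN_SHAPE)
        * noise_i
    )
    return np.maximum(glucose, 0.5), np.maximum(insulin, 0.0)


def apply_dropout(
    cohort: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Missing-at-random loss to follow-up, censoring from a random visit on."""
    keep_rows = np.ones(len(cohort), dtype=bool)
    base = cohort[cohort["timepoint_months"] == 0]
    for _, row in base.iterrows():
        rate = cfg.dropout_rate.get(row["arm"], 0.0)
        if rng.random() < rate:
            censor_from = int(rng.choice([6, 12]))
            mask = (cohort["participant_id"] == row["participant_id"]) & (
                cohort["timepoint_months"] >= censor_from
            )
            keep_rows &= ~mask.to_numpy()
    return cohort[keep_rows].reset_index(drop=True)


def simulate_cohort(cfg: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Full generator: baseline -> allocation -> trajectories -> prescribing -> dropout.

    Returns the canonical long-format cohort (one row per participant-visit)
    with wide drug columns and, when ``cfg.ogtt``, OGTT columns.
    """
    root = np.random.default_rng(seed)
    streams = root.spawn(6)
    participants = generate_baseline(cfg, streams[0])
    plan = randomize(participants, rng=streams[1])
    participants = participants.merge(
        plan.assignments[["participant_id", "arm"]], on="participant_id"
    )
    participants["compliant"] = np.where(
        participants["arm"] == "FMD", streams[2].random(len(participants)) < cfg.compliance_prob, True
    )
    trajectories = simulate_trajectories(participants, cfg, streams[3])

    policy_rng, ogtt_rng = streams[4], streams[5]
    rows = []
    for i, p in participants.iterrows():
        doses = {"metformin": p["metformin_dose"]} if p["metformin_dose"] > 0 else {}
        rows.append(_visit_row(p, 0, p["hba1c_mmol_mol"], p["weight_kg"], doses))
        if cfg.ogtt:
            g, ins = simulate_ogtt(
                p["fasting_glucose"],
                p["fasting_insulin"],
                p["insulin_resistance"],
                ogtt_rng,
                excursion_scale=cfg.ogtt_insulin_scale,
            )
            for k, t in enumerate(_OGTT_TIMES.astype(int)):
                rows[-1][f"glucose_{t}"] = g[k]
                rows[-1][f"insulin_{t}"] = ins[k]
        for t in sorted(trajectories):
            traj = trajectories[t]
            hba1c = float(traj.loc[traj["participant_id"] == p["participant_id"], "hba1c_mmol_mol"].iloc[0])
            weight = float(traj.loc[traj["participant_id"] == p["participant_id"], "weight_kg"].iloc[0])
            doses = simulate_gp_policy(
                doses, hba1c, (weight - p["weight_kg"]) / p["weight_kg"], cfg, policy_rng
            )
            rows.append(_visit_row(p, t, hba1c, weight, doses))
    cohort = pd.DataFrame(rows)
    return apply_dropout(cohort, cfg, root)


def _visit_row(p: pd.Series, timepoint: int, hba1c: float, weight: float, doses: Mapping[str, float]) -> dict:
    row = {
        "participant_id": p["participant_id"],
        "arm": p["arm"],
        "sex": p["sex"],
        "weight_stratum": p["weight_stratum"],
        "compliant": bool(p["compliant"]),
        "timepoint_months": timepoint,
        "hba1c_mmol_mol": hba1c,
        "weight_kg": weight,
    }
    for j, (name, dose) in enumerate(sorted(doses.items()), start=1):
        row[f"drug_{j}_name"] = name
        row[f"drug_{j}_dose"] = dose
    return row


# ---------------------------------------------------------------------------
# count-encoder: published contingency tables back into cohort form

_MED_REGIMENS: dict[str, tuple[dict[str, float], dict[str, float]]] = {
    "stop": ({"metformin": 1000.0}, {}),
    "lower": ({"metformin": 1000.0}, {"metformin": 500.0}),
    "stable": ({"metformin": 1000.0}, {"metformin": 1000.0}),
    "raise": ({"metformin": 1000.0}, {"metformin": 1500.0}),
    "add": ({"metformin": 1000.0}, {"metformin": 1000.0, "gliclazide": 80.0}),
}
_HBA1C_PAIRS: dict[str, tuple[float, float]] = {
    "improved": (52.0, 45.0),
    "stable": (52.0, 52.0),
    "deteriorated": (52.0, 58.0),
}

CellSpec = tuple[str, str, int]  # (medication action, hba1c category, count)


def cohort_from_counts(
    cells_by_arm: Mapping[str, Sequence[CellSpec]],
    timepoint: int = 12,
    compliant: bool | Literal["all"] = "all",
) -> pd.DataFrame:
    """Encode per-arm (medication action, HbA1c category) counts as a cohort.

    Each cell expands to ``count`` participants whose baseline and
    ``timepoint`` visits realise exactly that medication action
    (stop / lower / stable / raise / add, relative to metformin 1000 mg)
    and that HbA1c change category. Classifying the result returns the
    encoded counts identically, which is how published category tables are
    round-tripped through the pipeline.
    """
    rows = []
    counter = 0
    for arm, cells in cells_by_arm.items():
        for action, hba1c_cat, count in cells:
            if action not in _MED_REGIMENS:
                raise ValueError(f"unknown medication action {action!r}")
            if hba1c_cat not in _HBA1C_PAIRS:
                raise ValueError(f"unknown HbA1c category {hba1c_cat!r}")
            for _ in range(int(count)):
                counter += 1
                pid = f"E{counter:04d}"
                base_reg, final_reg = _MED_REGIMENS[action]
                hb_base, hb_final = _HBA1C_PAIRS[hba1c_cat]
                sex = "M" if counter % 2 else "F"
                p = pd.Series(
                    {
                        "participant_id": pid,
                        "arm": arm,
                        "sex": sex,
                        "weight_stratum": "low",
                        "compliant": True if compliant == "all" else bool(compliant),
                    }
                )
                rows.append(_visit_row(p, 0, hb_base, 95.0, base_reg))
                rows.append(_visit_row(p, timepoint, hb_final, 95.0, final_reg))
    return pd.DataFrame(rows)
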