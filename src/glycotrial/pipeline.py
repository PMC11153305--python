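"""Cohort I/O and the end-to-end analysis pipeline.

A cohort is a long-format CSV, one row per participant-visit, with columns
``participant_id, arm, sex, weight_stratum, compliant, timepoint_months,
hba1c_mmol_mol, weight_kg``, wide drug columns ``drug_<i>_name`` /
``drug_<i>_dose`` and optional OGTT columns ``glucose_<t>`` /
``insulin_<t>``. ``run_pipeline`` scores medication use per visit,
classifies changes at a follow-up timepoint, runs the association tests and
(optionally) the mixed-model treatment effects, and returns an auditable
report: every percentage is co-reported with its counts, expected cell
counts and the test actually used are recorded, and provenance (inputs
hash, seed, version) travels with the result.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_cohort
from .drugs import DrugTable, load_drug_table
from .mes import MedicationEffectScorer
from .stats import (
    ContingencyResult,
    TreatmentEffect,
    association_test,
    benjamini_hochberg,
    fit_treatment_effect,
    select_analysis_set,
)
from .units import hba1c_mmol_to_percent

REQUIRED_COLUMNS = (
    "participant_id",
    "arm",
    "sex",
    "weight_stratum",
    "timepoint_months",
    "hba1c_mmol_mol",
    "weight_kg",
)
VALID_TIMEPOINTS = {0, 6, 12}


class CohortSchemaError(ValueError):
    """The cohort file violates the long-format schema."""


@dataclass
class TrialReport:
    """Serialisable result of one pipeline run."""

    timepoint: int
    analysis_set: str
    count_tables: dict[str, pd.DataFrame]
    contingency: dict[str, ContingencyResult]
    percentages: dict[str, dict[str, dict[str, float]]]
    treatment_effects: dict[str, TreatmentEffect] = field(default_factory=dict)
    bh_adjusted: dict[str, float] = field(default_factory=dict)
    excluded: pd.DataFrame | None = None
    tie_breaks: int = 0
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "timepoint": self.timepoint,
            "analysis_set": self.analysis_set,
            "count_tables": {
                k: {str(arm): {c: int(v[c]) for c in v.index} for arm, v in t.iterrows()}
                for k, t in self.count_tables.items()
            },
            "percentages": self.percentages,
            "contingency": {
                k: {
                    "test_used": r.test_used,
                    "p_value": r.p_value,
                    "statistic": r.statistic,
                    "df": r.df,
                    "min_expected": r.min_expected,
                    "expected_counts": np.asarray(r.expected_counts).round(4).tolist(),
                }
                for k, r in self.contingency.items()
            },
            "treatment_effects": {k: asdict(v) for k, v in self.treatment_effects.items()},
            "bh_adjusted": self.bh_adjusted,
            "tie_breaks": self.tie_breaks,
            "n_excluded": 0 if self.excluded is None else int(len(self.excluded)),
            "provenance": self.provenance,
        }
        return out

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    return validate_cohort(df, source=str(path))


def validate_cohort(df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{source}: missing columns {missing}")
    bad_tp = sorted(set(df["timepoint_months"].unique()) - VALID_TIMEPOINTS)
    if bad_tp:
        rows = df.index[df["timepoint_months"].isin(bad_tp)][:5].tolist()
        raise CohortSchemaError(
            f"{source}: invalid timepoints {bad_tp} (rows {rows}); allowed {sorted(VALID_TIMEPOINTS)}"
        )
    dupes = df.duplicated(subset=["participant_id", "timepoint_months"], keep=False)
    if dupes.any():
        who = df.loc[dupes, ["participant_id", "timepoint_months"]].drop_duplicates()
        first = who.iloc[0]
        raise CohortSchemaError(
            f"{source}: duplicate participant-timepoint rows, e.g. participant "
            f"{first['participant_id']!r} at {first['timepoint_months']} months"
        )
    if "compliant" not in df.columns:
        df = df.copy()
        df["compliant"] = True
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV with a canonical column order."""
    lead = [c for c in REQUIRED_COLUMNS if c in df.columns] + (
        ["compliant"] if "compliant" in df.columns else []
    )
    rest = sorted(c for c in df.columns if c not in lead)
    df[lead + rest].to_csv(path, index=False)


def run_pipeline(
    cohort: pd.DataFrame,
    drug_table: DrugTable | None = None,
    timepoint: int = 12,
    analysis_set: str = "ITT",
    fit_effects: bool = False,
    effect_outcomes: tuple[str, ...] = ("hba1c_mmol_mol", "mes_total", "weight_kg"),
    seed: int | None = None,
) -> TrialReport:
    """Score, classify, test and report one cohort at one timepoint.

    With ``fit_effects`` the mixed-model adjusted treatment effects are
    estimated for ``effect_outcomes`` and the secondary (non-HbA1c,
    non-MES) p-values are Benjamini-Hochberg corrected.
    """
    cohort = validate_cohort(cohort)
    if drug_table is None:
        drug_table = load_drug_table()
    if (cohort.loc[cohort["timepoint_months"] == 0, "arm"] == "FMD").sum() == 0:
        raise ValueError("analysis requires a non-empty FMD arm at baseline")

    subset = select_analysis_set(cohort, analysis_set)
    scorer = MedicationEffectScorer(drug_table=drug_table).fit(subset)
    scored = scorer.transform(subset)
    scored["hba1c_percent"] = scored["hba1c_mmol_mol"].map(
        lambda v: hba1c_mmol_to_percent(v) if pd.notna(v) else np.nan
    )
    scored["hba1c_mes_corrected"] = scored["hba1c_percent"] + scored["mes_total"]

    results, tables, excluded = classify_cohort(scored, timepoint, drug_table=drug_table)
    contingency = {name: association_test(t.to_numpy()) for name, t in tables.items()}

    # binary endpoints: medication stopped / additional medication prescribed
    for name, flag in _binary_endpoints(scored, timepoint).items():
        tables[name] = flag
        contingency[name] = association_test(flag.to_numpy())

    percentages = {
        name: {
            str(arm): {
                cat: round(100.0 * t.loc[arm, cat] / t.loc[arm].sum())
                for cat in t.columns
            }
            for arm in t.index
        }
        for name, t in tables.items()
    }

    effects: dict[str, TreatmentEffect] = {}
    bh_adjusted: dict[str, float] = {}
    if fit_effects:
        for outcome in effect_outcomes:
            effects[outcome] = fit_treatment_effect(scored, outcome, timepoint=timepoint)
        secondary = [k for k in effects if k not in ("hba1c_mmol_mol", "mes_total")]
        if secondary:
            adj, _ = benjamini_hochberg([effects[k].p_value for k in secondary])
            bh_adjusted = dict(zip(secondary, adj.tolist()))

    report = TrialReport(
        timepoint=timepoint,
        analysis_set=analysis_set,
        count_tables=tables,
        contingency=contingency,
        percentages=percentages,
        treatment_effects=effects,
        bh_adjusted=bh_adjusted,
        excluded=excluded,
        tie_breaks=int(results["tie_break_applied"].sum()) if len(results) else 0,
        provenance={
            "software": f"glycotrial {__version__}",
            "seed": seed,
            "analysis_set": analysis_set,
            "timepoint": timepoint,
            "n_input_rows": int(len(cohort)),
            "input_hash": _hash_frame(cohort),
        },
    )
    return report


def _binary_endpoints(scored: pd.DataFrame, timepoint: int) -> dict[str, pd.DataFrame]:
    """2x2 stopped-medication and additional-medication tables (yes/no per arm)."""
    from .mes import regimen_from_row

    base = scored[scored["timepoint_months"] == 0].set_index("participant_id")
    final = scored[scored["timepoint_months"] == timepoint].set_index("participant_id")
    shared = [p for p in base.index if p in final.index and pd.notna(base.loc[p, "hba1c_mmol_mol"]) and pd.notna(final.loc[p, "hba1c_mmol_mol"])]
    rows = []
    for pid in shared:
        rb, rf = regimen_from_row(base.loc[pid]), regimen_from_row(final.loc[pid])
        rows.append(
            {
                "arm": base.loc[pid, "arm"],
                "stopped": len(rb) > 0 and len(rf) == 0,
                "additional": len(rf.drug_names - rb.drug_names) > 0,
            }
        )
    df = pd.DataFrame(rows)
    out = {}
    for name, col in (("medication_stopped", "stopped"), ("additional_medication", "additional")):
        arms = sorted(df["arm"].unique(), key=lambda a: (a != "FMD", a))
        t = pd.DataFrame(0, index=arms, columns=["yes", "no"])
        for arm in arms:
            sub = df[df["arm"] == arm]
            t.loc[arm, "yes"] = int(sub[col].sum())
            t.loc[arm, "no"] = int((~sub[col]).sum())
        t.index.name = "arm"
        out[name] = t
    return out


def _hash_frame(df: pd.DataFrame) -> str:
    payload = df.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
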