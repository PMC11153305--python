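"""Composite glycaemic-management classification.

Each participant's change from baseline to a follow-up visit is categorised
three ways:

* HbA1c change — improved / stable / deteriorated against a symmetric
  threshold (default 5 mmol/mol, i.e. 0.5 percentage points, boundaries
  inclusive);
* medication change — decreased / stable / increased, where any dose
  escalation or added drug counts as an increase and, absent any increase,
  any dose reduction or discontinuation counts as a decrease;
* glycaemic management — the composite of the two. A participant improves by
  needing less medication without losing glycaemic control, or by a genuine
  HbA1c improvement on unchanged medication; any medication escalation, or
  an HbA1c deterioration not bought back by medication, is a deterioration.

The one genuinely ambiguous cell — less medication but a deteriorated
HbA1c — is resolved as deteriorated and flagged (``tie_break_applied``), so
downstream reports can audit how often the rule fired.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator

from .drugs import DrugTable, Regimen
from .mes import regimen_from_row
from .units import hba1c_percent_to_mmol

HBA1C_CATEGORIES = ("improved", "stable", "deteriorated")
MED_CATEGORIES = ("decreased", "stable", "increased")
MANAGEMENT_CATEGORIES = ("improved", "stable", "deteriorated")

DEFAULT_THRESHOLD_MMOL_MOL = 5.0

# full (medication, hba1c) -> glycaemic management decision table
_DECISION_TABLE: dict[tuple[str, str], tuple[str, bool]] = {
    ("decreased", "improved"): ("improved", False),
    ("decreased", "stable"): ("improved", False),
    ("decreased", "deteriorated"): ("deteriorated", True),
    ("stable", "improved"): ("improved", False),
    ("stable", "stable"): ("stable", False),
    ("stable", "deteriorated"): ("deteriorated", False),
    ("increased", "improved"): ("deteriorated", False),
    ("increased", "stable"): ("deteriorated", False),
    ("increased", "deteriorated"): ("deteriorated", False),
}


@dataclass(frozen=True)
class CategoryResult:
    """Per-participant classification with audit flag."""

    participant_id: str
    hba1c_category: str
    medication_category: str
    glycaemic_management: str
    tie_break_applied: bool


def classify_hba1c_change(
    baseline: float, final: float, threshold: float = DEFAULT_THRESHOLD_MMOL_MOL
) -> str:
    """Categorise an HbA1c change on the mmol/mol scale.

    Improved when final is at least ``threshold`` below baseline,
    deteriorated when at least ``threshold`` above; boundaries inclusive.
    """
    if baseline <= 0 or final <= 0:
        raise ValueError("HbA1c values must be positive")
    if final <= baseline - threshold:
        return "improved"
    if final >= baseline + threshold:
        return "deteriorated"
    return "stable"


def classify_medication_change(baseline: Regimen, final: Regimen) -> str:
    """Categorise a regimen change; escalation dominates de-escalation.

    Increased if any drug's dose rose or a new drug appeared; otherwise
    decreased if any dose fell or a drug was stopped; otherwise stable.
    """
    drugs = baseline.drug_names | final.drug_names
    any_up = any(final.dose_of(d) > baseline.dose_of(d) for d in drugs)
    if any_up:
        return "increased"
    any_down = any(final.dose_of(d) < baseline.dose_of(d) for d in drugs)
    return "decreased" if any_down else "stable"


def classify_glycaemic_management(hba1c_cat: str, med_cat: str) -> tuple[str, bool]:
    """Composite category from the HbA1c and medication categories.

    Total over all 9 combinations; returns ``(category, tie_break_applied)``
    where the flag marks the (medication decreased, HbA1c deteriorated)
    cell, resolved as deteriorated.
    """
    if hba1c_cat not in HBA1C_CATEGORIES:
        raise ValueError(f"unknown HbA1c category: {hba1c_cat!r}")
    if med_cat not in MED_CATEGORIES:
        raise ValueError(f"unknown medication category: {med_cat!r}")
    return _DECISION_TABLE[(med_cat, hba1c_cat)]


class GlycaemicManagementClassifier(BaseEstimator):
    """Classifier mapping paired baseline/follow-up observations to categories.

    Parameters
    ----------
    threshold_mmol_mol : float, default 5.0
        HbA1c change threshold (IFCC scale). Percent-scale inputs are
        converted to mmol/mol before the threshold is applied, never the
        other way round.
    drug_table : DrugTable or None
        Used only to validate regimens when provided.

    ``predict`` takes a DataFrame with one row per participant carrying
    ``hba1c_baseline``/``hba1c_final`` (mmol/mol; or ``*_percent``) and
    regimen objects in ``regimen_baseline``/``regimen_final``, and returns a
    DataFrame of :class:`CategoryResult` fields.
    """

    def __init__(self, threshold_mmol_mol: float = DEFAULT_THRESHOLD_MMOL_MOL, drug_table=None):
        self.threshold_mmol_mol = threshold_mmol_mol
        self.drug_table = drug_table

    def fit(self, X=None, y=None) -> "GlycaemicManagementClassifier":
        if self.threshold_mmol_mol <= 0:
            raise ValueError("threshold_mmol_mol must be positive")
        self.threshold_ = float(self.threshold_mmol_mol)
        return self

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "threshold_"):
            self.fit()
        rows = []
        for _, r in X.iterrows():
            if "hba1c_baseline" in r.index and pd.notna(r.get("hba1c_baseline")):
                b, f = float(r["hba1c_baseline"]), float(r["hba1c_final"])
            else:
                b = hba1c_percent_to_mmol(float(r["hba1c_baseline_percent"]))
                f = hba1c_percent_to_mmol(float(r["hba1c_final_percent"]))
            hba = classify_hba1c_change(b, f, self.threshold_)
            med = classify_medication_change(r["regimen_baseline"], r["regimen_final"])
            gm, flag = classify_glycaemic_management(hba, med)
            rows.append(
                CategoryResult(
                    participant_id=str(r.get("participant_id", "")),
                    hba1c_category=hba,
                    medication_category=med,
                    glycaemic_management=gm,
                    tie_break_applied=flag,
                )
            )
        return pd.DataFrame([vars(c) for c in rows])


def classify_cohort(
    cohort: pd.DataFrame,
    timepoint: int,
    drug_table: DrugTable | None = None,
    threshold_mmol_mol: float = DEFAULT_THRESHOLD_MMOL_MOL,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Classify every participant of a long-format cohort at one timepoint.

    Participants lacking either the baseline or the follow-up HbA1c are
    excluded and logged (mirroring loss to follow-up). Returns
    ``(results, count_tables, excluded)`` where ``count_tables`` maps each
    outcome (``medication_change``, ``hba1c_change``,
    ``glycaemic_management``) to an arm x category count DataFrame.
    """
    if timepoint not in (6, 12):
        raise ValueError("timepoint must be 6 or 12 months")
    base = cohort[cohort["timepoint_months"] == 0].set_index("participant_id")
    final = cohort[cohort["timepoint_months"] == timepoint].set_index("participant_id")

    paired, excluded = [], []
    for pid in base.index:
        b = base.loc[pid]
        if pid not in final.index:
            excluded.append({"participant_id": pid, "reason": f"no visit at {timepoint} months"})
            continue
        f = final.loc[pid]
        if pd.isna(b.get("hba1c_mmol_mol")) or pd.isna(f.get("hba1c_mmol_mol")):
            excluded.append({"participant_id": pid, "reason": "missing HbA1c"})
            continue
        rb, rf = regimen_from_row(b), regimen_from_row(f)
        if drug_table is not None:
            drug_table.resolve(rb)
            drug_table.resolve(rf)
        paired.append(
            {
                "participant_id": pid,
                "arm": b["arm"],
                "hba1c_baseline": b["hba1c_mmol_mol"],
                "hba1c_final": f["hba1c_mmol_mol"],
                "regimen_baseline": rb,
                "regimen_final": rf,
            }
        )
    excluded_df = pd.DataFrame(excluded, columns=["participant_id", "reason"])
    if not paired:
        empty = pd.DataFrame(
            columns=["participant_id", "hba1c_category", "medication_category",
                     "glycaemic_management", "tie_break_applied", "arm"]
        )
        return empty, {}, excluded_df

    paired_df = pd.DataFrame(paired)
    clf = GlycaemicManagementClassifier(threshold_mmol_mol=threshold_mmol_mol).fit()
    results = clf.predict(paired_df)
    results["arm"] = paired_df["arm"].to_numpy()

    tables = {
        "medication_change": _count_table(results, "medication_category", MED_CATEGORIES),
        "hba1c_change": _count_table(results, "hba1c_category", HBA1C_CATEGORIES),
        "glycaemic_management": _count_table(
            results, "glycaemic_management", MANAGEMENT_CATEGORIES
        ),
    }
    return results, tables, excluded_df


def _count_table(results: pd.DataFrame, column: str, categories: tuple[str, ...]) -> pd.DataFrame:
    arms = sorted(results["arm"].unique(), key=lambda a: (a != "FMD", a))
    table = pd.DataFrame(0, index=arms, columns=list(categories))
    for arm in arms:
        counts = results.loc[results["arm"] == arm, column].value_counts()
        for cat in categories:
            table.loc[arm, cat] = int(counts.get(cat, 0))
    table.index.name = "arm"
    return table
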