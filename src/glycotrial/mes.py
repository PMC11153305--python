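"""Medication effect score (MES).

The MES of a drug prescription is (actual daily dose / maximum daily dose)
x drug-specific adjustment factor, where the factor is the expected maximal
HbA1c reduction in percentage points when the drug is used as monotherapy at
its maximum dose. Summing over a regimen gives the total MES: the maximal
HbA1c reduction that regimen could be expected to deliver. Adding the total
MES to the measured HbA1c (%) yields a glycaemic-control measure corrected
for how much pharmacological support it required.

Doses above the maximum are capped at a ratio of 1 and flagged: the score is
defined as a maximal expected reduction, which cannot exceed the monotherapy
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .drugs import DrugSpec, DrugTable, Prescription, Regimen, load_drug_table


@dataclass(frozen=True)
class MesResult:
    """Per-drug and total medication effect scores for one regimen."""

    per_drug: dict[str, float]
    total: float
    capped_flags: frozenset[str] = field(default_factory=frozenset)


def drug_mes(p: Prescription, spec: DrugSpec) -> tuple[float, bool]:
    """Score one prescription against its drug specification.

    Returns ``(score, capped)`` where ``score`` is in HbA1c percentage
    points, linear in dose up to the maximum and capped at the adjustment
    factor beyond it.
    """
    if p.drug_name != spec.name:
        raise ValueError(f"prescription {p.drug_name!r} scored against spec {spec.name!r}")
    ratio = p.daily_dose / spec.max_daily_dose
    capped = ratio > 1.0
    return min(ratio, 1.0) * spec.adjustment_factor, capped


def total_mes(regimen: Regimen, table: DrugTable) -> MesResult:
    """Total MES of a regimen: the sum of per-drug scores.

    The empty (diet-only) regimen scores 0. Any drug missing from the table
    aborts with an :class:`~glycotrial.drugs.UnknownDrugError` naming every
    unresolvable drug.
    """
    table.resolve(regimen)
    per_drug: dict[str, float] = {}
    capped: set[str] = set()
    for p in regimen:
        score, was_capped = drug_mes(p, table[p.drug_name])
        per_drug[p.drug_name] = score
        if was_capped:
            capped.add(p.drug_name)
    return MesResult(per_drug=per_drug, total=sum(per_drug.values()), capped_flags=frozenset(capped))


def mes_corrected_hba1c(hba1c_percent: float, mes_total: float) -> float:
    """HbA1c (%) plus total MES: glycaemic control corrected for drug use."""
    if hba1c_percent < 0 or mes_total < 0:
        raise ValueError("HbA1c and total MES must be non-negative")
    return hba1c_percent + mes_total


class MedicationEffectScorer(BaseEstimator, TransformerMixin):
    """Transformer computing total MES per row of a regimen table.

    Rows hold wide drug columns ``drug_<i>_name`` / ``drug_<i>_dose`` (the
    canonical cohort layout). ``transform`` appends ``mes_total`` and, when
    an ``hba1c_percent`` (or ``hba1c_mmol_mol``) column is present,
    ``hba1c_mes_corrected``.

    Parameters
    ----------
    drug_table : DrugTable, str or None
        Table to score against; a path loads JSON, ``None`` loads the
        packaged default.
    """

    def __init__(self, drug_table=None):
        self.drug_table = drug_table

    def fit(self, X: pd.DataFrame, y=None) -> "MedicationEffectScorer":
        if isinstance(self.drug_table, DrugTable):
            self.drug_table_ = self.drug_table
        else:
            self.drug_table_ = load_drug_table(self.drug_table)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "drug_table_"):
            self.fit(X)
        out = X.copy()
        totals = []
        for _, row in X.iterrows():
            regimen = regimen_from_row(row)
            totals.append(total_mes(regimen, self.drug_table_).total)
        out["mes_total"] = totals
        if "hba1c_percent" in out.columns:
            out["hba1c_mes_corrected"] = out["hba1c_percent"] + out["mes_total"]
        elif "hba1c_mmol_mol" in out.columns:
            from .units import hba1c_mmol_to_percent

            out["hba1c_mes_corrected"] = [
                hba1c_mmol_to_percent(v) + m if pd.notna(v) else float("nan")
                for v, m in zip(out["hba1c_mmol_mol"], out["mes_total"])
            ]
        return out


def regimen_from_row(row: pd.Series) -> Regimen:
    """Build a :class:`Regimen` from wide ``drug_<i>_name``/``drug_<i>_dose`` columns."""
    prescriptions = []
    i = 1
    while f"drug_{i}_name" in row.index:
        name = row[f"drug_{i}_name"]
        dose = row.get(f"drug_{i}_dose", 0.0)
        if isinstance(name, str) and name and pd.notna(dose) and dose > 0:
            prescriptions.append(Prescription(drug_name=name, daily_dose=float(dose)))
        i += 1
    return Regimen(prescriptions)
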