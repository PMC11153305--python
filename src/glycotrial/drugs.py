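"""Drug specifications, prescriptions and regimens.

The substrate of the medication effect score: a table of glucose-lowering
drugs (maximum daily dose and the expected maximal HbA1c reduction when used
as monotherapy at that dose) and a participant's prescription set at a visit.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from pydantic import BaseModel, ConfigDict, field_validator


class UnknownDrugError(KeyError):
    """Raised when a prescription references a drug absent from the table."""

    def __init__(self, names: Iterable[str]):
        self.names = sorted(set(names))
        super().__init__(f"unknown drug(s): {', '.join(self.names)}")


class DrugSpec(BaseModel):
    """One row of the drug table.

    ``adjustment_factor`` is the expected maximal HbA1c reduction, in
    percentage points, when the drug is used as monotherapy at
    ``max_daily_dose``.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    drug_class: str
    max_daily_dose: float
    dose_unit: str = "mg/day"
    adjustment_factor: float

    @field_validator("max_daily_dose", "adjustment_factor")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be positive")
        return v


class Prescription(BaseModel):
    """A drug at a daily dose. Zero dose is equivalent to absence."""

    model_config = ConfigDict(frozen=True)

    drug_name: str
    daily_dose: float

    @field_validator("daily_dose")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("daily_dose must be non-negative")
        return v


class Regimen:
    """An unordered set of prescriptions, at most one per drug.

    Zero-dose prescriptions are dropped on construction, so an all-zero
    regimen compares equal to the empty (diet-only) regimen.
    """

    def __init__(self, prescriptions: Iterable[Prescription | Mapping | tuple] = ()):
        by_name: dict[str, Prescription] = {}
        for p in prescriptions:
            if isinstance(p, tuple):
                p = Prescription(drug_name=p[0], daily_dose=p[1])
            elif isinstance(p, Mapping):
                p = Prescription(**p)
            if p.drug_name in by_name:
                raise ValueError(f"duplicate drug in regimen: {p.drug_name}")
            if p.daily_dose > 0:
                by_name[p.drug_name] = p
        self._by_name = by_name

    @classmethod
    def from_doses(cls, doses: Mapping[str, float]) -> "Regimen":
        return cls(Prescription(drug_name=k, daily_dose=v) for k, v in doses.items())

    def dose_of(self, drug_name: str) -> float:
        p = self._by_name.get(drug_name)
        return p.daily_dose if p is not None else 0.0

    @property
    def drug_names(self) -> frozenset[str]:
        return frozenset(self._by_name)

    def __iter__(self) -> Iterator[Prescription]:
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Regimen):
            return NotImplemented
        return {p.drug_name: p.daily_dose for p in self} == {
            p.drug_name: p.daily_dose for p in other
        }

    def __repr__(self) -> str:
        inner = ", ".join(f"{p.drug_name}={p.daily_dose:g}" for p in self)
        return f"Regimen({inner})"


class DrugTable:
    """Lookup table of :class:`DrugSpec`, unique by name."""

    def __init__(self, specs: Iterable[DrugSpec | Mapping]):
        self._specs: dict[str, DrugSpec] = {}
        for s in specs:
            if not isinstance(s, DrugSpec):
                s = DrugSpec(**s)
            if s.name in self._specs:
                raise ValueError(f"duplicate drug in table: {s.name}")
            self._specs[s.name] = s

    def __getitem__(self, name: str) -> DrugSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise UnknownDrugError([name]) from None

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self) -> Iterator[DrugSpec]:
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def resolve(self, regimen: Regimen) -> None:
        """Raise :class:`UnknownDrugError` listing every unresolvable drug."""
        unknown = [p.drug_name for p in regimen if p.drug_name not in self._specs]
        if unknown:
            raise UnknownDrugError(unknown)


def load_drug_table(path: str | Path | None = None) -> DrugTable:
    """Load a drug table from JSON.

    With no ``path``, loads the packaged default table (conventional
    literature values; override for formal analyses). The JSON is either a
    list of drug objects or an object with a ``drugs`` list.
    """
    if path is None:
        text = (
            resources.files("glycotrial").joinpath("data/drug_table.json").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    entries = raw["drugs"] if isinstance(raw, dict) else raw
    specs = []
    for i, entry in enumerate(entries):
        try:
            specs.append(DrugSpec(**entry))
        except Exception as exc:
            name = entry.get("name", f"entry #{i}") if isinstance(entry, dict) else f"entry #{i}"
            raise ValueError(f"invalid drug table entry {name!r}: {exc}") from exc
    return DrugTable(specs)
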