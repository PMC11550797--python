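"""Core data containers shared by the simulation and curation stages.

A cohort is a collection of emergency-department case records.  Each record
carries the patient's demographics, the visit index (patients may present
more than once), the list of drug names documented at admission, and --
once assigned -- a binary adverse-event outcome label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: canonical CYP450 enzymes used as drug-drug-interaction covariates
CYP_ENZYMES = ("cyp2c9", "cyp2c19", "cyp2d6", "cyp3a4")
#: canonical roles a drug may play for an enzyme
CYP_ROLES = ("substrate", "inhibitor")
#: the eight catalog flag columns, substrates first
CYP_FLAGS = tuple(f"{enzyme}_{role}" for role in CYP_ROLES for enzyme in CYP_ENZYMES)


@dataclass(frozen=True)
class CaseRecord:
    """One emergency-department presentation of one patient."""

    case_id: int
    patient_id: int
    visit_index: int
    age: float
    sex: str  # "female" | "male"
    drugs: tuple[str, ...]
    outcome: int | None = None

    def __post_init__(self) -> None:
        if self.visit_index < 1:
            raise ValueError(f"visit_index must be >= 1, got {self.visit_index}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")


@dataclass
class RawCohort:
    """An ordered collection of case records.

    ``case_id`` values are unique; an empty drug tuple means the medication
    record is missing for that case.
    """

    records: list[CaseRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.case_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("case_id values must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def with_records(self, records: Iterable[CaseRecord]) -> "RawCohort":
        return RawCohort(records=list(records))

    def with_outcomes(self, outcomes: Mapping[int, int]) -> "RawCohort":
        """Return a copy with outcome labels attached by case_id."""
        new = [
            replace(r, outcome=int(outcomes[r.case_id])) if r.case_id in outcomes else r
            for r in self.records
        ]
        return RawCohort(records=new)

    # ------------------------------------------------------------------ IO
    def case_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": [r.case_id for r in self.records],
                "patient_id": [r.patient_id for r in self.records],
                "visit_index": [r.visit_index for r in self.records],
                "age": [r.age for r in self.records],
                "sex": [r.sex for r in self.records],
                "outcome": [r.outcome for r in self.records],
            }
        )

    def exposure_frame(self) -> pd.DataFrame:
        """Long format: one row per (case, drug)."""
        rows = [(r.case_id, d) for r in self.records for d in r.drugs]
        return pd.DataFrame(rows, columns=["case_id", "drug_name"])

    def to_csv(self, out_dir: str | Path) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        case_path = out_dir / "cases.csv"
        exp_path = out_dir / "exposures.csv"
        self.case_frame().to_csv(case_path, index=False)
        self.exposure_frame().to_csv(exp_path, index=False)
        return case_path, exp_path

    @classmethod
    def from_frames(
        cls, cases: pd.DataFrame, exposures: pd.DataFrame
    ) -> "RawCohort":
        by_case: dict[int, list[str]] = {int(c): [] for c in cases["case_id"]}
        for cid, drug in zip(exposures["case_id"], exposures["drug_name"]):
            by_case[int(cid)].append(str(drug))
        records = []
        for row in cases.itertuples(index=False):
            outcome = None if pd.isna(row.outcome) else int(row.outcome)
            records.append(
                CaseRecord(
                    case_id=int(row.case_id),
                    patient_id=int(row.patient_id),
                    visit_index=int(row.visit_index),
                    age=float(row.age),
                    sex=str(row.sex),
                    drugs=tuple(by_case[int(row.case_id)]),
                    outcome=outcome,
                )
            )
        return cls(records=records)

    @classmethod
    def from_csv(cls, case_path: str | Path, exposure_path: str | Path) -> "RawCohort":
        return cls.from_frames(pd.read_csv(case_path), pd.read_csv(exposure_path))


@dataclass
class DrugCatalog:
    """The universe of drug names with combination structure and CYP membership.

    ``table`` has one row per drug with columns ``drug_name``,
    ``is_combination``, ``is_unspecific``, ``is_supplement`` and the eight
    boolean CYP flag columns in :data:`CYP_FLAGS` order.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"drug_name", "is_combination", "is_unspecific", "is_supplement", *CYP_FLAGS}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"catalog table missing columns: {sorted(missing)}")
        if self.table["drug_name"].duplicated().any():
            raise ValueError("catalog drug names must be unique")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        return list(self.table["drug_name"])

    def cyp_table(self) -> dict[str, dict[str, bool]]:
        """Map drug name -> the eight CYP membership flags."""
        out: dict[str, dict[str, bool]] = {}
        for row in self.table.itertuples(index=False):
            flags = {f: bool(getattr(row, f)) for f in CYP_FLAGS}
            out[row.drug_name] = flags
        return out

    def unspecific_names(self) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["is_unspecific"], "drug_name"])

    def supplement_names(self) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["is_supplement"], "drug_name"])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugCatalog":
        return cls(table=pd.read_csv(path))


def split_combination(name: str) -> list[str]:
    """Split an "a/b/c" combination-product name into its components."""
    return [part for part in (p.strip() for p in name.split("/")) if part]
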