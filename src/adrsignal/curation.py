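"""Curation of raw medication records into an analysis design matrix.

The pipeline follows the standard registry data-preparation flow: keep only
each patient's first presentation (later visits are confounded by the
treatment received at the first), drop cases with missing medication
records, normalize drug names (split combination products into components,
keep only the main substance for fixed-dose combinations with a
pharmacologically insignificant partner, drop unspecific labels and
supplements), restrict to the most frequent substances, and assemble binary
drug indicators together with demographic and CYP450 interaction covariates
into one case-by-predictor matrix.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CYP_ENZYMES, CYP_FLAGS, CYP_ROLES, CaseRecord, RawCohort, split_combination

__all__ = [
    "CurationConfig",
    "CurationReport",
    "DesignMatrix",
    "keep_first_visits",
    "drop_missing_medication",
    "normalize_drugs",
    "select_top_drugs",
    "count_excluded",
    "annotate_cyp",
    "assemble_design_matrix",
    "case_covariates",
    "curate",
    "COVARIATE_NAMES",
]

#: fixed-dose combinations whose second component only boosts the main
#: substance; the main substance is retained instead of splitting
DEFAULT_KEEP_MAIN = {
    "amoxicillin/clavulanic acid": "amoxicillin",
    "oxycodone/naloxone": "oxycodone",
    "tilidine/naloxone": "tilidine",
}

#: covariate column order of the design matrix: demographics, the per-case
#: count of drugs excluded from the indicator block, then the eight CYP
#: counts (substrates first)
COVARIATE_NAMES = ("age", "sex_female", "n_excluded") + tuple(
    f"n_{flag}" for flag in CYP_FLAGS
)


@dataclass(frozen=True)
class CurationConfig:
    """Tunable rules of the curation pipeline.

    ``min_count`` is the substance-frequency threshold (drop substances
    appearing fewer times across the curated cohort); ``"auto"`` picks the
    threshold by the coverage-minus-retained-fraction knee criterion.
    ``top_n`` caps the number of selected substances.  Sex is coded
    female=1.
    """

    min_count: int | str = 32
    top_n: int = 100
    keep_main_substance: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_KEEP_MAIN))
    unspecific_names: frozenset[str] = frozenset()
    supplement_names: frozenset[str] = frozenset()
    cyp_table: Mapping[str, Mapping[str, bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if isinstance(self.min_count, str):
            if self.min_count != "auto":
                raise ValueError("min_count must be a positive integer or 'auto'")
        elif self.min_count < 1:
            raise ValueError("min_count must be >= 1 when numeric")
        for combo, main in self.keep_main_substance.items():
            if "/" in main:
                raise ValueError(
                    f"keep_main target {main!r} must be a single substance")


@dataclass
class CurationReport:
    """Counts and selections recorded while curating one cohort."""

    n_raw: int
    n_removed_repeat: int
    n_removed_missing_med: int
    n_final: int
    n_substances_raw: int
    n_substances_after_threshold: int
    selected_drugs: list[str]
    threshold_used: int | None = None
    timestamps: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_final != self.n_raw - self.n_removed_repeat - self.n_removed_missing_med:
            raise ValueError("case counts do not conserve across curation stages")

    def stamp(self, stage: str) -> None:
        self.timestamps[stage] = _dt.datetime.now(_dt.timezone.utc).isoformat()

    def to_json(self, path: str | Path, include_timestamps: bool = False) -> Path:
        """Write the report as JSON.

        Timestamps are omitted by default so that report files are
        byte-reproducible across reruns of the same configuration.
        """
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = asdict(self)
        if not include_timestamps:
            payload.pop("timestamps")
        path.write_text(json.dumps(payload, indent=2))
        return path


@dataclass
class DesignMatrix:
    """The n-by-p analysis matrix with its outcome vector.

    ``frame`` is indexed by case_id (ascending) and holds, in order, one
    binary indicator column per selected drug, the eleven covariate columns
    of :data:`COVARIATE_NAMES`, and the binary ``outcome`` column.
    """

    frame: pd.DataFrame
    drug_names: list[str]

    def __post_init__(self) -> None:
        expected = list(self.drug_names) + list(COVARIATE_NAMES) + ["outcome"]
        if list(self.frame.columns) != expected:
            raise ValueError("design matrix columns do not match the documented layout")

    @property
    def case_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @property
    def column_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def predictor_names(self) -> list[str]:
        return list(self.frame.columns[:-1])

    @property
    def covariate_names(self) -> list[str]:
        return list(COVARIATE_NAMES)

    @property
    def X(self) -> np.ndarray:
        return self.frame.iloc[:, :-1].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["outcome"].to_numpy(dtype=int)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, index_label="case_id")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "DesignMatrix":
        frame = pd.read_csv(path, index_col="case_id")
        n_drugs = len(frame.columns) - len(COVARIATE_NAMES) - 1
        return cls(frame=frame, drug_names=list(frame.columns[:n_drugs]))


# --------------------------------------------------------------- stages

def keep_first_visits(raw: RawCohort) -> tuple[RawCohort, int]:
    """Retain only each patient's earliest presentation."""
    pairs = [(r.patient_id, r.visit_index) for r in raw]
    if len(pairs) != len(set(pairs)):
        raise ValueError("duplicate (patient_id, visit_index) pairs in cohort")
    first: dict[int, CaseRecord] = {}
    for rec in raw:
        cur = first.get(rec.patient_id)
        if cur is None or rec.visit_index < cur.visit_index:
            first[rec.patient_id] = rec
    kept_ids = {rec.case_id for rec in first.values()}
    kept = [rec for rec in raw if rec.case_id in kept_ids]
    return raw.with_records(kept), len(raw) - len(kept)


def drop_missing_medication(cohort: RawCohort) -> tuple[RawCohort, int]:
    """Drop cases whose medication record is missing (empty drug list)."""
    kept = [rec for rec in cohort if len(rec.drugs) > 0]
    return cohort.with_records(kept), len(cohort) - len(kept)


def normalize_drugs(drugs: Sequence[str], config: CurationConfig,
                    ) -> tuple[list[str], int]:
    """Normalize one case's drug list.

    Fixed-dose combinations listed in ``keep_main_substance`` collapse to
    their main substance; other "a/b" names split into components;
    unspecific labels and supplements are removed and counted; duplicates
    collapse (first occurrence kept).
    """
    out: list[str] = []
    n_dropped = 0
    seen: set[str] = set()
    for name in drugs:
        if not name:
            raise ValueError("drug names must be non-empty strings")
        if name in config.keep_main_substance:
            parts = [config.keep_main_substance[name]]
        elif "/" in name:
            parts = split_combination(name)
        else:
            parts = [name]
        for part in parts:
            if part in config.unspecific_names or part in config.supplement_names:
                n_dropped += 1
            elif part not in seen:
                seen.add(part)
                out.append(part)
    return out, n_dropped


def _normalized_cohort(cohort: RawCohort, config: CurationConfig,
                       ) -> tuple[RawCohort, dict[int, int]]:
    """Apply name normalization to every case; return per-case drop counts."""
    records = []
    dropped: dict[int, int] = {}
    for rec in cohort:
        norm, n_drop = normalize_drugs(rec.drugs, config)
        dropped[rec.case_id] = n_drop
        records.append(replace(rec, drugs=tuple(norm)))
    return cohort.with_records(records), dropped


def drug_frequencies(cohort: RawCohort) -> dict[str, int]:
    """Number of cases in which each substance appears."""
    freq: dict[str, int] = {}
    for rec in cohort:
        for d in set(rec.drugs):
            freq[d] = freq.get(d, 0) + 1
    return freq


def select_top_drugs(cohort: RawCohort, config: CurationConfig,
                     ) -> tuple[list[str], int, pd.DataFrame]:
    """Select the analysis substances from a name-normalized cohort.

    With a numeric ``min_count``, substances appearing fewer times are
    dropped, then the ``top_n`` most frequent are kept.  With
    ``min_count="auto"`` the threshold t maximizing
    coverage(t) - retained_fraction(t) is chosen, where coverage is the
    fraction of all drug exposures contributed by substances of frequency
    >= t and retained_fraction the fraction of substances kept -- a knee
    criterion trading coefficient count against exposure coverage.  Ties in
    frequency break alphabetically.  Returns the selection, the threshold
    used, and the coverage-curve diagnostics.
    """
    freq = drug_frequencies(cohort)
    if not freq:
        raise ValueError("no drugs present after normalization")
    items = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    counts = np.array([c for _, c in items], dtype=float)
    total = counts.sum()
    candidates = np.unique(counts)[::-1]
    coverage = np.array([counts[counts >= t].sum() / total for t in candidates])
    retained = np.array([(counts >= t).sum() / len(counts) for t in candidates])
    diag = pd.DataFrame({"threshold": candidates.astype(int),
                         "coverage": coverage, "retained_fraction": retained,
                         "objective": coverage - retained})
    if config.min_count == "auto":
        threshold = int(candidates[np.argmax(coverage - retained)])
    else:
        threshold = int(config.min_count)
    surviving = [(d, c) for d, c in items if c >= threshold]
    if not surviving:
        raise ValueError(f"no substance reaches the frequency threshold {threshold}")
    selected = [d for d, _ in surviving[: config.top_n]]
    return selected, threshold, diag


def count_excluded(drugs: Sequence[str], selected: Iterable[str]) -> int:
    """Number of a case's normalized drugs absent from the selected list."""
    sel = set(selected)
    return sum(1 for d in set(drugs) if d not in sel)


def annotate_cyp(drugs: Sequence[str],
                 cyp_table: Mapping[str, Mapping[str, bool]]) -> dict[str, int]:
    """Per-enzyme counts of the case's CYP substrates and inhibitors.

    Drugs absent from the table contribute 0 to every count; a drug flagged
    both substrate and inhibitor of an enzyme contributes 1 to each.
    """
    counts = {f"n_{flag}": 0 for flag in CYP_FLAGS}
    for d in set(drugs):
        flags = cyp_table.get(d)
        if flags is None:
            continue
        for flag in CYP_FLAGS:
            if flags.get(flag, False):
                counts[f"n_{flag}"] += 1
    return counts


def case_covariates(cohort: RawCohort, selected: Sequence[str],
                    config: CurationConfig,
                    dropped_counts: Mapping[int, int] | None = None,
                    ) -> dict[int, dict[str, float]]:
    """The eleven analysis covariates for every case of a normalized cohort.

    ``n_excluded`` counts normalized drugs outside the selected list plus
    the case's unspecific/supplement drops from normalization (the latter
    default to 0 when ``dropped_counts`` is not given).
    """
    out: dict[int, dict[str, float]] = {}
    for rec in cohort:
        cov: dict[str, float] = {
            "age": float(rec.age),
            "sex_female": 1.0 if rec.sex == "female" else 0.0,
            "n_excluded": float(count_excluded(rec.drugs, selected)
                                + (dropped_counts or {}).get(rec.case_id, 0)),
        }
        cov.update({k: float(v) for k, v in
                    annotate_cyp(rec.drugs, config.cyp_table).items()})
        out[rec.case_id] = cov
    return out


def assemble_design_matrix(cohort: RawCohort, selected: Sequence[str],
                           config: CurationConfig,
                           dropped_counts: Mapping[int, int] | None = None,
                           stage_counts: Mapping[str, int] | None = None,
                           threshold_used: int | None = None,
                           n_substances_raw: int | None = None,
                           n_substances_after_threshold: int | None = None,
                           ) -> tuple[DesignMatrix, CurationReport]:
    """Assemble the analysis matrix from a curated, normalized cohort.

    Rows are ordered by ascending case_id.  Columns: one binary indicator
    per selected drug, the eleven covariates, and the outcome.  With the
    default 100 selected drugs this gives the documented n x 112 layout.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("selected drug list must be non-empty")
    missing = [r.case_id for r in cohort if r.outcome is None]
    if missing:
        raise ValueError(f"outcome missing for cases: {missing[:5]}")

    records = sorted(cohort, key=lambda r: r.case_id)
    covs = case_covariates(cohort, selected, config, dropped_counts)
    n = len(records)
    drug_block = np.zeros((n, len(selected)), dtype=int)
    col_of = {d: j for j, d in enumerate(selected)}
    for i, rec in enumerate(records):
        for d in set(rec.drugs):
            j = col_of.get(d)
            if j is not None:
                drug_block[i, j] = 1
    data = {d: drug_block[:, j] for d, j in col_of.items()}
    for name in COVARIATE_NAMES:
        data[name] = np.array([covs[r.case_id][name] for r in records])
    data["outcome"] = np.array([int(r.outcome) for r in records])
    frame = pd.DataFrame(data, index=pd.Index([r.case_id for r in records],
                                              name="case_id"))
    dm = DesignMatrix(frame=frame, drug_names=selected)

    sc = dict(stage_counts or {})
    n_removed_repeat = sc.get("n_removed_repeat", 0)
    n_removed_missing = sc.get("n_removed_missing_med", 0)
    report = CurationReport(
        n_raw=sc.get("n_raw", n + n_removed_repeat + n_removed_missing),
        n_removed_repeat=n_removed_repeat,
        n_removed_missing_med=n_removed_missing,
        n_final=n,
        n_substances_raw=(n_substances_raw if n_substances_raw is not None
                          else len(drug_frequencies(cohort))),
        n_substances_after_threshold=(
            n_substances_after_threshold
            if n_substances_after_threshold is not None else len(selected)),
        selected_drugs=selected,
        threshold_used=threshold_used,
    )
    report.stamp("assemble")
    return dm, report


def curate(raw: RawCohort, config: CurationConfig,
           ) -> tuple[DesignMatrix, CurationReport]:
    """Run the full curation pipeline on a raw cohort.

    Stage order: first-visit filter, missing-medication drop, name
    normalization, substance selection, covariate annotation, matrix
    assembly.
    """
    cohort, n_repeat = keep_first_visits(raw)
    cohort, n_missing = drop_missing_medication(cohort)
    normalized, dropped = _normalized_cohort(cohort, config)
    freq = drug_frequencies(normalized)
    n_substances_raw = len(freq)
    selected, threshold, _ = select_top_drugs(normalized, config)
    n_after = sum(1 for c in freq.values() if c >= threshold)
    return assemble_design_matrix(
        normalized, selected, config,
        dropped_counts=dropped,
        stage_counts={"n_raw": len(raw), "n_removed_repeat": n_repeat,
                      "n_removed_missing_med": n_missing},
        threshold_used=threshold,
        n_substances_raw=n_substances_raw,
        n_substances_after_threshold=n_after,
    )
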