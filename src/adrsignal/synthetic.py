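"""Seeded synthetic polypharmacy cohorts with known sparse ground truth.

Real multi-center adverse-drug-reaction registries are rarely public, so the
package ships a generator that emulates their structure: a long-tailed drug
popularity distribution (a few very common substances, hundreds of rare
ones), a median of about seven drugs per case, repeat emergency-department
visits by some patients, left-skewed old-age demographics, and rare binary
outcomes produced by a sparse logistic model in which only a handful of
drugs plus demographic covariates carry nonzero effects.

All randomness flows through an explicit :class:`numpy.random.Generator`;
identical (spec, seed) pairs produce byte-identical cohorts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cohort import CYP_FLAGS, CaseRecord, DrugCatalog, RawCohort

__all__ = [
    "CohortSpec",
    "TrueEffects",
    "build_drug_catalog",
    "sample_cohort",
    "assign_outcomes",
    "reference_fixture",
    "recovery_benchmark",
    "write_simulation",
]

# Syllable pool for pseudo-drug names; picked to look like INN stems.
_PRE = ("lor", "flu", "ami", "keto", "pro", "meta", "oxa", "riva", "dulo", "ser",
        "tra", "val", "esci", "pan", "cilo", "beni", "dexa", "levo", "nor", "zopi")
_MID = ("va", "pi", "do", "ra", "mi", "xo", "ne", "ta", "lu", "ze")
_SUF = ("pril", "statin", "olol", "sartan", "mab", "zepam", "idone", "micin",
        "azole", "prazole", "oxetine", "afil", "dipine", "tinib", "mide", "caine")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated cohort.

    Defaults are calibrated against the descriptive summaries typical of a
    large multi-center emergency-department ADR registry: 7967 raw cases of
    which 791 are repeat visits, 1627 distinct substances, median age 72
    (IQR 58-81), roughly half female, and a median of 7 (3-10) drugs per
    case.
    """

    n_cases: int = 7967
    n_repeat_visits: int = 791
    n_missing_medication: int = 1
    catalog_size: int = 1627
    zipf_exponent: float = 1.45
    drugs_per_case_mean: float = 7.8
    drugs_per_case_dispersion: float = 2.0
    age_location: float = 90.0
    age_scale: float = 27.0
    age_skew: float = -3.0
    female_fraction: float = 0.492
    combination_fraction: float = 0.05
    unspecific_fraction: float = 0.02
    supplement_fraction: float = 0.03
    cyp_flag_prob: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.catalog_size < 1:
            raise ValueError("catalog_size must be >= 1")
        if self.n_repeat_visits + self.n_missing_medication >= self.n_cases:
            raise ValueError(
                "n_repeat_visits + n_missing_medication must be < n_cases"
            )
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        if self.zipf_exponent <= 0 or self.drugs_per_case_mean <= 0 \
                or self.drugs_per_case_dispersion <= 0:
            raise ValueError("skew/count parameters must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TrueEffects:
    """Ground-truth log-odds effects of the generating logistic model."""

    intercept: float
    drug_effects: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.intercept, *self.drug_effects.values(), *self.covariate_effects.values()]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all effect values must be finite")

    def validate_against(self, catalog: DrugCatalog) -> None:
        unknown = set(self.drug_effects) - set(catalog.names)
        if unknown:
            raise ValueError(f"drug effects reference unknown drugs: {sorted(unknown)}")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TrueEffects":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _make_names(n: int, rng: np.random.Generator) -> list[str]:
    """Generate ``n`` distinct pseudo-drug names."""
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n:
        name = _PRE[rng.integers(len(_PRE))] + _MID[rng.integers(len(_MID))] \
            + _SUF[rng.integers(len(_SUF))]
        if name in seen:
            name = f"{name}{len(names)}"
        seen.add(name)
        names.append(name)
    return names


def build_drug_catalog(spec: CohortSpec, rng: np.random.Generator) -> DrugCatalog:
    """Build the drug universe: plain substances, combination products
    ("a/b" names), unspecific labels and supplements, each a configurable
    fraction of the catalog, plus independently assigned CYP flags."""
    n = spec.catalog_size
    if n < 1:
        raise ValueError("catalog_size must be >= 1")
    n_comb = int(round(spec.combination_fraction * n))
    n_unspec = int(round(spec.unspecific_fraction * n))
    n_supp = int(round(spec.supplement_fraction * n))
    n_plain = n - n_comb - n_unspec - n_supp
    if n_plain < 0:
        raise ValueError("combination/unspecific/supplement fractions exceed 1")

    plain = _make_names(n_plain + 2 * n_comb + n_unspec + n_supp, rng)
    names: list[str] = plain[:n_plain]
    comb_pool = plain[n_plain: n_plain + 2 * n_comb]
    names += [f"{comb_pool[2 * i]}/{comb_pool[2 * i + 1]}" for i in range(n_comb)]
    unspec = plain[n_plain + 2 * n_comb: n_plain + 2 * n_comb + n_unspec]
    supp = plain[n_plain + 2 * n_comb + n_unspec:]
    names += unspec + supp

    is_comb = np.zeros(n, bool)
    is_comb[n_plain: n_plain + n_comb] = True
    is_unspec = np.zeros(n, bool)
    is_unspec[n_plain + n_comb: n_plain + n_comb + n_unspec] = True
    is_supp = np.zeros(n, bool)
    is_supp[n_plain + n_comb + n_unspec:] = True

    table = pd.DataFrame({"drug_name": names, "is_combination": is_comb,
                          "is_unspecific": is_unspec, "is_supplement": is_supp})
    for flag in CYP_FLAGS:
        table[flag] = rng.random(n) < spec.cyp_flag_prob
    # permute rows so special drug types are spread across popularity ranks
    table = table.iloc[rng.permutation(n)].reset_index(drop=True)
    return DrugCatalog(table=table)


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1, dtype=float) ** exponent
    return w / w.sum()


def _sample_ages(n: int, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Skew-normal ages truncated to [18, 105] by resampling."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = stats.skewnorm.rvs(spec.age_skew, loc=spec.age_location,
                                  scale=spec.age_scale, size=2 * (n - filled),
                                  random_state=rng)
        keep = draw[(draw >= 18.0) & (draw <= 105.0)][: n - filled]
        out[filled: filled + keep.size] = keep
        filled += keep.size
    return np.round(out, 1)


def _sample_drug_count(spec: CohortSpec, rng: np.random.Generator) -> int:
    """Zero-truncated negative binomial, capped at the catalog size."""
    k = spec.drugs_per_case_dispersion
    p = k / (k + spec.drugs_per_case_mean)
    while True:
        c = int(rng.negative_binomial(k, p))
        if c >= 1:
            return min(c, spec.catalog_size)


def sample_cohort(spec: CohortSpec, catalog: DrugCatalog,
                  rng: np.random.Generator) -> RawCohort:
    """Sample a raw cohort of ``spec.n_cases`` case records.

    Exactly ``n_repeat_visits`` records are second presentations of patients
    who also have a first-visit record, and exactly ``n_missing_medication``
    first-visit records carry an empty drug list.  Drug identities are drawn
    without replacement within a case from Zipf popularity weights over the
    catalog order; catalog rank 1 is the most popular substance.
    """
    if spec.n_repeat_visits + spec.n_missing_medication >= spec.n_cases:
        raise ValueError("n_repeat_visits + n_missing_medication must be < n_cases")
    n_patients = spec.n_cases - spec.n_repeat_visits
    weights = _zipf_weights(len(catalog), spec.zipf_exponent)
    names = np.asarray(catalog.names, dtype=object)

    ages = _sample_ages(n_patients, spec, rng)
    female = rng.random(n_patients) < spec.female_fraction

    # repeat-visit and missing-medication patients are disjoint sets
    special = rng.choice(n_patients, size=spec.n_repeat_visits + spec.n_missing_medication,
                         replace=False)
    repeat_patients = set(special[: spec.n_repeat_visits].tolist())
    missing_patients = set(special[spec.n_repeat_visits:].tolist())

    def draw_drugs() -> tuple[str, ...]:
        count = _sample_drug_count(spec, rng)
        idx = rng.choice(len(catalog), size=count, replace=False, p=weights)
        return tuple(names[idx])

    records: list[CaseRecord] = []
    case_id = 0
    for pid in range(n_patients):
        case_id += 1
        drugs = () if pid in missing_patients else draw_drugs()
        records.append(CaseRecord(case_id=case_id, patient_id=pid + 1, visit_index=1,
                                  age=float(ages[pid]),
                                  sex="female" if female[pid] else "male",
                                  drugs=drugs))
    for pid in sorted(repeat_patients):
        case_id += 1
        records.append(CaseRecord(case_id=case_id, patient_id=pid + 1, visit_index=2,
                                  age=float(ages[pid]),
                                  sex="female" if female[pid] else "male",
                                  drugs=draw_drugs()))
    return RawCohort(records=records)


def linear_predictor(cohort: RawCohort, effects: TrueEffects,
                     covariates: Mapping[int, Mapping[str, float]] | None = None,
                     ) -> np.ndarray:
    """Per-case log-odds under the generating model, in record order.

    Drug effects apply when the named drug appears in the case's drug list.
    ``age`` and ``sex_female`` are resolved from the record itself; any other
    covariate effect requires an entry in ``covariates`` (typically produced
    by the curation module's annotators).
    """
    eta = np.full(len(cohort), effects.intercept)
    for i, rec in enumerate(cohort):
        taken = set(rec.drugs)
        for drug, beta in effects.drug_effects.items():
            if drug in taken:
                eta[i] += beta
        for name, beta in effects.covariate_effects.items():
            if name == "age":
                eta[i] += beta * rec.age
            elif name == "sex_female":
                eta[i] += beta * (1.0 if rec.sex == "female" else 0.0)
            else:
                if covariates is None or rec.case_id not in covariates \
                        or name not in covariates[rec.case_id]:
                    raise KeyError(
                        f"effect references covariate {name!r} not provided for "
                        f"case {rec.case_id}"
                    )
                eta[i] += beta * covariates[rec.case_id][name]
    return eta


def assign_outcomes(cohort: RawCohort, effects: TrueEffects,
                    rng: np.random.Generator,
                    covariates: Mapping[int, Mapping[str, float]] | None = None,
                    ) -> RawCohort:
    """Draw each case's outcome independently as Bernoulli(logistic(eta))."""
    prob = expit(linear_predictor(cohort, effects, covariates))
    draws = rng.random(len(cohort)) < prob
    outcomes = {rec.case_id: int(d) for rec, d in zip(cohort, draws)}
    return cohort.with_outcomes(outcomes)


def _analysis_survivors(cohort: RawCohort) -> list[int]:
    """Case ids that survive curation's visit and missing-medication filters."""
    first: dict[int, CaseRecord] = {}
    for rec in cohort:
        cur = first.get(rec.patient_id)
        if cur is None or rec.visit_index < cur.visit_index:
            first[rec.patient_id] = rec
    return [rec.case_id for rec in first.values() if len(rec.drugs) > 0]


#: outcome variants of the reference fixture: positives among the 7175
#: analysis survivors (455 falls vs 6720 controls; 1977 bleeds vs 5198)
FIXTURE_POSITIVES = {"falls": 455, "bleeding": 1977}
_FIXTURE_SURVIVORS = 7175


def reference_fixture(seed: int = 0, outcome: str = "falls",
                      ) -> tuple[RawCohort, TrueEffects, DrugCatalog]:
    """A preset cohort reproducing the registry's data-flow arithmetic.

    The raw cohort holds 7967 cases with 791 repeat visits and one case
    with a missing medication record, over a 1627-substance catalog, so the
    curation pipeline leaves exactly 7175 analysis cases.  Outcome labels
    are assigned so that exactly 455 survivors are fall-positive (or 1977
    bleeding-positive): survivors are tilted toward positivity by their
    ground-truth logistic probability via weighted sampling without
    replacement, which fixes the case split exactly while preserving the
    planted drug-outcome associations.
    """
    if outcome not in FIXTURE_POSITIVES:
        raise ValueError(f"outcome must be one of {sorted(FIXTURE_POSITIVES)}")
    n_pos = FIXTURE_POSITIVES[outcome]
    spec = CohortSpec(seed=seed)
    rng = spec.rng()
    catalog = build_drug_catalog(spec, rng)
    cohort = sample_cohort(spec, catalog, rng)

    # plant a handful of moderately popular causal drugs (plain products only)
    planted_positions = (3, 8, 15, 26, 40)  # positions within the plain-drug ranking
    planted_betas = (1.5, 1.2, 1.4, 1.1, 1.0)
    special = (catalog.table["is_combination"] | catalog.table["is_unspecific"]
               | catalog.table["is_supplement"]).to_numpy()
    plain_by_rank = [name for name, s in zip(catalog.names, special) if not s]
    names = catalog.names
    q = n_pos / _FIXTURE_SURVIVORS
    effects = TrueEffects(
        intercept=math.log(q / (1.0 - q)) - 1.2,  # offset absorbs age/sex load
        drug_effects={plain_by_rank[i]: b
                      for i, b in zip(planted_positions, planted_betas)},
        covariate_effects={"age": 0.012, "sex_female": 0.25},
    )
    effects.validate_against(catalog)

    prob = expit(linear_predictor(cohort, effects))
    survivors = _analysis_survivors(cohort)
    surv_set = set(survivors)
    by_id = {rec.case_id: i for i, rec in enumerate(cohort)}

    w = np.array([prob[by_id[cid]] for cid in survivors])
    pos_ids = set(rng.choice(survivors, size=n_pos, replace=False,
                             p=w / w.sum()).tolist())
    outcomes: dict[int, int] = {}
    for rec in cohort:
        if rec.case_id in surv_set:
            outcomes[rec.case_id] = 1 if rec.case_id in pos_ids else 0
        else:
            outcomes[rec.case_id] = int(rng.random() < prob[by_id[rec.case_id]])
    return cohort.with_outcomes(outcomes), effects, catalog


def recovery_benchmark(seed: int, n_cases: int = 4092,
                       catalog_size: int = 400,
                       effect_size: float = 1.5,
                       intercept: float = -3.3,
                       ) -> tuple["DesignMatrix", list[str]]:  # noqa: F821
    """The sparse parameter-recovery benchmark: ~4000 curated cases, 100
    drug indicators, five planted effects, every other predictor null.

    Five plain drugs of moderate popularity (plain-product popularity
    positions 11, 19, 29, 41 and 56; per-drug exposure between roughly 1.5%
    and 15% of cases) carry a log-odds effect of ``effect_size``; the
    intercept gives an outcome prevalence near 8%, comparable to a rare ADR
    such as falls.  Returns the curated design matrix and the planted drug
    names.
    """
    from .curation import curate  # deferred: curation imports this module's types
    from .pipeline import curation_config_from

    spec = CohortSpec(n_cases=n_cases, n_repeat_visits=int(0.022 * n_cases),
                      n_missing_medication=2, catalog_size=catalog_size,
                      seed=seed)
    rng = spec.rng()
    catalog = build_drug_catalog(spec, rng)
    cohort = sample_cohort(spec, catalog, rng)
    special = (catalog.table["is_combination"] | catalog.table["is_unspecific"]
               | catalog.table["is_supplement"]).to_numpy()
    plain = [nm for nm, s in zip(catalog.names, special) if not s]
    planted = [plain[i] for i in (10, 18, 28, 40, 55)]
    effects = TrueEffects(intercept=intercept,
                          drug_effects={d: effect_size for d in planted})
    cohort = assign_outcomes(cohort, effects, rng)
    dm, _ = curate(cohort, curation_config_from(
        catalog, {"min_count": 20, "top_n": 100}))
    missing = [d for d in planted if d not in dm.drug_names]
    if missing:
        raise RuntimeError(f"planted drugs fell below the selection "
                           f"threshold: {missing}")
    return dm, planted


def write_simulation(cohort: RawCohort, catalog: DrugCatalog,
                     effects: TrueEffects, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort CSVs, catalog CSV and ground-truth JSON."""
    out_dir = Path(out_dir)
    case_path, exp_path = cohort.to_csv(out_dir)
    cat_path = catalog.to_csv(out_dir / "catalog.csv")
    truth_path = effects.to_json(out_dir / "true_effects.json")
    return {"cases": case_path, "exposures": exp_path,
            "catalog": cat_path, "true_effects": truth_path}
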