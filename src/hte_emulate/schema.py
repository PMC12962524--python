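"""Covariate schema for the emulated hypertension-program cohort.

The cohort mirrors an employer health-checkup population: annual checkup
measurements (blood pressure, lipids, liver enzymes, HbA1c), self-reported
lifestyle questionnaire items, claims-derived diagnosis flags, and a
comorbidity index.  Every downstream stage (generation, imputation, outcome
modelling, cluster profiling) is driven by this schema rather than by
hard-coded column lists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

KINDS = ("binary", "categorical", "continuous")

#: Name of the treatment indicator column in cohort tables.
TREATMENT_COL = "treatment"
#: Columns that are outcomes or bookkeeping, never covariates.
NON_COVARIATE_COLS = (
    TREATMENT_COL,
    "followup_days",
    "sbp_fu",
    "dbp_fu",
    "y_uncontrolled",
    "delta_sbp",
    "delta_dbp",
)


@dataclass(frozen=True)
class Covariate:
    """A single baseline covariate."""

    name: str
    kind: str  # binary | categorical | continuous
    levels: tuple[str, ...] = ()  # categorical only
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown covariate kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise ValueError(f"categorical covariate {self.name!r} needs >= 2 levels")
        if self.kind != "categorical" and self.levels:
            raise ValueError(f"{self.kind} covariate {self.name!r} must not define levels")


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered collection of covariates with unique names."""

    entries: tuple[Covariate, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [c.name for c in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")

    # -- lookups ------------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [c.name for c in self.entries]

    def __getitem__(self, name: str) -> Covariate:
        for c in self.entries:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def of_kind(self, kind: str) -> list[Covariate]:
        return [c for c in self.entries if c.kind == kind]

    def indicator_columns(self) -> list[tuple[str, str | None]]:
        """Expansion of the schema into indicator/continuous columns.

        Binary covariates map to themselves; each level of a categorical
        covariate maps to one indicator (name, level); continuous map to
        (name, None).  This is the feature space used for covariate z-score
        importance, where categorical levels are profiled separately.
        """
        cols: list[tuple[str, str | None]] = []
        for c in self.entries:
            if c.kind == "categorical":
                cols.extend((c.name, lev) for lev in c.levels)
            else:
                cols.append((c.name, None))
        return cols

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "entries": [
                    {
                        "name": c.name,
                        "kind": c.kind,
                        "levels": list(c.levels),
                        "units": c.units,
                    }
                    for c in self.entries
                ]
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CovariateSchema":
        raw = json.loads(text)
        return cls(
            tuple(
                Covariate(
                    name=e["name"],
                    kind=e["kind"],
                    levels=tuple(e.get("levels", ())),
                    units=e.get("units", ""),
                )
                for e in raw["entries"]
            )
        )


def default_schema() -> CovariateSchema:
    """Baseline covariate set of the emulated checkup cohort.

    Lifestyle questionnaire items are yes/no; drinking status uses the
    three analysis levels (everyday / sometimes / rare or never); eating
    speed has three levels.  Laboratory values, blood pressure, age, the
    Charlson comorbidity index and the days-since-last-checkup offset are
    continuous.
    """
    b = lambda name: Covariate(name, "binary")  # noqa: E731
    entries = (
        b("sex_male"),
        b("dx_hypertension"),
        b("dx_diabetes"),
        b("dx_dyslipidemia"),
        b("smoking"),
        Covariate("drinking", "categorical", ("everyday", "sometimes", "rare_never")),
        b("weight_change_since_20"),
        b("intention_improve_lifestyle"),
        b("exercise_sweating"),
        b("walking_activity"),
        Covariate("eating_speed", "categorical", ("fast", "normal", "slow")),
        b("late_dinner"),
        b("skip_breakfast"),
        b("sleep_rest"),
        Covariate("age", "continuous", units="years"),
        Covariate("bmi", "continuous", units="kg/m^2"),
        Covariate("triglycerides", "continuous", units="mg/dL"),
        Covariate("hdl", "continuous", units="mg/dL"),
        Covariate("ldl", "continuous", units="mg/dL"),
        Covariate("dbp", "continuous", units="mmHg"),
        Covariate("sbp", "continuous", units="mmHg"),
        Covariate("got", "continuous", units="U/L"),
        Covariate("gpt", "continuous", units="U/L"),
        Covariate("gamma_gtp", "continuous", units="U/L"),
        Covariate("hba1c", "continuous", units="%"),
        Covariate("cci", "continuous", units="points"),
        Covariate("days_since_checkup", "continuous", units="days"),
    )
    return CovariateSchema(entries)
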