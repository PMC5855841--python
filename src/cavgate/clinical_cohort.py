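"""Stroke-like-episode (SLE) cohort tables and comparisons for PMM2-CDG.

The packaged episode table holds the nine SLE of the cohort plus two
synthetic candidate rows representing the excluded events (a true ischemic
stroke on MRI, and an epileptic seizure at the onset of a CNS infection); the
two synthetic rows are flagged in the ``synthetic`` column.  The SLE
definition is applied as an explicit classification rule: an acute event with
sudden focal deficit, irritability or decreased consciousness, with no
alternative diagnosis, no ischemic stroke on MRI, and not a seizure at the
onset of a brain infection.

The group-comparison table ships only group means/SD (raw per-patient labs
are not public; the MVRD spread is a synthetic 0.10 placeholder), so
patient-level comparisons run on synthetic patient records drawn from those
summaries; categorical counts are reproduced exactly, numeric p-values are
meaningful only as sanity checks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AgeParseError, InvalidInputError
from .stats_compare import fisher_exact, mann_whitney_u

__all__ = [
    "Episode",
    "PatientRecord",
    "load_episodes",
    "load_group_summary",
    "parse_age",
    "classify_episode",
    "episode_summary",
    "make_synthetic_patients",
    "compare_cohort",
]

TRIGGERS = ("head_trauma", "infection", "unknown")
MRI_FINDINGS = ("none", "hemispheric_edema", "ischemic_stroke")

SLE = "SLE"
EXCLUDED_TRUE_STROKE = "excluded_true_stroke"
EXCLUDED_SEIZURE_CNS_INFECTION = "excluded_seizure_cns_infection"
NOT_SLE = "not_SLE"


@dataclass(frozen=True)
class Episode:
    """One candidate stroke-like episode (one table row)."""

    episode_id: str
    patient_id: str
    sex: str
    age_text: str
    trigger: str
    free_interval_h: float | None
    focal_deficit: bool
    irritability: bool
    decreased_consciousness: bool
    seizures: bool
    temperature_c: float | None
    eeg_abnormal: bool
    mri_finding: str
    cns_infection_at_onset: bool
    alternative_diagnosis: bool
    treatment: tuple[str, ...] = ()
    duration_h: float | None = None
    icars: float | None = None
    synthetic: bool = False

    def __post_init__(self) -> None:
        if self.trigger not in TRIGGERS:
            raise InvalidInputError(f"unknown trigger {self.trigger!r}")
        if self.mri_finding not in MRI_FINDINGS:
            raise InvalidInputError(f"unknown MRI finding {self.mri_finding!r}")
        if self.temperature_c is not None and not 30.0 <= self.temperature_c <= 43.0:
            raise InvalidInputError(
                f"temperature {self.temperature_c} outside plausible range"
            )
        if self.duration_h is not None and self.duration_h < 0:
            raise InvalidInputError("duration_h must be >= 0")


@dataclass(frozen=True)
class PatientRecord:
    """One cohort patient with group label and (possibly synthetic) labs."""

    patient_id: str
    group: str  # sle_positive | sle_negative | excluded_early_death
    age_years: float
    sex: str
    labs: dict[str, float] = field(default_factory=dict)
    mvrd: float | None = None
    vascular_personal: bool = False
    vascular_familial: bool = False
    febrile_seizures: bool = False
    epilepsy: bool = False

    def __post_init__(self) -> None:
        for key, value in self.labs.items():
            if value < 0:
                raise InvalidInputError(f"lab {key} negative: {value}")


_AGE_RE = re.compile(r"^\s*(\d+)\s*yr(?:\s+(\d+)\s*mo)?\s*$")


def parse_age(age_text: str) -> float:
    """Parse ``"<y> yr [<m> mo]"`` to decimal years."""
    m = _AGE_RE.match(age_text)
    if not m:
        raise AgeParseError(f"cannot parse age from {age_text!r}")
    years = int(m.group(1))
    months = int(m.group(2)) if m.group(2) else 0
    return years + months / 12.0


def classify_episode(e: Episode) -> str:
    """Apply the SLE definition and exclusion rules to one candidate episode.

    Exclusion reasons (ischemic stroke on MRI; seizure at the onset of a CNS
    infection) take precedence over a plain ``not_SLE``.
    """
    if e.mri_finding == "ischemic_stroke":
        return EXCLUDED_TRUE_STROKE
    if e.seizures and e.cns_infection_at_onset:
        return EXCLUDED_SEIZURE_CNS_INFECTION
    core = e.focal_deficit or e.irritability or e.decreased_consciousness
    if core and not e.alternative_diagnosis:
        return SLE
    return NOT_SLE


def _row_to_episode(row: pd.Series) -> Episode:
    def opt(v):
        return None if pd.isna(v) else float(v)

    treatment = (
        tuple(str(row["treatment"]).split(";")) if pd.notna(row["treatment"]) else ()
    )
    return Episode(
        episode_id=str(row["episode_id"]),
        patient_id=str(row["patient_id"]),
        sex=str(row["sex"]),
        age_text=str(row["age_text"]),
        trigger=str(row["trigger"]),
        free_interval_h=opt(row["free_interval_h"]),
        focal_deficit=bool(row["focal_deficit"]),
        irritability=bool(row["irritability"]),
        decreased_consciousness=bool(row["decreased_consciousness"]),
        seizures=bool(row["seizures"]),
        temperature_c=opt(row["temperature_c"]),
        eeg_abnormal=bool(row["eeg_abnormal"]),
        mri_finding=str(row["mri_finding"]),
        cns_infection_at_onset=bool(row["cns_infection_at_onset"]),
        alternative_diagnosis=bool(row["alternative_diagnosis"]),
        treatment=treatment,
        duration_h=opt(row["duration_h"]),
        icars=opt(row["icars"]),
        synthetic=bool(row["synthetic"]),
    )


def load_episodes(path: str | None = None, include_synthetic: bool = True) -> list[Episode]:
    """Load the packaged candidate-episode table (or a CSV with its layout)."""
    if path is None:
        with resources.files("cavgate.data").joinpath("episodes.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    episodes = [_row_to_episode(row) for _, row in df.iterrows()]
    if not include_synthetic:
        episodes = [e for e in episodes if not e.synthetic]
    return episodes


def load_group_summary(path: str | None = None) -> pd.DataFrame:
    """Printed SLE-positive vs SLE-negative group summary (means/SD, counts)."""
    if path is None:
        with resources.files("cavgate.data").joinpath("table2_summary.csv").open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def _numeric_summary(values: Sequence[float | None]) -> dict:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return {"n": 0, "mean": None, "sd": None, "range": (None, None)}
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "range": (float(arr.min()), float(arr.max())),
    }


def episode_summary(episodes: Sequence[Episode]) -> dict:
    """Mean/SD/range of the numeric episode variables plus key counts.

    Missing values are excluded per variable, with the per-variable n
    reported.  Ages are episode-level (an episode at 3 yr and one at 14 yr
    from the same patient both count).
    """
    if not episodes:
        raise InvalidInputError("need at least one episode")
    n = len(episodes)
    summary = {
        "n_episodes": n,
        "age_years": _numeric_summary([parse_age(e.age_text) for e in episodes]),
        "free_interval_h": _numeric_summary([e.free_interval_h for e in episodes]),
        "temperature_c": _numeric_summary([e.temperature_c for e in episodes]),
        "duration_h": _numeric_summary([e.duration_h for e in episodes]),
        "trigger_counts": {
            t: sum(1 for e in episodes if e.trigger == t) for t in TRIGGERS
        },
        "eeg_abnormal_count": sum(1 for e in episodes if e.eeg_abnormal),
        "hemispheric_edema_count": sum(
            1 for e in episodes if e.mri_finding == "hemispheric_edema"
        ),
    }
    return summary


def make_synthetic_patients(seed: int = 0, path: str | None = None) -> list[PatientRecord]:
    """Synthetic 43-patient roster matching the printed group structure.

    Group sizes (7 SLE-positive, 32 SLE-negative, 4 early-death exclusions),
    sex splits and categorical counts are reproduced exactly; numeric labs are
    drawn from normal distributions with the printed group means/SD (clipped
    at zero).  The per-patient values are synthetic: only the structure and
    the group-level first moments are faithful.
    """
    summary = load_group_summary(path)
    rng = np.random.default_rng(seed)
    numeric = summary[summary["kind"] == "numeric"].set_index("variable")
    categorical = summary[summary["kind"] == "categorical"].set_index("variable")

    patients: list[PatientRecord] = []
    for group, prefix, n_group, col in (
        ("sle_positive", "SLE", 7, "sle_pos"),
        ("sle_negative", "CTL", 32, "sle_neg"),
    ):
        n_male = int(categorical.loc["sex_male", f"{col}_count"])
        counts = {
            var: int(categorical.loc[var, f"{col}_count"])
            for var in ("vascular_personal", "vascular_familial",
                        "febrile_seizures", "epilepsy")
        }
        for i in range(n_group):
            labs = {}
            for var in numeric.index:
                if var in ("age_years", "mvrd"):
                    continue
                mu = float(numeric.loc[var, f"{col}_mean"])
                sd = float(numeric.loc[var, f"{col}_sd"])
                labs[var] = float(max(rng.normal(mu, sd), 0.0))
            age = float(
                max(rng.normal(float(numeric.loc["age_years", f"{col}_mean"]),
                               float(numeric.loc["age_years", f"{col}_sd"])), 0.5)
            )
            mvrd = float(rng.normal(float(numeric.loc["mvrd", f"{col}_mean"]),
                                    float(numeric.loc["mvrd", f"{col}_sd"])))
            patients.append(
                PatientRecord(
                    patient_id=f"{prefix}{i + 1:02d}",
                    group=group,
                    age_years=age,
                    sex="M" if i < n_male else "F",
                    labs=labs,
                    mvrd=mvrd,
                    vascular_personal=i < counts["vascular_personal"],
                    vascular_familial=i < counts["vascular_familial"],
                    febrile_seizures=i < counts["febrile_seizures"],
                    epilepsy=i < counts["epilepsy"],
                )
            )
    for i in range(4):  # early deaths, excluded from every comparison
        patients.append(
            PatientRecord(
                patient_id=f"ED{i + 1:02d}",
                group="excluded_early_death",
                age_years=1.0,
                sex="M" if i % 2 == 0 else "F",
            )
        )
    return patients


def compare_cohort(patients: Sequence[PatientRecord]) -> dict:
    """SLE-positive vs SLE-negative comparison on a patient roster.

    Early-death patients are excluded before any test.  Numeric variables are
    compared with the Mann-Whitney U test, categorical flags with Fisher's
    exact test.  Returns group sizes, SLE prevalence among evaluable
    patients, and one row per variable with per-group n and the p-value.
    """
    pos = [p for p in patients if p.group == "sle_positive"]
    neg = [p for p in patients if p.group == "sle_negative"]
    excluded = [p for p in patients if p.group == "excluded_early_death"]
    if not pos or not neg:
        raise InvalidInputError("both groups must be non-empty after exclusions")

    rows = []

    def numeric_row(name: str, getter) -> None:
        x = [getter(p) for p in pos if getter(p) is not None]
        y = [getter(p) for p in neg if getter(p) is not None]
        res = mann_whitney_u(x, y)
        rows.append(
            {"variable": name, "kind": "numeric", "n_pos": len(x), "n_neg": len(y),
             "mean_pos": float(np.mean(x)), "mean_neg": float(np.mean(y)),
             "p_value": res.p_value, "method": res.method}
        )

    def categorical_row(name: str, getter) -> None:
        a = sum(1 for p in pos if getter(p))
        c = sum(1 for p in neg if getter(p))
        res = fisher_exact([[a, len(pos) - a], [c, len(neg) - c]])
        rows.append(
            {"variable": name, "kind": "categorical", "n_pos": len(pos),
             "n_neg": len(neg), "count_pos": a, "count_neg": c,
             "p_value": res.p_value, "method": res.method}
        )

    numeric_row("age_years", lambda p: p.age_years)
    categorical_row("sex_male", lambda p: p.sex == "M")
    lab_names = sorted({k for p in pos + neg for k in p.labs})
    for lab in lab_names:
        numeric_row(lab, lambda p, lab=lab: p.labs.get(lab))
    numeric_row("mvrd", lambda p: p.mvrd)
    categorical_row("vascular_personal", lambda p: p.vascular_personal)
    categorical_row("vascular_familial", lambda p: p.vascular_familial)
    categorical_row("febrile_seizures", lambda p: p.febrile_seizures)
    categorical_row("epilepsy", lambda p: p.epilepsy)

    n_evaluable = len(pos) + len(neg)
    return {
        "n_sle_positive": len(pos),
        "n_sle_negative": len(neg),
        "n_excluded_early_death": len(excluded),
        "sle_prevalence_pct": 100.0 * len(pos) / n_evaluable,
        "rows": rows,
    }
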