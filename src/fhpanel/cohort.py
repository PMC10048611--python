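"""Cohort data model, CSV I/O, and nested case-control extreme-lipid selection.

The study design is a nested case-control sample drawn from a population
cohort: participants are ranked on their lipid panel and the phenotypic
extremes form the two arms.  Cases (``HLDL``) are hypercholesterolemic by
Simon Broome-derived cut-offs (LDL-C > 4.9 mmol/L *and* TC > 7.5 mmol/L);
controls (``LLDL``) sit in a normolipidemic window (TC < 5.2 mmol/L and
LDL-C in [2.6, 3.4] mmol/L).

A cohort is represented as a :class:`pandas.DataFrame` with one row per
participant.  Binary clinical covariates are *tristate* strings
(``"yes"`` / ``"no"`` / ``""`` for missing) so that complete-case analyses
reproduce per-variable denominators; genotype calls live in ``gt_``-prefixed
columns with levels ``"ref"`` / ``"het"`` / ``"hom"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Tristate binary clinical covariates (yes / no / missing).
BINARY_COVARIATES: tuple[str, ...] = (
    "tobacco_ever",
    "stroke_history",
    "angina_mi_history",
    "heart_failure_history",
    "obesity_on_medication",
    "htn_on_medication",
    "dm_on_medication",
    "famhx_htn",
    "famhx_dm",
    "famhx_stroke",
    "famhx_angina",
    "famhx_hyperlipidemia",
    "famhx_heart_disease",
    "famhx_cvd",
)

#: Continuous measurements carried per participant.
CONTINUOUS_COVARIATES: tuple[str, ...] = (
    "age_years",
    "fasting_glucose_mmol_l",
    "bmi_kg_m2",
)

LIPID_COLUMNS: tuple[str, ...] = (
    "tc_mmol_l",
    "ldl_mmol_l",
    "hdl_mmol_l",
    "tg_mmol_l",
)

#: Columns that must be present in a cohort CSV.
MANDATORY_COLUMNS: tuple[str, ...] = (
    ("id", "sex") + CONTINUOUS_COVARIATES + LIPID_COLUMNS + BINARY_COVARIATES
)

GROUPS = ("HLDL", "LLDL", "unassigned")

GT_PREFIX = "gt_"


@dataclass(frozen=True)
class SelectionCriteria:
    """Lipid cut-offs and arm size for the extreme-phenotype selection.

    Defaults are the study's operational criteria: hypercholesterolemia at
    LDL-C > 4.9 mmol/L and TC > 7.5 mmol/L; the low extreme at
    TC < 5.2 mmol/L with LDL-C between 2.6 and 3.4 mmol/L.
    """

    hldl_ldl_cutoff: float = 4.9
    hldl_tc_cutoff: float = 7.5
    lldl_tc_max: float = 5.2
    lldl_ldl_range: tuple[float, float] = (2.6, 3.4)
    k_per_arm: int = 25

    def __post_init__(self) -> None:
        if min(self.hldl_ldl_cutoff, self.hldl_tc_cutoff, self.lldl_tc_max) <= 0:
            raise ValueError("lipid cut-offs must be positive")
        lo, hi = self.lldl_ldl_range
        if not lo <= hi:
            raise ValueError(f"lldl_ldl_range must be ordered, got ({lo}, {hi})")
        if self.k_per_arm <= 0:
            raise ValueError("k_per_arm must be positive")


def classify_eligibility(
    tc: float, ldl: float, criteria: SelectionCriteria | None = None
) -> str:
    """Classify a lipid pair as ``"HLDL-eligible"``, ``"LLDL-eligible"`` or ``"neither"``.

    HLDL eligibility requires *both* cut-offs to be exceeded; LLDL eligibility
    requires low TC together with LDL-C inside the normolipidemic window.
    The three classes partition the (tc, ldl) plane.
    """
    criteria = criteria or SelectionCriteria()
    for name, value in (("tc", tc), ("ldl", ldl)):
        if not math.isfinite(value) or value < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {value!r}")
    if ldl > criteria.hldl_ldl_cutoff and tc > criteria.hldl_tc_cutoff:
        return "HLDL-eligible"
    lo, hi = criteria.lldl_ldl_range
    if tc < criteria.lldl_tc_max and lo <= ldl <= hi:
        return "LLDL-eligible"
    return "neither"


def select_extremes(
    participants: pd.DataFrame, criteria: SelectionCriteria | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select the ``k_per_arm`` highest-ranked cases and lowest-ranked controls.

    Ranking is by LDL-C (primary), TC (tie-break), then id (deterministic
    final tie-break).  Raises ``ValueError`` naming the shortfall if either
    arm has fewer than ``k_per_arm`` eligible participants.  The returned
    (case, control) frames are disjoint by construction because eligibility
    classes are disjoint.
    """
    criteria = criteria or SelectionCriteria()
    elig = participants.apply(
        lambda r: classify_eligibility(r["tc_mmol_l"], r["ldl_mmol_l"], criteria),
        axis=1,
    )
    k = criteria.k_per_arm
    hldl = participants[elig == "HLDL-eligible"]
    lldl = participants[elig == "LLDL-eligible"]
    for name, pool in (("HLDL", hldl), ("LLDL", lldl)):
        if len(pool) < k:
            raise ValueError(
                f"{name} arm: {len(pool)} eligible participants, need {k} "
                f"(shortfall {k - len(pool)})"
            )
    cases = hldl.sort_values(
        ["ldl_mmol_l", "tc_mmol_l", "id"], ascending=[False, False, True]
    ).head(k)
    controls = lldl.sort_values(
        ["ldl_mmol_l", "tc_mmol_l", "id"], ascending=[True, True, True]
    ).head(k)
    return cases, controls


def _coerce_tristate(series: pd.Series) -> pd.Series:
    out = series.fillna("").astype(str).str.strip().str.lower()
    bad = ~out.isin(["yes", "no", ""])
    if bad.any():
        raise ValueError(
            f"column {series.name!r}: unparseable tristate values "
            f"{sorted(out[bad].unique())}"
        )
    return out


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema.

    Empty cells in tristate covariate columns become ``""`` (missing); the
    ``group`` column is optional on input and filled with ``"unassigned"``
    when absent.  Unknown columns are preserved.
    """
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=True)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing mandatory columns: {missing}")
    if "group" not in df.columns:
        df["group"] = "unassigned"
    df["group"] = df["group"].fillna("unassigned")
    bad_groups = set(df["group"].unique()) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    for col in BINARY_COVARIATES:
        df[col] = _coerce_tristate(df[col])
    for col in df.columns:
        if col.startswith(GT_PREFIX):
            df[col] = df[col].fillna("").astype(str)
    for col in CONTINUOUS_COVARIATES + LIPID_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"column {col!r} is not numeric")
    return df


def write_cohort(participants: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (round-trips through :func:`read_cohort`)."""
    participants.to_csv(path, index=False)


def complete_cases(participants: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Rows with a non-missing value for ``variable`` (tristate or numeric)."""
    col = participants[variable]
    if variable in BINARY_COVARIATES or col.dtype == object:
        return participants[col.astype(str).str.len() > 0]
    return participants[col.notna()]
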