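"""Univariable case-control association: crude odds ratios and Wald tests.

For a 2x2 table (a = exposed cases, b = unexposed cases, c = exposed
controls, d = unexposed controls) the crude odds ratio is the
cross-product ratio OR = ad / bc, with Woolf standard error of the
log odds se = sqrt(1/a + 1/b + 1/c + 1/d), Wald chi-square
(ln OR / se)^2 on 1 df, and 95% CI exp(ln OR +/- 1.96 se).  The Wald
(not Pearson) chi-square is what the published univariable tables print:
recomputing the tobacco row (102, 228, 70, 260) gives Wald 7.98 where
Pearson would give 8.05.

Genotype odds ratios compare each non-reference genotype category against
the reference category as its own 2x2.  Multiple testing across a variant
panel uses the Bonferroni-corrected threshold alpha / m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import riskmodel
from .cohort import BINARY_COVARIATES, CONTINUOUS_COVARIATES, GT_PREFIX, complete_cases

Z95 = 1.96  # used exactly; matches the printed intervals at 2 dp


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure-by-outcome counts: a/b exposed/unexposed cases, c/d controls."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b <= 0 or self.c + self.d <= 0:
            raise ValueError("each group needs at least one observation")


@dataclass(frozen=True)
class AssociationResult:
    or_hat: float
    ln_or: float
    se_ln_or: float
    wald_chi2: float
    df: int
    p_value: float
    ci95: tuple[float, float]
    significant_after_bonferroni: bool | None = None

    def rounded(self) -> dict:
        """Report-style rounding: 2 dp for OR/CI/chi2, 3 dp for p."""
        return {
            "or": round(self.or_hat, 2),
            "ci_low": round(self.ci95[0], 2),
            "ci_high": round(self.ci95[1], 2),
            "wald_chi2": round(self.wald_chi2, 2),
            "p": round(self.p_value, 3),
        }


def crude_or(
    table: TwoByTwoTable, haldane_correction: bool = False
) -> AssociationResult:
    """Crude (cross-product) odds ratio with Wald test and 95% CI.

    Zero cells raise by default; ``haldane_correction=True`` adds the
    Haldane-Anscombe 0.5 to every cell instead.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        if not haldane_correction:
            raise ValueError(
                "zero cell in 2x2 table; pass haldane_correction=True to add 0.5"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_hat = (a * d) / (b * c)
    ln_or = math.log(or_hat)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    wald = (ln_or / se) ** 2
    p = float(stats.chi2.sf(wald, df=1))
    ci = (math.exp(ln_or - Z95 * se), math.exp(ln_or + Z95 * se))
    return AssociationResult(
        or_hat=or_hat, ln_or=ln_or, se_ln_or=se, wald_chi2=wald, df=1,
        p_value=p, ci95=ci,
    )


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-genotype case/control counts with a named reference category."""

    categories: tuple[str, ...]
    case_counts: tuple[int, ...]
    control_counts: tuple[int, ...]
    reference: str

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError("need at least two genotype categories")
        if len(self.case_counts) != len(self.categories) or len(
            self.control_counts
        ) != len(self.categories):
            raise ValueError("count vectors must match categories")
        if self.reference not in self.categories:
            raise ValueError(f"reference {self.reference!r} not among categories")
        i = self.categories.index(self.reference)
        if self.case_counts[i] <= 0 or self.control_counts[i] <= 0:
            raise ValueError("reference category must be observed in both groups")


def genotype_or(
    counts: GenotypeCounts, haldane_correction: bool = False
) -> dict[str, AssociationResult]:
    """Per-genotype odds ratios against the reference category.

    Each non-reference category forms its own 2x2 against the reference
    (the published genotype tables' "CT vs C" layout).
    """
    ref_i = counts.categories.index(counts.reference)
    ref_case, ref_control = counts.case_counts[ref_i], counts.control_counts[ref_i]
    out = {}
    for i, cat in enumerate(counts.categories):
        if i == ref_i:
            continue
        table = TwoByTwoTable(
            a=counts.case_counts[i], b=ref_case,
            c=counts.control_counts[i], d=ref_control,
        )
        out[cat] = crude_or(table, haldane_correction=haldane_correction)
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m."""
    if m <= 0:
        raise ValueError("number of tests must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def _binary_table(
    cohort: pd.DataFrame, variable: str, positive_level: str
) -> TwoByTwoTable:
    cc = complete_cases(cohort, variable)
    case = cc[cc["group"] == "HLDL"][variable]
    control = cc[cc["group"] == "LLDL"][variable]
    return TwoByTwoTable(
        a=int((case == positive_level).sum()),
        b=int((case != positive_level).sum()),
        c=int((control == positive_level).sum()),
        d=int((control != positive_level).sum()),
    )


def univariable_table(
    cohort: pd.DataFrame,
    variables: list[str],
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Per-variable crude association table (the univariable-analysis shape).

    Binary tristate covariates use :func:`crude_or` on complete cases
    (exposed = ``"yes"``; for ``sex``, exposed = ``"male"``).  Continuous
    covariates use a single-predictor logistic fit and report the per-unit
    OR with its Wald statistic.  ``n_used`` is the per-variable
    complete-case denominator.
    """
    threshold = (
        bonferroni_threshold(alpha, bonferroni_m) if bonferroni_m else None
    )
    rows = []
    for variable in variables:
        if variable not in cohort.columns:
            raise ValueError(f"variable {variable!r} not in cohort")
        if variable in CONTINUOUS_COVARIATES or pd.api.types.is_numeric_dtype(
            cohort[variable]
        ):
            cc = cohort[cohort[variable].notna() & cohort["group"].isin(["HLDL", "LLDL"])]
            y = (cc["group"] == "HLDL").to_numpy(dtype=float)
            fit = riskmodel.fit_logistic(cc[[variable]], y)
            b, se = fit.coef(variable), fit.se(variable)
            wald = (b / se) ** 2
            res = AssociationResult(
                or_hat=math.exp(b), ln_or=b, se_ln_or=se, wald_chi2=wald, df=1,
                p_value=float(stats.chi2.sf(wald, df=1)),
                ci95=(math.exp(b - Z95 * se), math.exp(b + Z95 * se)),
            )
            n_used = len(cc)
            level = "per_unit"
        else:
            level = "male" if variable == "sex" else "yes"
            try:
                table = _binary_table(cohort, variable, level)
                res = crude_or(table)
            except ValueError as err:
                raise ValueError(f"variable {variable!r}: {err}") from err
            n_used = int(table.a + table.b + table.c + table.d)
        rows.append(
            {
                "variable": variable,
                "exposed_level": level,
                "or": res.or_hat,
                "ci_low": res.ci95[0],
                "ci_high": res.ci95[1],
                "wald_chi2": res.wald_chi2,
                "df": res.df,
                "p": res.p_value,
                "n_used": n_used,
                "significant": res.p_value < (threshold if threshold else alpha),
            }
        )
    return pd.DataFrame(rows)


def genotype_table(
    cohort: pd.DataFrame,
    variant_ids: list[str],
    alpha: float = 0.05,
    haldane_correction: bool = False,
) -> pd.DataFrame:
    """Genotype odds ratios for ``gt_``-coded variants in a cohort table.

    The reference category is homozygous reference (``"ref"``).  The
    Bonferroni threshold uses the number of variants tested.
    """
    threshold = bonferroni_threshold(alpha, len(variant_ids)) if variant_ids else alpha
    rows = []
    for vid in variant_ids:
        col = GT_PREFIX + vid
        if col not in cohort.columns:
            raise ValueError(f"genotype column {col!r} not in cohort")
        cc = complete_cases(cohort, col)
        case = cc[cc["group"] == "HLDL"][col]
        control = cc[cc["group"] == "LLDL"][col]
        cats = tuple(
            c for c in ("ref", "het", "hom")
            if (case == c).sum() + (control == c).sum() > 0
        )
        counts = GenotypeCounts(
            categories=cats,
            case_counts=tuple(int((case == c).sum()) for c in cats),
            control_counts=tuple(int((control == c).sum()) for c in cats),
            reference="ref",
        )
        for cat, res in genotype_or(counts, haldane_correction=haldane_correction).items():
            rows.append(
                {
                    "variant": vid, "genotype": cat,
                    "n_case": counts.case_counts[cats.index(cat)],
                    "n_control": counts.control_counts[cats.index(cat)],
                    "or": res.or_hat, "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                    "wald_chi2": res.wald_chi2, "df": res.df, "p": res.p_value,
                    "significant_after_bonferroni": res.p_value < threshold,
                }
            )
    return pd.DataFrame(rows)
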