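"""Multivariable logistic risk modelling.

Builds the validation-phase models: parsimonious logistic regression of
case status on clinical covariates and genotyped variants, summarised by
adjusted odds ratios, Nagelkerke's pseudo R-squared, and the AUROC with a
DeLong 95% confidence interval; plus the variance-explained increment
from adding a variant to a clinical-only model and multiplicative
gene-environment interaction tests.

Maximum-likelihood fitting is delegated to ``statsmodels`` (Newton
iterations, standard errors from the observed information); everything
statistical layered on top - the pseudo R-squared, AUROC/DeLong,
change-in-estimate backward elimination, interaction Wald tests - is
implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import BINARY_COVARIATES, GT_PREFIX

Z95 = 1.96


@dataclass
class LogisticFit:
    """A fitted binary logistic model."""

    predictors: list[str]  # without the intercept
    params: pd.Series  # includes "const"
    bse: pd.Series
    loglik_fit: float
    loglik_null: float
    n: int
    converged: bool
    separated: bool
    fitted: np.ndarray  # in-sample probabilities
    y: np.ndarray
    row_index: pd.Index

    def coef(self, name: str) -> float:
        return float(self.params[name])

    def se(self, name: str) -> float:
        return float(self.bse[name])

    def p_value(self, name: str) -> float:
        z = self.coef(name) / self.se(name)
        return float(stats.chi2.sf(z * z, df=1))

    def odds_ratio(self, name: str) -> tuple[float, tuple[float, float]]:
        b, s = self.coef(name), self.se(name)
        with np.errstate(over="ignore"):
            return float(np.exp(b)), (
                float(np.exp(b - Z95 * s)), float(np.exp(b + Z95 * s))
            )


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank == X.shape[1]:
        return
    culprits = []
    for col in X.columns:
        reduced = X.drop(columns=[col]).to_numpy(dtype=float)
        if np.linalg.matrix_rank(reduced) == rank:
            culprits.append(col)
    raise ValueError(f"design matrix is rank deficient; collinear columns: {culprits}")


def fit_logistic(X: pd.DataFrame | np.ndarray, y) -> LogisticFit:
    """Fit a binary logistic regression by maximum likelihood.

    Rows with any missing value are dropped (complete-case).  Raises on
    rank-deficient designs, naming the collinear columns.  Perfect
    separation is flagged on the returned fit rather than raised; its
    standard errors are not interpretable and CIs should be suppressed.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
    if not set(np.unique(y.dropna())) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X[keep], y[keep]
    n = len(y)
    if n <= X.shape[1] + 1:
        raise ValueError(f"n={n} too small for {X.shape[1]} predictors")
    design = sm.add_constant(X.astype(float), has_constant="add")
    _check_rank(design)

    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(method="newton", maxiter=100, disp=0)
        except Exception:  # perfect separation aborts Newton in some versions
            separated = True
            res = sm.Logit(y, design).fit(method="bfgs", maxiter=200, disp=0)
    fitted = np.asarray(res.predict(design))
    if not separated and (np.max(np.abs(res.params.to_numpy())) > 25
                          or np.any(fitted > 1 - 1e-12) or np.any(fitted < 1e-12)):
        separated = True
    try:
        bse = np.asarray(res.bse)
    except np.linalg.LinAlgError:  # singular information under separation
        separated = True
        bse = np.full(design.shape[1], np.nan)
    p_bar = float(y.mean())
    loglik_null = float(
        n * (p_bar * np.log(p_bar) + (1 - p_bar) * np.log1p(-p_bar))
        if 0 < p_bar < 1
        else 0.0
    )
    return LogisticFit(
        predictors=list(X.columns),
        params=pd.Series(res.params, index=design.columns),
        bse=pd.Series(bse, index=design.columns),
        loglik_fit=float(res.llf),
        loglik_null=loglik_null,
        n=n,
        converged=bool(getattr(res, "mle_retvals", {}).get("converged", True)),
        separated=separated,
        fitted=fitted,
        y=y.to_numpy(),
        row_index=X.index,
    )


def nagelkerke_r2(fit: LogisticFit) -> float:
    """Nagelkerke's pseudo R-squared (Cox-Snell rescaled to max 1)."""
    if fit.n == 0:
        raise ValueError("empty fit")
    r2_cs = 1.0 - np.exp(2.0 * (fit.loglik_null - fit.loglik_fit) / fit.n)
    max_cs = 1.0 - np.exp(2.0 * fit.loglik_null / fit.n)
    if max_cs <= 0:
        return 0.0
    return float(r2_cs / max_cs)


def auroc(scores, labels) -> tuple[float, tuple[float, float]]:
    """AUROC with DeLong 95% CI.

    AUC is the Mann-Whitney statistic U / (n1 * n0) with ties counted 1/2
    (the probability a random case outscores a random control).  The CI is
    the DeLong placement-variance normal interval, truncated to [0, 1].
    Raises if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    case = scores[labels == 1]
    control = scores[labels == 0]
    m, n = len(case), len(control)
    if m == 0 or n == 0:
        raise ValueError("need both classes to compute AUROC")
    # placements: for each case, fraction of controls it beats (ties 1/2)
    order = np.argsort(control, kind="mergesort")
    sorted_ctrl = control[order]
    lt = np.searchsorted(sorted_ctrl, case, side="left")
    le = np.searchsorted(sorted_ctrl, case, side="right")
    v10 = (lt + 0.5 * (le - lt)) / n
    order = np.argsort(case, kind="mergesort")
    sorted_case = case[order]
    lt = np.searchsorted(sorted_case, control, side="left")
    le = np.searchsorted(sorted_case, control, side="right")
    v01 = 1.0 - (lt + 0.5 * (le - lt)) / m
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = Z95 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return auc, ci


# ---------------------------------------------------------------------------
# design-matrix encoding of cohort tables

def encode_predictors(
    cohort: pd.DataFrame,
    predictors: list[str],
    genotype_coding: str = "indicator",
) -> pd.DataFrame:
    """Numeric design columns from a cohort table.

    Tristate covariates become 1/0 with missing as NaN (``sex``: male = 1);
    ``gt_`` genotype columns become a carrier indicator vs homozygous
    reference (``"indicator"``, the published "CA vs C" coding) or an
    additive 0/1/2 copy count (``"additive"``).  Continuous columns pass
    through untransformed (per-unit odds ratios).
    """
    if genotype_coding not in ("indicator", "additive"):
        raise ValueError(f"unknown genotype coding {genotype_coding!r}")
    out = {}
    for name in predictors:
        if name not in cohort.columns:
            raise ValueError(f"predictor {name!r} not in cohort")
        col = cohort[name]
        if name == "sex":
            out[name] = col.map({"male": 1.0, "female": 0.0, "": np.nan})
        elif name in BINARY_COVARIATES or (
            col.dtype == object and not name.startswith(GT_PREFIX)
        ):
            out[name] = col.map({"yes": 1.0, "no": 0.0, "": np.nan})
        elif name.startswith(GT_PREFIX):
            if genotype_coding == "indicator":
                mapping = {"ref": 0.0, "het": 1.0, "hom": 1.0, "": np.nan}
            else:
                mapping = {"ref": 0.0, "het": 1.0, "hom": 2.0, "": np.nan}
            out[name] = col.map(mapping)
        else:
            out[name] = col.astype(float)
    return pd.DataFrame(out, index=cohort.index)


def outcome_vector(cohort: pd.DataFrame) -> np.ndarray:
    """1 for HLDL cases, 0 for LLDL controls."""
    groups = cohort["group"]
    if not set(groups.unique()) <= {"HLDL", "LLDL"}:
        raise ValueError("cohort contains unassigned participants")
    return (groups == "HLDL").to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# model building

def backward_select(
    X: pd.DataFrame,
    y,
    p_keep: float = 0.20,
    change_tol: float = 0.15,
    forced: tuple[str, ...] = (),
) -> tuple[LogisticFit, list[dict]]:
    """Parsimonious model by backward elimination with a change-in-estimate guard.

    Iteratively removes the highest-p candidate with p >= ``p_keep``,
    *unless* its removal changes any remaining coefficient by more than
    ``change_tol`` (relative) - such confounders are retained.  ``forced``
    predictors are never candidates.  Deterministic; returns the final fit
    and an audit trail of every attempted removal.
    """
    current = list(X.columns)
    if not current:
        raise ValueError("empty candidate set")
    fit = fit_logistic(X[current], y)
    trail: list[dict] = []
    locked: set[str] = set(forced)
    while True:
        candidates = [
            (fit.p_value(name), name)
            for name in current
            if name not in locked and fit.p_value(name) >= p_keep
        ]
        if not candidates:
            break
        candidates.sort(key=lambda t: (-t[0], t[1]))
        removed_any = False
        for p_val, name in candidates:
            remaining = [c for c in current if c != name]
            if not remaining:
                locked.add(name)
                trail.append({"predictor": name, "p": p_val, "action": "kept_last"})
                continue
            trial = fit_logistic(X[remaining], y)
            max_change = 0.0
            for other in remaining:
                old, new = fit.coef(other), trial.coef(other)
                denom = abs(old) if abs(old) > 1e-8 else 1.0
                max_change = max(max_change, abs(new - old) / denom)
            if max_change > change_tol:
                locked.add(name)
                trail.append(
                    {"predictor": name, "p": p_val, "action": "kept_confounder",
                     "max_coef_change": max_change}
                )
                continue
            current, fit = remaining, trial
            trail.append(
                {"predictor": name, "p": p_val, "action": "removed",
                 "max_coef_change": max_change}
            )
            removed_any = True
            break
        if not removed_any:
            break
    return fit, trail


def fit_nested(
    data: pd.DataFrame,
    y,
    base_predictors: list[str],
    extra_predictors: list[str],
) -> tuple[LogisticFit, LogisticFit]:
    """Fit base and base+extra models on the common complete-case rows."""
    all_cols = list(dict.fromkeys(base_predictors + extra_predictors))
    keep = data[all_cols].notna().all(axis=1)
    aligned = data[keep]
    y = pd.Series(np.asarray(y, dtype=float), index=data.index)[keep]
    fit_base = fit_logistic(aligned[base_predictors], y)
    fit_plus = fit_logistic(aligned[all_cols], y)
    return fit_base, fit_plus


def delta_r2(fit_base: LogisticFit, fit_plus: LogisticFit) -> float:
    """Nagelkerke R-squared increment between two fits on identical rows.

    Raises if the fits used different row sets (use :func:`fit_nested` to
    align complete cases first).
    """
    if len(fit_base.row_index) != len(fit_plus.row_index) or not (
        fit_base.row_index == fit_plus.row_index
    ).all():
        raise ValueError("fits were made on different row sets; align complete cases")
    return nagelkerke_r2(fit_plus) - nagelkerke_r2(fit_base)


def interaction_test(
    X: pd.DataFrame,
    y,
    snp: str,
    env: str,
    adjusters: list[str] | None = None,
) -> float:
    """Wald p-value for a multiplicative SNP-by-environment interaction.

    Fits main effects (plus ``adjusters``) and the product term; returns
    the Wald p for the product coefficient.  Raises when the SNP or
    environment column is constant or the product term is inestimable
    (e.g. an empty exposure-genotype cell making it collinear).
    """
    adjusters = adjusters or []
    cols = [snp, env] + [a for a in adjusters if a not in (snp, env)]
    design = X[cols].copy()
    keep = design.notna().all(axis=1)
    design = design[keep]
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)[keep]
    for name in (snp, env):
        if design[name].nunique() < 2:
            raise ValueError(f"{name!r} is constant on complete cases")
    product = f"{snp}:{env}"
    design[product] = design[snp] * design[env]
    try:
        fit = fit_logistic(design, y)
    except ValueError as err:
        raise ValueError(f"interaction term {product!r} inestimable: {err}") from err
    if fit.separated:
        raise ValueError(f"interaction term {product!r} inestimable: separation")
    return fit.p_value(product)


def model_summary(fit: LogisticFit) -> dict:
    """Adjusted ORs with CIs and p-values, Nagelkerke R2, AUROC with CI."""
    auc, auc_ci = auroc(fit.fitted, fit.y)
    terms = []
    for name in fit.predictors:
        or_hat, ci = fit.odds_ratio(name)
        terms.append(
            {
                "predictor": name,
                "aor": or_hat,
                "ci_low": ci[0] if not fit.separated else np.nan,
                "ci_high": ci[1] if not fit.separated else np.nan,
                "p": fit.p_value(name),
            }
        )
    return {
        "terms": pd.DataFrame(terms),
        "nagelkerke_r2": nagelkerke_r2(fit),
        "auc": auc,
        "auc_ci95": auc_ci,
        "n": fit.n,
        "converged": fit.converged,
        "separated": fit.separated,
    }
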