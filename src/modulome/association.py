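"""Regression layers linking modules and single features to weight change.

The phenotype of interest is the annual percentage body weight change

    dbw = 100 * ((weight_f4 - weight_s4) / weight_s4) / followup_years

(positive = gain).  The base model regresses each module eigengene (or
single feature) on dbw adjusted for age, sex and baseline body weight, with
a Wald test on the dbw coefficient and Bonferroni-referenced significance.
On top of that sit subgroup interaction models, sensitivity-adjustment
models (lifestyle / incident disease / medication-change blocks) and
cross-sectional clinical-trait models (logistic for binary traits, linear
for log-transformed continuous traits).

The base fit uses a closed-form least-squares path (needed for the large
calibration studies); the interaction, sensitivity and clinical models are
fitted with statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import OmicsMatrix
from .impute import ImputationSet, pool_estimates

__all__ = [
    "compute_dbw",
    "bonferroni_threshold",
    "adjust_technical",
    "fit_me_association",
    "subgroup_interaction_model",
    "sensitivity_adjusted_model",
    "clinical_trait_association",
]

BASE_COVARIATES = ("age", "sex", "weight_s4")

RESULT_COLUMNS = ["target_id", "effect", "se", "wald_stat", "p", "n_tests",
                  "bonferroni_threshold", "significant", "pooled_over_m"]


def compute_dbw(weight_s4, weight_f4, followup_years):
    """Annual percentage body weight change; positive for weight gain."""
    w0 = np.asarray(weight_s4, dtype=float)
    w1 = np.asarray(weight_f4, dtype=float)
    yrs = np.asarray(followup_years, dtype=float)
    if np.any(w0 <= 0) or np.any(w1 <= 0):
        raise ValueError("weights must be positive")
    if np.any(yrs <= 0):
        raise ValueError("follow-up years must be positive")
    out = 100.0 * ((w1 - w0) / w0) / yrs
    if np.isscalar(weight_s4) or np.ndim(weight_s4) == 0:
        return float(out)
    if isinstance(weight_s4, pd.Series):
        return pd.Series(out, index=weight_s4.index, name="dbw")
    return out


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def adjust_technical(transcripts: OmicsMatrix | pd.DataFrame,
                     technical: pd.DataFrame):
    """Replace each transcript by its residuals on the technical covariates.

    The design includes an intercept; a rank-deficient design raises with
    the collinear columns named.
    """
    frame = transcripts.values if isinstance(transcripts, OmicsMatrix) else transcripts
    tech = technical.loc[frame.index].astype(float)
    if tech.isna().any().any():
        raise ValueError("technical covariates must be complete")
    X = np.column_stack([np.ones(len(frame))] + [tech[c].to_numpy() for c in tech])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full column rank
        collinear = []
        for j, c in enumerate(tech.columns, start=1):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                collinear.append(c)
        raise ValueError(f"rank-deficient technical design; collinear: {collinear}")
    Q, _ = np.linalg.qr(X)
    Y = frame.to_numpy(float)
    resid = Y - Q @ (Q.T @ Y)
    out = pd.DataFrame(resid, index=frame.index, columns=frame.columns)
    if isinstance(transcripts, OmicsMatrix):
        return OmicsMatrix(out, transcripts.annotation.copy())
    return out


def _ols(y: np.ndarray, X: np.ndarray):
    """Closed-form OLS: returns (beta, se, df)."""
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} too small for {k} parameters")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = (resid * resid).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    return beta, se, df


def _design(pheno: pd.DataFrame, samples, covariates) -> tuple:
    cols = ["dbw", *covariates]
    missing = [c for c in cols if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    block = pheno.loc[samples, cols].astype(float)
    if block.isna().any().any():
        raise ValueError("covariates must be complete")
    X = np.column_stack([np.ones(len(block)), block.to_numpy()])
    return X, ["const"] + cols


def fit_me_association(targets: pd.DataFrame | OmicsMatrix, pheno: pd.DataFrame,
                       covariates=BASE_COVARIATES,
                       imputations: ImputationSet | None = None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Base association model for every column of ``targets``.

    Each target (module eigengene or single feature) is regressed on dbw
    plus the covariates; the Wald statistic ``effect/se`` for the dbw
    coefficient is referred to a t distribution, and significance uses the
    Bonferroni threshold ``alpha / n_targets``.

    When an :class:`ImputationSet` is given the targets are taken from each
    completed dataset and the per-dataset estimates pooled by Rubin's rules
    (targets must then name features of the imputed matrix).
    """
    frame = targets.values if isinstance(targets, OmicsMatrix) else targets
    n_tests = frame.shape[1]
    threshold = bonferroni_threshold(alpha, n_tests)
    rows = []
    if imputations is None or imputations.m == 1:
        X, _ = _design(pheno, frame.index, covariates)
        Y = frame.to_numpy(float)
        beta, se, df = _ols(Y, X)
        for j, target in enumerate(frame.columns):
            b, s = float(beta[1, j]), float(se[1, j])
            w = b / s
            p = float(2 * stats.t.sf(abs(w), df))
            rows.append((target, b, s, w, p, n_tests, threshold,
                         p < threshold, False))
    else:
        per_target = {t: [] for t in frame.columns}
        dfcom = None
        for ds in imputations.datasets:
            sub = ds.values[list(frame.columns)]
            X, _ = _design(pheno, sub.index, covariates)
            beta, se, df = _ols(sub.to_numpy(float), X)
            dfcom = df
            for j, t in enumerate(frame.columns):
                per_target[t].append((float(beta[1, j]), float(se[1, j])))
        for t, pairs in per_target.items():
            pooled = pool_estimates(pairs, dfcom=dfcom)
            rows.append((t, pooled.estimate, pooled.se, pooled.statistic,
                         pooled.p, n_tests, threshold, pooled.p < threshold, True))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def subgroup_interaction_model(targets: pd.DataFrame, pheno: pd.DataFrame,
                               subgroup: str, covariates=BASE_COVARIATES) -> pd.DataFrame:
    """Single interaction model per target, reporting per-subgroup dbw slopes.

    The base model is extended by the subgroup indicator and its
    interactions with dbw and every covariate; subgroup-specific dbw slopes
    (and SEs) are linear combinations of the dbw main effect and the
    dbw x subgroup interaction, whose Wald p quantifies the slope difference.
    """
    flag = pheno.loc[targets.index, subgroup].astype(float)
    if flag.nunique() != 2:
        raise ValueError(f"subgroup {subgroup!r} must have two nonempty levels")
    g = (flag == flag.max()).astype(float).to_numpy()
    X, names = _design(pheno, targets.index, covariates)
    Xfull = np.column_stack([X, g, X[:, 1:] * g[:, None]])
    names = names + [subgroup] + [f"{c}:{subgroup}" for c in names[1:]]
    if Xfull.shape[0] <= Xfull.shape[1] + 1:
        raise ValueError("too few samples for the interaction model")
    i_dbw = names.index("dbw")
    i_int = names.index(f"dbw:{subgroup}")
    rows = []
    for target in targets.columns:
        fit = sm.OLS(targets[target].to_numpy(float), Xfull).fit()
        c = np.zeros(Xfull.shape[1])
        c[i_dbw] = 1.0
        b0, s0 = float(fit.params[i_dbw]), float(fit.bse[i_dbw])
        c[i_int] = 1.0
        b1 = float(fit.params[i_dbw] + fit.params[i_int])
        s1 = float(np.sqrt(c @ fit.cov_params() @ c))
        p_int = float(fit.pvalues[i_int])
        rows.append((target, b0, s0, b1, s1,
                     float(fit.params[i_int]), p_int))
    return pd.DataFrame(rows, columns=[
        "target_id", "effect_group0", "se_group0", "effect_group1", "se_group1",
        "interaction_effect", "interaction_p"])


def sensitivity_adjusted_model(targets: pd.DataFrame, pheno: pd.DataFrame,
                               extra_block, covariates=BASE_COVARIATES,
                               alpha: float = 0.05) -> pd.DataFrame:
    """Base model plus a named covariate block; reports the dbw-effect change.

    ``extra_block`` is a list of phenotype columns (for example changes in
    lifestyle factors, disease incidence, or medication changes).  Strong
    collinearity between the block and dbw is reported through the
    ``se_inflation`` column (ratio of adjusted to base SE) rather than
    failing silently.
    """
    extra_block = list(extra_block)
    missing = [c for c in extra_block if c not in pheno.columns]
    if missing:
        raise ValueError(f"missing covariate block columns: {missing}")
    base = fit_me_association(targets, pheno, covariates, alpha=alpha)
    adj = fit_me_association(targets, pheno,
                             tuple(covariates) + tuple(extra_block), alpha=alpha)
    out = base[["target_id", "effect", "se", "p"]].merge(
        adj[["target_id", "effect", "se", "wald_stat", "p", "n_tests",
             "bonferroni_threshold", "significant"]],
        on="target_id", suffixes=("_base", ""))
    out["effect_change"] = out["effect"] - out["effect_base"]
    out["se_inflation"] = out["se"] / out["se_base"]
    return out


def clinical_trait_association(eigengenes: pd.DataFrame, pheno: pd.DataFrame,
                               traits: dict, covariates=("age", "sex", "weight_f4"),
                               medication=(), alpha: float = 0.05) -> pd.DataFrame:
    """Cross-sectional models of clinical traits on module eigengenes.

    ``traits`` maps trait column -> kind ("binary" or "continuous").
    Binary traits are modelled by logistic regression of the trait on the
    eigengene plus covariates (Wald test on the eigengene coefficient);
    continuous traits are natural-log transformed and modelled linearly.
    The Bonferroni threshold is ``alpha / (n_traits * n_modules)``.
    Single-class binary traits are skipped with a warning.
    """
    import logging

    log = logging.getLogger(__name__)
    cov_cols = [c for c in (*covariates, *medication)]
    missing = [c for c in cov_cols if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    C = pheno.loc[eigengenes.index, cov_cols].astype(float)
    n_tests = len(traits) * eigengenes.shape[1]
    threshold = bonferroni_threshold(alpha, max(n_tests, 1))
    rows = []
    for trait, kind in traits.items():
        y = pheno.loc[eigengenes.index, trait].astype(float)
        if kind == "binary":
            if y.nunique() < 2:
                log.warning("trait %s has a single class; skipped", trait)
                continue
        else:
            if (y <= 0).any():
                raise ValueError(f"continuous trait {trait} must be positive "
                                 "for log transform")
            y = np.log(y)
        for me in eigengenes.columns:
            X = sm.add_constant(
                pd.concat([eigengenes[me].rename("ME"), C], axis=1))
            if kind == "binary":
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            else:
                fit = sm.OLS(y, X).fit()
            b, s = float(fit.params["ME"]), float(fit.bse["ME"])
            p = float(fit.pvalues["ME"])
            rows.append((f"{trait}~{me}", b, s, b / s, p, n_tests, threshold,
                         p < threshold, False))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
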