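"""Multiple imputation by chained equations (predictive mean matching)
and Rubin's-rules pooling of downstream estimates.

The imputation model follows the standard chained-equations scheme: each
variable with missing cells is regressed in turn on a predictor set (the
top-K most correlated variables plus age, sex and the weight-change
phenotype), regression coefficients are drawn from their approximate
posterior (normal draw for the coefficients, scaled inverse-chi-square for
the residual variance), and each missing cell is filled with the observed
value of a donor drawn at random from the ``donors`` closest predicted
means.  PMM keeps imputed values inside the observed support, which suits
log-scale metabolite concentrations.  Cycling the scheme ``n_iterations``
times per dataset and repeating for ``m`` datasets yields a proper multiple
imputation whose between-dataset variance feeds Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import OmicsMatrix

__all__ = ["ImputationSet", "PooledEstimate", "mice_impute", "pool_estimates"]

#: phenotype columns always included as predictors when available
DEFAULT_PHENO_PREDICTORS = ("age", "sex", "dbw")


@dataclass
class ImputationSet:
    """``m`` completed datasets plus the convergence trace.

    ``datasets`` are complete :class:`OmicsMatrix` objects sharing shape and
    ids with the input; ``trace`` records, per (dataset, iteration,
    variable), the mean and SD of the imputed cells — monitoring only.
    """

    m: int
    datasets: list
    n_iterations: int
    seed: int
    trace: pd.DataFrame = None
    pheno: pd.DataFrame = None


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of per-dataset (estimate, se) pairs."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    se: float
    df: float
    statistic: float
    p: float
    m: int


def _posterior_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """OLS fit plus a draw from the approximate coefficient posterior.

    Returns (beta_hat, beta_star).  Ridge jitter guards the rare singular
    design; the posterior uses sigma^2 ~ RSS / chi2(df) and
    beta* ~ N(beta_hat, sigma^2 (X'X)^-1).
    """
    n, k = X.shape
    XtX = X.T @ X
    XtX.flat[:: k + 1] += 1e-8  # ridge jitter for numerical rank safety
    Xty = X.T @ y
    L = np.linalg.cholesky(XtX)
    beta_hat = np.linalg.solve(L.T, np.linalg.solve(L, Xty))
    resid = y - X @ beta_hat
    df = max(n - k, 1)
    sigma2 = (resid @ resid) / rng.chisquare(df)
    # solve L^T z = eps gives z ~ N(0, (X'X)^-1)
    eps = rng.standard_normal(k)
    beta_star = beta_hat + np.sqrt(sigma2) * np.linalg.solve(L.T, eps)
    return beta_hat, beta_star


def _pmm_match(yhat_obs: np.ndarray, y_obs: np.ndarray, yhat_mis: np.ndarray,
               donors: int, rng: np.random.Generator) -> np.ndarray:
    """For each missing prediction, draw one of the ``donors`` nearest
    observed predictions and return its observed value."""
    order = np.argsort(yhat_obs, kind="stable")
    sorted_hat = yhat_obs[order]
    k = min(donors, len(y_obs))
    pos = np.searchsorted(sorted_hat, yhat_mis)
    out = np.empty(len(yhat_mis))
    for t, (p0, yh) in enumerate(zip(pos, yhat_mis)):
        lo = max(0, p0 - k)
        hi = min(len(sorted_hat), p0 + k)
        window = order[lo:hi]
        d = np.abs(yhat_obs[window] - yh)
        nearest = window[np.argsort(d, kind="stable")[:k]]
        out[t] = y_obs[nearest[rng.integers(len(nearest))]]
    return out


def mice_impute(matrix: OmicsMatrix, pheno: pd.DataFrame | None = None,
                m: int = 20, n_iterations: int = 10, k_predictors: int = 15,
                donors: int = 5, min_observed: int = 10,
                seed: int = 0) -> ImputationSet:
    """Chained-equations multiple imputation with predictive mean matching.

    Parameters mirror the analysis defaults: ``m`` = 20 completed datasets,
    ``n_iterations`` = 10 chained cycles each.  Phenotype columns with
    missing values (numeric) are imputed in the same process.  Observed
    cells are never altered.  Deterministic given ``seed``.
    """
    data = matrix.values.copy()
    pheno_cols: list = []
    if pheno is not None:
        extra = pheno.loc[matrix.sample_ids].select_dtypes("number")
        always = [c for c in DEFAULT_PHENO_PREDICTORS if c in extra.columns]
        with_missing = [c for c in extra.columns if extra[c].isna().any()]
        pheno_cols = sorted(set(always) | set(with_missing), key=list(extra.columns).index)
        data = pd.concat([data, extra[pheno_cols]], axis=1)

    arr = data.to_numpy(copy=True)
    n, p = arr.shape
    obs_mask = ~np.isnan(arr)
    targets = np.nonzero(~obs_mask.all(axis=0))[0]
    for j in targets:
        if obs_mask[:, j].sum() < min_observed:
            raise ValueError(
                f"variable {data.columns[j]!r} has fewer than "
                f"{min_observed} observed values"
            )
    if len(targets) == 0:
        complete = [matrix.copy() for _ in range(m)]
        return ImputationSet(m=m, datasets=complete, n_iterations=n_iterations,
                             seed=seed, trace=pd.DataFrame(), pheno=pheno)

    # predictor sets: top-K |correlation| on observed pairs + pheno anchors
    corr = pd.DataFrame(arr, columns=data.columns).corr().to_numpy()
    np.fill_diagonal(corr, 0.0)
    anchor_idx = [data.columns.get_loc(c) for c in
                  (c for c in DEFAULT_PHENO_PREDICTORS if c in data.columns)]
    predictors = {}
    for j in targets:
        c = np.abs(corr[j])
        c = np.where(np.isnan(c), 0.0, c)
        top = np.argsort(-c, kind="stable")[:k_predictors]
        cols = [int(t) for t in top if c[t] > 0 and t != j]
        for a in anchor_idx:
            if a != j and a not in cols:
                cols.append(a)
        predictors[j] = np.array(cols, dtype=int)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(m)
    datasets, trace_rows = [], []
    for d in range(m):
        rng = np.random.default_rng(child_seeds[d])
        filled = arr.copy()
        # initial fill: random draws from each variable's observed values
        for j in targets:
            obs = arr[obs_mask[:, j], j]
            nm = (~obs_mask[:, j]).sum()
            filled[~obs_mask[:, j], j] = rng.choice(obs, size=nm, replace=True)
        for it in range(n_iterations):
            for j in targets:
                mis = ~obs_mask[:, j]
                pred = predictors[j]
                X = np.column_stack([np.ones(n), filled[:, pred]])
                y_obs = arr[obs_mask[:, j], j]
                beta_hat, beta_star = _posterior_draw(X[obs_mask[:, j]], y_obs, rng)
                yhat_obs = X[obs_mask[:, j]] @ beta_hat
                yhat_mis = X[mis] @ beta_star
                filled[mis, j] = _pmm_match(yhat_obs, y_obs, yhat_mis, donors, rng)
                imp = filled[mis, j]
                trace_rows.append((d, it, data.columns[j],
                                   float(imp.mean()), float(imp.std(ddof=0))))
        frame = pd.DataFrame(filled, index=data.index, columns=data.columns)
        om = OmicsMatrix(frame[matrix.feature_ids], matrix.annotation.copy())
        if pheno_cols:
            om.completed_pheno = frame[pheno_cols]
        datasets.append(om)

    trace = pd.DataFrame(trace_rows,
                         columns=["dataset", "iteration", "variable",
                                  "imputed_mean", "imputed_sd"])
    _warn_if_nonconvergent(trace)
    return ImputationSet(m=m, datasets=datasets, n_iterations=n_iterations,
                         seed=seed, trace=trace, pheno=pheno)


def _warn_if_nonconvergent(trace: pd.DataFrame) -> None:
    """Monitoring only: warn when the imputed-mean trace still drifts."""
    import logging

    if trace.empty or trace["iteration"].max() < 3:
        return
    log = logging.getLogger(__name__)
    for var, g in trace.groupby("variable"):
        by_iter = g.groupby("iteration")["imputed_mean"].mean()
        tail = by_iter.iloc[-3:]
        spread = by_iter.max() - by_iter.min()
        if spread > 0 and (tail.max() - tail.min()) > 0.8 * spread and spread > 0.5:
            log.warning("imputation trace for %s may not have converged", var)


def pool_estimates(per_dataset, dfcom: float | None = None) -> PooledEstimate:
    """Combine per-dataset (estimate, se) pairs by Rubin's rules.

    ``total_var = within + (1 + 1/m) * between``; the reference distribution
    is t with the classical degrees of freedom
    ``(m - 1) * (1 + within / ((1 + 1/m) * between))^2``, replaced by the
    Barnard–Rubin small-sample adjustment when the complete-data residual
    degrees of freedom ``dfcom`` are supplied.  With a single dataset the
    pair is passed through with a normal reference.
    """
    pairs = [(float(b), float(s)) for b, s in per_dataset]
    m = len(pairs)
    if m == 0:
        raise ValueError("no estimates to pool")
    est = np.array([b for b, _ in pairs])
    se = np.array([s for _, s in pairs])
    if m == 1:
        import logging

        logging.getLogger(__name__).warning("pooling a single dataset: pass-through")
        b, s = pairs[0]
        z = b / s if s > 0 else np.inf
        p = 2 * stats.norm.sf(abs(z))
        return PooledEstimate(b, s**2, 0.0, s**2, s, np.inf, z, float(p), 1)

    qbar = float(est.mean())
    within = float((se**2).mean())
    between = float(est.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    se_pooled = float(np.sqrt(total))
    if between > 0:
        r = (1.0 + 1.0 / m) * between / within
        df = (m - 1) * (1.0 + 1.0 / r) ** 2
        if dfcom is not None and np.isfinite(dfcom):
            lam = (1.0 + 1.0 / m) * between / total
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
            df = 1.0 / (1.0 / df + 1.0 / df_obs)
    elif dfcom is not None and np.isfinite(dfcom):
        df = float(dfcom)
    else:
        df = np.inf
    statistic = qbar / se_pooled if se_pooled > 0 else np.inf
    p = float(2 * stats.t.sf(abs(statistic), df)) if np.isfinite(df) else \
        float(2 * stats.norm.sf(abs(statistic)))
    return PooledEstimate(qbar, within, between, total, se_pooled, float(df),
                          float(statistic), p, m)
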