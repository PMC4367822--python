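"""Module-eigengene partial-correlation network and connectivity tests.

For each pair of module eigengenes the partial correlation ``zeta`` is the
Pearson correlation of the residuals of the two eigengenes after regressing
each on all other eigengenes plus the covariates (sex, age, body weight,
weight change).  Because strongly interrelated modules can produce spurious
negative partial correlations, an edge additionally requires the marginal
correlation to exceed a minimum magnitude with the same sign as ``zeta``.
Edges are classed strong/weak by |zeta| thresholds (strict inequalities).

Inter-module connectivity is the correlation of two eigengenes within a
sample group (eigengenes projected with pooled loadings, so differences
reflect correlation changes, not rotated components); intra-module
connectivity is the mean |kME| of a module's members within the group.
Group differences are tested by permuting the group flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comodule import ModuleSet
from .datatypes import OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleNetwork",
    "partial_correlation_network",
    "classify_edge",
    "connectivity_permutation_test",
]

NETWORK_COVARIATES = ("sex", "age", "weight_f4", "dbw")

EDGE_CLASSES = ("strong+", "strong-", "weak+", "weak-", "none")


@dataclass
class ModuleNetwork:
    nodes: pd.DataFrame       # index: ME name; columns: layer
    edges: pd.DataFrame       # a, b, marginal_r, zeta, edge_class, drawn
    conditioning: str = ""

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(conditioning=self.conditioning)
        for node, row in self.nodes.iterrows():
            g.add_node(node, **row.to_dict())
        for _, e in self.edges.iterrows():
            if e["drawn"]:
                g.add_edge(e["a"], e["b"], marginal_r=float(e["marginal_r"]),
                           zeta=float(e["zeta"]), edge_class=e["edge_class"])
        return g


def classify_edge(zeta: float, strong: float = 0.1, weak: float = 0.05) -> str:
    """Edge class from the partial correlation, strict thresholds."""
    if not -1.0 <= zeta <= 1.0:
        raise ValueError("zeta must lie in [-1, 1]")
    if zeta > strong:
        return "strong+"
    if zeta < -strong:
        return "strong-"
    if weak < zeta <= strong:
        return "weak+"
    if -strong <= zeta < -weak:
        return "weak-"
    return "none"


def partial_correlation_network(eigengenes: pd.DataFrame,
                                pheno: pd.DataFrame | None = None,
                                covariates=NETWORK_COVARIATES,
                                strong: float = 0.1, weak: float = 0.05,
                                marginal_min: float = 0.05,
                                layer_of: dict | None = None) -> ModuleNetwork:
    """Partial-correlation network over the module eigengenes.

    For every pair (a, b), both eigengenes are regressed (least squares with
    intercept) on all remaining eigengenes plus the covariate columns taken
    from ``pheno``; ``zeta`` is the correlation of the residuals.  An edge
    is drawn only when ``|marginal_r| >= marginal_min`` and ``zeta`` agrees
    in sign with the marginal correlation.
    """
    me = eigengenes.astype(float)
    names = list(me.columns)
    if len(names) < 2:
        raise ValueError("need at least 2 modules for a partial-correlation network")
    if len(names) == 2 and not covariates:
        logger.info("two modules, empty conditioning set: zeta is the "
                    "marginal correlation")
    cov_cols = []
    if pheno is not None and covariates:
        missing = [c for c in covariates if c not in pheno.columns]
        if missing:
            raise ValueError(f"phenotype table lacks covariates: {missing}")
        cov_cols = [pheno.loc[me.index, c].to_numpy(float) for c in covariates]
    n = len(me)
    n_cond = len(names) - 2 + len(cov_cols)
    if n <= n_cond + 3:
        raise ValueError("too few samples for the conditioning set")

    marg = np.corrcoef(me.to_numpy(), rowvar=False)
    rows = []
    arr = me.to_numpy()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            others = [arr[:, t] for t in range(len(names)) if t not in (i, j)]
            X = np.column_stack([np.ones(n), *others, *cov_cols])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError("rank-deficient conditioning design")
            Q, _ = np.linalg.qr(X)
            ra = arr[:, i] - Q @ (Q.T @ arr[:, i])
            rb = arr[:, j] - Q @ (Q.T @ arr[:, j])
            va, vb = float(ra @ ra), float(rb @ rb)
            if va < 1e-12 * n or vb < 1e-12 * n:
                raise ValueError(
                    f"degenerate pair ({names[i]}, {names[j]}): residual "
                    "variance ~ 0 (eigengenes collinear with the conditioning set)"
                )
            zeta = float(np.clip(ra @ rb / np.sqrt(va * vb), -1.0, 1.0))
            mr = float(marg[i, j])
            drawn = abs(mr) >= marginal_min and np.sign(zeta) == np.sign(mr) \
                and zeta != 0
            cls = classify_edge(zeta, strong, weak) if drawn else "none"
            rows.append((names[i], names[j], mr, zeta, cls, drawn and cls != "none"))
    edges = pd.DataFrame(rows, columns=["a", "b", "marginal_r", "zeta",
                                        "edge_class", "drawn"])
    nodes = pd.DataFrame(
        {"layer": [
            (layer_of or {}).get(nm, "metabolite") for nm in names]},
        index=pd.Index(names, name="module"))
    conditioning = "all other MEs + " + ", ".join(covariates) if cov_cols \
        else "all other MEs"
    return ModuleNetwork(nodes=nodes, edges=edges, conditioning=conditioning)


def _group_corr(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    return float(xc @ yc / denom) if denom > 0 else 0.0


def _columnwise_corr(block: np.ndarray, me: np.ndarray) -> np.ndarray:
    bc = block - block.mean(axis=0)
    mc = me - me.mean()
    denom = np.sqrt((bc**2).sum(axis=0) * (mc @ mc))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = bc.T @ mc / denom
    return np.where(np.isfinite(out), out, 0.0)


def connectivity_permutation_test(data: OmicsMatrix | pd.DataFrame,
                                  module_set: ModuleSet, group: pd.Series,
                                  kind: str = "intra", n_perm: int = 10_000,
                                  seed: int = 0) -> pd.DataFrame:
    """Permutation test of group differences in module connectivity.

    ``kind="inter"``: statistic per module pair = cor(ME_a, ME_b) within
    each group, eigengenes projected with pooled loadings.  ``kind="intra"``:
    statistic per module = mean |kME| of its members within each group.  The
    observed between-group difference is compared (two-sided, absolute
    difference) to the null from shuffling the group flag; p uses +1
    smoothing.
    """
    if kind not in ("inter", "intra"):
        raise ValueError("kind must be 'inter' or 'intra'")
    frame = data.values if isinstance(data, OmicsMatrix) else data
    flag = group.loc[frame.index].astype(int).to_numpy()
    n1, n0 = int(flag.sum()), int((1 - flag).sum())
    if min(n0, n1) < 10:
        raise ValueError("both groups must have at least 10 samples")
    if min(n0, n1) / len(flag) < 0.05:
        logger.warning("group imbalance beyond 95/5; permutation p unstable")
    me = module_set.eigengenes.loc[frame.index].to_numpy(float)
    labels = module_set.module_labels
    rng = np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(flag) for _ in range(n_perm)])

    results = []
    if kind == "inter":
        for ai in range(len(labels)):
            for bi in range(ai + 1, len(labels)):
                a, b = me[:, ai], me[:, bi]

                def stat(f):
                    return (_group_corr(a[f == 1], b[f == 1]),
                            _group_corr(a[f == 0], b[f == 0]))

                s1, s0 = stat(flag)
                obs = s1 - s0
                null = np.array([np.subtract(*stat(perms[:, t]))
                                 for t in range(n_perm)])
                p = (1.0 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (1.0 + n_perm)
                results.append(("inter", f"ME{labels[ai]}|ME{labels[bi]}",
                                s1, s0, obs, n_perm, float(p), seed))
    else:
        for mi, label in enumerate(labels):
            members = module_set.members(label)
            block = frame[list(members)].to_numpy(float)
            e = me[:, mi]

            def stat(f):
                sel1, sel0 = f == 1, f == 0
                k1 = np.abs(_columnwise_corr(block[sel1], e[sel1])).mean()
                k0 = np.abs(_columnwise_corr(block[sel0], e[sel0])).mean()
                return k1, k0

            s1, s0 = stat(flag)
            obs = s1 - s0
            null = np.array([np.subtract(*stat(perms[:, t]))
                             for t in range(n_perm)])
            p = (1.0 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (1.0 + n_perm)
            results.append(("intra", f"ME{label}", s1, s0, obs, n_perm,
                            float(p), seed))
    return pd.DataFrame(results, columns=[
        "kind", "target", "stat_group1", "stat_group0", "difference",
        "n_perm", "p_perm", "seed"])
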