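"""Weighted correlation network construction and module detection.

Implements the WGCNA-style chain on complete data: signed adjacency
``a_ij = ((1 + r_ij)/2)^beta`` from Pearson correlations, soft power chosen
by the scale-free topology criterion, topological overlap similarity,
average-linkage clustering of ``1 - TOM`` with a static quantile cut and a
minimum module size, eigengenes (first principal component of the scaled
member sub-matrix, unit variance, sign-oriented), merging of modules whose
eigengenes cluster below a dendrogram height, and module membership (kME,
the correlation of each feature with each eigengene).

Module labels are canonical — 1..K in decreasing size order with
lexicographic feature-id tie-break, label 0 for unassigned — so results do
not depend on the input feature order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SoftPowerScan",
    "ModuleSet",
    "select_soft_power",
    "signed_adjacency",
    "topological_overlap",
    "cluster_modules",
    "module_eigengenes",
    "merge_close_modules",
    "module_membership",
    "detect_modules",
    "preselect_transcripts",
]

#: soft powers reported for the original metabolite / transcript networks,
#: kept as replay defaults for configurations that bypass the scan
REPLAY_POWER_METABOLITE = 13
REPLAY_POWER_TRANSCRIPT = 8


@dataclass
class SoftPowerScan:
    candidate_powers: list
    fit_r2: pd.Series          # signed scale-free fit R^2 per power
    mean_connectivity: pd.Series
    selected_power: int


@dataclass
class ModuleSet:
    """Feature -> module assignment with eigengenes and membership."""

    assignment: pd.Series            # feature -> int label, 0 = unassigned
    eigengenes: pd.DataFrame         # samples x modules ("ME1", ...)
    kme: pd.DataFrame                # features x modules

    @property
    def module_labels(self) -> list:
        return sorted(int(m) for m in self.assignment.unique() if m != 0)

    @property
    def module_sizes(self) -> pd.Series:
        counts = self.assignment[self.assignment != 0].value_counts().sort_index()
        counts.index = counts.index.astype(int)
        return counts

    def members(self, label: int) -> pd.Index:
        return self.assignment.index[self.assignment == label]


def _corr(data: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        bad = list(pd.Index(data.columns)[sd == 0][:5])
        raise ValueError(f"zero-variance feature(s): {bad}")
    if np.isnan(arr).any():
        raise ValueError("complete data required (impute first)")
    r = np.corrcoef(arr, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def signed_adjacency(data: OmicsMatrix | pd.DataFrame, power: float) -> pd.DataFrame:
    """Signed weighted adjacency ``((1 + cor)/2)^power`` with zero diagonal."""
    frame = data.values if isinstance(data, OmicsMatrix) else data
    r = _corr(frame)
    a = ((1.0 + r) / 2.0) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=frame.columns, columns=frame.columns)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity.

    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with ``TOM_ii = 1``; pairs with a zero denominator (isolated pair in an
    empty graph) get overlap 0 with a warning.  The clustering dissimilarity
    is ``1 - TOM``.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be square and symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a                       # diagonal of a is 0, so u != i,j
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / denom
    zero = denom <= 0
    if zero.any():
        logger.warning("TOM denominator 0 for %d pairs; overlap set to 0",
                       int(zero.sum() // 2))
        tom[zero] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def select_soft_power(data: OmicsMatrix | pd.DataFrame, candidates=range(1, 21),
                      r2_target: float = 0.85, n_bins: int = 10) -> SoftPowerScan:
    """Scan soft powers for approximate scale-free topology.

    For each power the connectivity ``k_i = sum_j a_ij`` is binned (10
    equal-width bins); the fit is the R^2 of ``log10 p(k)`` on ``log10 mean
    k`` per bin, negated when the slope is positive (a scale-free network
    has a falling connectivity distribution).  The selected power is the
    smallest with signed R^2 >= ``r2_target``, else the argmax.
    """
    frame = data.values if isinstance(data, OmicsMatrix) else data
    candidates = [int(b) for b in candidates]
    if not candidates:
        raise ValueError("no candidate powers")
    r = _corr(frame)
    base = (1.0 + r) / 2.0
    np.fill_diagonal(base, 0.0)
    fits, means = {}, {}
    for beta in candidates:
        a = base**beta
        k = a.sum(axis=0)
        means[beta] = float(k.mean())
        fits[beta] = _scale_free_fit(k, n_bins)
    fit_r2 = pd.Series(fits, name="fit_r2")
    selected = next((b for b in candidates if fit_r2[b] >= r2_target), None)
    if selected is None:
        selected = int(fit_r2.idxmax())
        logger.info("no power reached R^2 %.2f; using argmax %d", r2_target, selected)
    return SoftPowerScan(candidates, fit_r2,
                         pd.Series(means, name="mean_connectivity"), int(selected))


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    """Signed R^2 of the log-log connectivity-distribution regression."""
    k = np.asarray(k, dtype=float)
    lo, hi = k.min(), k.max()
    if hi <= lo:
        raise ValueError("degenerate connectivity: all features identical")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        kbar = k[sel].mean()
        freq = sel.mean()
        if kbar > 0 and freq > 0:
            xs.append(np.log10(kbar))
            ys.append(np.log10(freq))
    if len(xs) < 2:
        raise ValueError("fewer than 2 nonempty connectivity bins")
    slope, intercept = np.polyfit(xs, ys, 1)
    yhat = slope * np.array(xs) + intercept
    ss_res = float(((np.array(ys) - yhat) ** 2).sum())
    ss_tot = float(((np.array(ys) - np.mean(ys)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -r2 if slope > 0 else r2


def _canonical_labels(assignment: pd.Series) -> pd.Series:
    """Relabel modules 1..K by decreasing size, ties by smallest feature id."""
    out = pd.Series(0, index=assignment.index, dtype=int, name="module")
    groups = [
        (label, members)
        for label, members in assignment.groupby(assignment).groups.items()
        if label != 0
    ]
    groups.sort(key=lambda t: (-len(t[1]), str(min(map(str, t[1])))))
    for new, (_, members) in enumerate(groups, start=1):
        out.loc[members] = new
    return out


def cluster_modules(dissimilarity: pd.DataFrame, min_module_size: int = 5,
                    cut_height_quantile: float = 0.92) -> pd.Series:
    """Average-linkage clustering of a dissimilarity with a static cut.

    The dendrogram is cut at ``cut_height_quantile`` times the maximum merge
    height; branches with at least ``min_module_size`` members become
    modules, everything else gets label 0.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be square and symmetric")
    ids = pd.Index(dissimilarity.index)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    cut = cut_height_quantile * Z[:, 2].max()
    flat = fcluster(Z, t=cut, criterion="distance")
    assignment = pd.Series(flat, index=ids, dtype=int)
    sizes = assignment.value_counts()
    small = sizes.index[sizes < min_module_size]
    assignment[assignment.isin(small)] = 0
    if (assignment == 0).all():
        logger.warning("no branch reached min_module_size=%d; all unassigned",
                       min_module_size)
    return _canonical_labels(assignment)


def _scale(frame: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(frame, dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature in module")
    return (arr - mean) / sd


def module_eigengenes(data: OmicsMatrix | pd.DataFrame,
                      assignment: pd.Series) -> pd.DataFrame:
    """First principal component of each module's scaled sub-matrix.

    Columns are named ``ME<label>``; each eigengene is scaled to unit
    (sample) variance and sign-flipped so that its mean correlation with the
    module members is positive.  A singleton module's eigengene is the
    z-scored feature itself.
    """
    frame = data.values if isinstance(data, OmicsMatrix) else data
    mes = {}
    for label in sorted(int(m) for m in assignment.unique() if m != 0):
        members = assignment.index[assignment == label]
        X = _scale(frame[members])
        if X.shape[1] == 1:
            me = X[:, 0]
        else:
            u, s, _ = np.linalg.svd(X, full_matrices=False)
            me = u[:, 0] * s[0]
        me = me / me.std(ddof=1)
        corrs = (X * me[:, None]).mean(axis=0)
        if corrs.mean() < 0:
            me = -me
        mes[f"ME{label}"] = me
    return pd.DataFrame(mes, index=frame.index)


def module_membership(data: OmicsMatrix | pd.DataFrame,
                      eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME: Pearson correlation of every feature with every eigengene."""
    frame = data.values if isinstance(data, OmicsMatrix) else data
    X = _scale(frame)
    E = _scale(eigengenes)
    n = X.shape[0]
    kme = X.T @ E / (n - 1)
    return pd.DataFrame(np.clip(kme, -1.0, 1.0),
                        index=frame.columns, columns=eigengenes.columns)


def merge_close_modules(data: OmicsMatrix | pd.DataFrame, assignment: pd.Series,
                        merge_height: float = 0.25) -> ModuleSet:
    """Merge modules whose eigengenes cluster below ``merge_height``.

    Modules are clustered (average linkage) on ``1 - cor(ME)``; clusters
    joined below the height are merged, eigengenes recomputed, and the
    procedure repeats until stable.  Returns the final :class:`ModuleSet`
    with canonical labels, eigengenes and kME.
    """
    frame = data.values if isinstance(data, OmicsMatrix) else data
    assignment = assignment.copy()
    while True:
        labels = sorted(int(m) for m in assignment.unique() if m != 0)
        if len(labels) < 2:
            break
        mes = module_eigengenes(frame, assignment)
        d = 1.0 - np.corrcoef(mes.to_numpy(), rowvar=False)
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        Z = linkage(squareform(d, checks=False), method="average")
        flat = fcluster(Z, t=merge_height, criterion="distance")
        if len(set(flat)) == len(labels):
            break
        mapping = {}
        for label, group in zip(labels, flat):
            mapping.setdefault(group, []).append(label)
        for group, merged in mapping.items():
            keep = merged[0]
            for other in merged[1:]:
                assignment[assignment == other] = keep
    assignment = _canonical_labels(assignment)
    mes = module_eigengenes(frame, assignment)
    kme = module_membership(frame, mes) if not mes.empty else pd.DataFrame(
        index=frame.columns)
    return ModuleSet(assignment=assignment, eigengenes=mes, kme=kme)


def detect_modules(data: OmicsMatrix | pd.DataFrame, power: int | None = None,
                   min_module_size: int = 5, merge_height: float = 0.25,
                   cut_height_quantile: float = 0.92,
                   r2_target: float = 0.85) -> tuple:
    """Full chain: (scan or fixed power) -> adjacency -> TOM -> modules.

    Returns ``(ModuleSet, SoftPowerScan | None)``.
    """
    scan = None
    if power is None:
        scan = select_soft_power(data, r2_target=r2_target)
        power = scan.selected_power
    adjacency = signed_adjacency(data, power)
    tom = topological_overlap(adjacency)
    assignment = cluster_modules(1.0 - tom, min_module_size=min_module_size,
                                 cut_height_quantile=cut_height_quantile)
    module_set = merge_close_modules(data, assignment, merge_height=merge_height)
    return module_set, scan


def preselect_transcripts(metabolites: OmicsMatrix | pd.DataFrame,
                          transcripts: OmicsMatrix | pd.DataFrame,
                          pheno: pd.DataFrame, p_threshold: float = 1e-5,
                          same_metabolite_both: bool = True) -> pd.Index:
    """Select transcripts with a suggestive metabolite association in both
    covariate models.

    Model A regresses each metabolite on the transcript plus age and sex;
    model B additionally adjusts for baseline body weight and the
    weight-change phenotype, to avoid selecting transcript–metabolite pairs
    whose association is driven by those variables.  A transcript is kept
    when some metabolite attains ``p < p_threshold`` for the transcript
    coefficient in both models (by default the *same* metabolite in both;
    ``same_metabolite_both=False`` relaxes to any metabolite per model).

    Transcripts are expected to be residualized on technical covariates
    beforehand (see :func:`modulome.association.adjust_technical`).
    """
    from scipy import stats

    met = metabolites.values if isinstance(metabolites, OmicsMatrix) else metabolites
    tr = transcripts.values if isinstance(transcripts, OmicsMatrix) else transcripts
    common = met.index.intersection(tr.index).intersection(pheno.index)
    met, tr = met.loc[common], tr.loc[common]
    n = len(common)

    designs = {
        "A": ["age", "sex"],
        "B": ["age", "sex", "weight_s4", "dbw"],
    }
    hits = {}
    for tag, cols in designs.items():
        C = np.column_stack([np.ones(n)] + [pheno.loc[common, c].to_numpy(float)
                                            for c in cols])
        k = C.shape[1]
        if n < k + 2:
            raise ValueError("too few samples for the preselection models")
        # residualize transcripts and metabolites on the covariates; the
        # t-test of the transcript coefficient equals the partial-correlation
        # test of (metabolite, transcript) given the covariates
        Q, _ = np.linalg.qr(C)
        Rt = tr.to_numpy(float) - Q @ (Q.T @ tr.to_numpy(float))
        Rm = met.to_numpy(float) - Q @ (Q.T @ met.to_numpy(float))
        Rt = Rt / np.sqrt((Rt**2).sum(axis=0))
        Rm = Rm / np.sqrt((Rm**2).sum(axis=0))
        pr = np.clip(Rt.T @ Rm, -1.0, 1.0)       # transcripts x metabolites
        df = n - k - 1
        tstat = pr * np.sqrt(df / np.maximum(1e-300, 1.0 - pr**2))
        pval = 2.0 * stats.t.sf(np.abs(tstat), df)
        hits[tag] = pval < p_threshold
    both = hits["A"] & hits["B"] if same_metabolite_both else None
    if same_metabolite_both:
        keep = both.any(axis=1)
    else:
        keep = hits["A"].any(axis=1) & hits["B"].any(axis=1)
    return tr.columns[keep]
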