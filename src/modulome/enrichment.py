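"""Pathway and term enrichment of detected modules.

Metabolite modules are tested with a weighted permutation statistic: for
pathway ``c`` and module ``m``,

    S_cm = sum of |kME_im| over metabolites annotated to c AND assigned to m

(metabolites outside the module carry zero weight).  The null is built by
permuting the pathway-label vector across all metabolites — unassigned
(label-0) metabolites keep zero weight but take part in the permutation —
and the permutation p-value is ``(1 + #{S_perm >= S_obs}) / (1 + n_perm)``
(the raw strict-greater count is reported alongside).

Gene (transcript) modules are tested with a one-sided Fisher exact test per
term set, after collapsing probes to genes by the largest |kME|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "weighted_enrichment", "fisher_term_enrichment"]


@dataclass
class EnrichmentResult:
    pathway_id: str
    module_id: int
    s_cm: float
    n_pathway: int
    n_in_module: int
    n_perm: int
    p_perm: float
    n_greater: int          # raw strict-greater count
    seed: int


def _module_weights(kme: pd.DataFrame, assignment: pd.Series, label: int,
                    signed: bool) -> np.ndarray:
    """Per-feature weight for module ``label``: |kME| (or kME) for its own
    members, 0 elsewhere."""
    w = np.zeros(len(assignment))
    members = assignment.to_numpy() == label
    col = kme.loc[assignment.index, f"ME{label}"].to_numpy(float)
    w[members] = col[members] if signed else np.abs(col[members])
    return w


def weighted_enrichment(kme: pd.DataFrame, assignment: pd.Series,
                        pathway_of: pd.Series, n_perm: int = 100_000,
                        seed: int = 0, signed: bool = False,
                        chunk: int = 5_000) -> pd.DataFrame:
    """Weighted permutation enrichment of every (pathway, module) pair.

    ``pathway_of`` maps feature id -> pathway label; every metabolite must
    carry a label ("unannotated" is a legal label).  Permutations shuffle
    the label vector over all metabolites with one seeded generator, so
    results are reproducible.  Implemented by permuting the (weight,
    assignment) pairs against the fixed label one-hot, in chunks, which is
    equivalent and vectorizes the 100,000 permutations.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    assignment = assignment.astype(int)
    missing = assignment.index.difference(pathway_of.index)
    if len(missing):
        raise ValueError(f"features without a pathway label: {list(missing[:5])}")
    labels = pathway_of.loc[assignment.index]
    pathways = sorted(labels.unique())
    onehot = np.column_stack([(labels == c).to_numpy(float) for c in pathways])
    counts = onehot.sum(axis=0).astype(int)
    module_labels = sorted(int(m) for m in assignment.unique() if m != 0)

    rng = np.random.default_rng(seed)
    rows = []
    nf = len(assignment)
    for label in module_labels:
        w = _module_weights(kme, assignment, label, signed)
        s_obs = w @ onehot                     # per pathway
        greater = np.zeros(len(pathways), dtype=np.int64)
        ge = np.zeros(len(pathways), dtype=np.int64)
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            perm = np.argsort(rng.random((b, nf)), axis=1)
            s_perm = w[perm] @ onehot          # b x pathways
            greater += (s_perm > s_obs + 1e-12).sum(axis=0)
            ge += (s_perm >= s_obs - 1e-12).sum(axis=0)
            done += b
        p = (1.0 + ge) / (1.0 + n_perm)
        n_members = int((assignment == label).sum())
        for c, pathway in enumerate(pathways):
            in_mod = int(((labels == pathway) & (assignment == label)).sum())
            rows.append(EnrichmentResult(
                pathway_id=str(pathway), module_id=label, s_cm=float(s_obs[c]),
                n_pathway=int(counts[c]), n_in_module=in_mod, n_perm=n_perm,
                p_perm=float(p[c]), n_greater=int(greater[c]), seed=seed,
            ))
    frame = pd.DataFrame([r.__dict__ for r in rows])
    return frame.sort_values(["module_id", "p_perm", "pathway_id"],
                             ignore_index=True)


def fisher_term_enrichment(module_features, term_sets: dict, universe,
                           collapse: dict | None = None,
                           kme: pd.Series | None = None) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of a module in each term set.

    ``collapse`` maps probe -> gene; when several probes map to one gene the
    probe with the largest |kME| represents it (``kme`` must then be given,
    indexed by probe).  Term sets are intersected with the universe; empty
    terms are skipped with a warning.  Returns a frame sorted by p with the
    2x2 counts and odds ratio.
    """
    universe = set(universe)
    module = set(module_features)
    if not module <= universe:
        raise ValueError("module features must be a subset of the universe")
    if collapse:
        best: dict = {}
        for probe in universe:
            gene = collapse.get(probe, probe)
            weight = abs(float(kme.loc[probe])) if kme is not None else 0.0
            if gene not in best or weight > best[gene][1]:
                best[gene] = (probe, weight)
        chosen = {probe for probe, _ in best.values()}
        module = {collapse.get(p, p) for p in module & chosen}
        universe = set(best.keys())
    if not universe:
        raise ValueError("empty universe")
    rows = []
    n_univ, n_mod = len(universe), len(module)
    for term, members in term_sets.items():
        members = set(members) & universe
        if not members:
            logger.warning("term %s has no members in the universe; skipped", term)
            continue
        a = len(module & members)
        b = n_mod - a
        c = len(members) - a
        d = n_univ - n_mod - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((term, a, len(members), n_mod, n_univ, float(odds), float(p)))
    frame = pd.DataFrame(rows, columns=["term", "n_overlap", "n_term",
                                        "n_module", "n_universe",
                                        "odds_ratio", "p"])
    return frame.sort_values(["p", "term"], ignore_index=True)
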