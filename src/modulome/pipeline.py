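"""End-to-end driver chaining every stage of the analysis.

Order: simulate/load -> sample exclusions -> metabolite preprocessing ->
multiple imputation -> metabolite module detection -> transcript
adjustment + preselection -> transcript module detection -> association
models (Rubin-pooled for the imputed metabolite layer) -> pathway
enrichment -> eigengene partial-correlation network -> connectivity
permutation tests.

Module detection needs complete data, so it runs on the cell-wise mean of
the completed datasets; eigengenes for the association layer are then
recomputed inside each completed dataset under the fixed assignment and the
per-dataset estimates pooled by Rubin's rules.

Every output table starts with a ``# config_hash=...`` comment line, and a
JSON manifest records versions, seeds, parameters, and per-stage sample and
feature accounting.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import comodule, enrichment, io, module_network, preprocess
from .config import PipelineConfig, config_hash
from .datatypes import OmicsMatrix
from .impute import ImputationSet, mice_impute
from .synthetic_data import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "eigengenes_per_dataset", "average_completed"]


def average_completed(imputations: ImputationSet) -> pd.DataFrame:
    """Cell-wise mean of the completed datasets (complete by construction)."""
    stack = np.stack([ds.values.to_numpy(float) for ds in imputations.datasets])
    first = imputations.datasets[0].values
    return pd.DataFrame(stack.mean(axis=0), index=first.index,
                        columns=first.columns)


def eigengenes_per_dataset(imputations: ImputationSet,
                           assignment: pd.Series) -> list:
    """Eigengenes recomputed inside each completed dataset (fixed assignment)."""
    return [comodule.module_eigengenes(ds.values, assignment)
            for ds in imputations.datasets]


def pooled_me_association(imputations: ImputationSet, assignment: pd.Series,
                          pheno: pd.DataFrame, covariates=assoc.BASE_COVARIATES,
                          n_tests: int | None = None) -> pd.DataFrame:
    """Fit the base model per completed dataset's eigengenes; Rubin-pool."""
    from .impute import pool_estimates

    per_me: dict = {}
    dfcom = None
    for mes in eigengenes_per_dataset(imputations, assignment):
        res = assoc.fit_me_association(mes, pheno, covariates)
        dfcom = len(mes) - (len(covariates) + 2)
        for _, row in res.iterrows():
            per_me.setdefault(row["target_id"], []).append(
                (row["effect"], row["se"]))
    n_tests = n_tests if n_tests is not None else len(per_me)
    threshold = assoc.bonferroni_threshold(0.05, max(n_tests, 1))
    rows = []
    for target, pairs in per_me.items():
        pooled = pool_estimates(pairs, dfcom=dfcom)
        rows.append((target, pooled.estimate, pooled.se, pooled.statistic,
                     pooled.p, n_tests, threshold, pooled.p < threshold, True))
    return pd.DataFrame(rows, columns=assoc.RESULT_COLUMNS)


def _write_table(frame: pd.DataFrame, path: Path, chash: str,
                 index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        frame.to_csv(fh, sep="\t", na_rep="NA", float_format=io.FLOAT_FORMAT,
                     index=index_label is not None, index_label=index_label)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured pipeline; returns the run directory."""
    config.validate()
    chash = config_hash(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": chash,
        "config": config.to_dict(),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": [],
    }

    def account(stage, **info):
        manifest["stages"].append({"stage": stage, **info})
        logger.info("stage %s: %s", stage, info)

    try:
        # ---- inputs ----------------------------------------------------
        if config.metabolites_path is None:
            spec = CohortSpec(**{"seed": config.seed_simulate, **config.cohort})
            pheno, metab, transcripts, truth = generate_cohort(spec)
            io.write_ground_truth(truth, out / "ground_truth.tsv")
            account("simulate", n_samples=metab.n_samples,
                    n_metabolites=metab.n_features,
                    n_transcripts=transcripts.n_features)
        else:
            ann = (io.read_annotation(config.metabolites_path + ".annotation")
                   if Path(str(config.metabolites_path) + ".annotation").exists()
                   else None)
            metab = io.read_matrix(config.metabolites_path, annotation=ann)
            pheno = io.read_phenotype(config.phenotype_path)
            transcripts = (io.read_matrix(config.transcripts_path)
                           if config.transcripts_path else None)
            account("load", n_samples=metab.n_samples,
                    n_metabolites=metab.n_features)
        _write_table(pheno, out / "phenotype_input.tsv", chash, "sample_id")
        _write_table(metab.values, out / "metabolites_input.tsv", chash,
                     "sample_id")

        # ---- sample exclusions -----------------------------------------
        n_in = len(pheno)
        pheno, dropped = preprocess.exclude_samples(
            pheno, config.min_fasting_h, config.dbw_sd_limit)
        metab = metab.subset(samples=pheno.index)
        if transcripts is not None:
            transcripts = transcripts.subset(
                samples=pheno.index.intersection(transcripts.sample_ids))
        _write_table(dropped, out / "excluded_samples.tsv", chash)
        account("exclude_samples", samples_in=n_in, samples_out=len(pheno),
                dropped=len(dropped))

        # ---- preprocessing ---------------------------------------------
        if config.run_preprocess:
            metab, report = preprocess.preprocess_metabolites(
                metab, pheno, outlier_k=config.outlier_k,
                feature_max=config.feature_max_missing,
                sample_max=config.sample_max_missing)
            pheno = pheno.loc[metab.sample_ids]
            if report.day_median_cv is not None:
                _write_table(report.day_median_cv.to_frame(),
                             out / "day_median_cv.tsv", chash, "feature_id")
            _write_table(report.dropped_features, out / "dropped_features.tsv",
                         chash)
            _write_table(report.dropped_samples, out / "dropped_samples.tsv",
                         chash)
            account("preprocess", n_features=metab.n_features,
                    n_samples=metab.n_samples,
                    n_outliers_masked=report.n_outliers_masked,
                    dropped_features=len(report.dropped_features),
                    dropped_samples=len(report.dropped_samples))

        # ---- imputation ------------------------------------------------
        if config.run_impute and not metab.is_complete():
            imputations = mice_impute(metab, pheno, m=config.m,
                                      n_iterations=config.n_iterations,
                                      seed=config.seed_impute)
            _write_table(imputations.trace, out / "imputation_trace.tsv", chash)
            complete = average_completed(imputations)
            account("impute", m=config.m, n_iterations=config.n_iterations,
                    n_missing=int(metab.values.isna().sum().sum()))
        else:
            imputations = None
            complete = metab.values
            account("impute", skipped=True)

        # ---- metabolite modules ----------------------------------------
        mset, scan = comodule.detect_modules(
            complete, power=config.power_metabolite,
            min_module_size=config.min_module_size,
            merge_height=config.merge_height,
            cut_height_quantile=config.cut_height_quantile)
        _write_table(mset.assignment.to_frame(), out / "metabolite_modules.tsv",
                     chash, "feature_id")
        _write_table(mset.eigengenes, out / "metabolite_eigengenes.tsv", chash,
                     "sample_id")
        _write_table(mset.kme, out / "metabolite_kme.tsv", chash, "feature_id")
        if scan is not None:
            _write_table(pd.DataFrame({"fit_r2": scan.fit_r2,
                                       "mean_connectivity": scan.mean_connectivity}),
                         out / "soft_power_scan_metabolites.tsv", chash, "power")
        account("modules_metabolites",
                power=scan.selected_power if scan else config.power_metabolite,
                n_modules=len(mset.module_labels),
                n_assigned=int((mset.assignment != 0).sum()))

        # ---- transcript layer ------------------------------------------
        tset = None
        if config.run_transcripts and transcripts is not None \
                and transcripts.n_features >= 2:
            tech_cols = [c for c in pheno.columns if c.startswith("tech_")]
            tvals = transcripts.values.loc[
                transcripts.sample_ids.intersection(pheno.index)]
            if tech_cols:
                tvals = assoc.adjust_technical(tvals, pheno[tech_cols])
            met_for_sel = complete.loc[tvals.index]
            selected = comodule.preselect_transcripts(
                met_for_sel, tvals, pheno, p_threshold=config.preselect_p)
            account("preselect_transcripts", n_in=tvals.shape[1],
                    n_selected=len(selected))
            if len(selected) >= max(config.min_module_size, 20):
                tset, tscan = comodule.detect_modules(
                    tvals[list(selected)], power=config.power_transcript,
                    min_module_size=config.min_module_size,
                    merge_height=config.merge_height,
                    cut_height_quantile=config.cut_height_quantile)
                tset.eigengenes.columns = [
                    c.replace("ME", "GenME") for c in tset.eigengenes.columns]
                _write_table(tset.assignment.to_frame(),
                             out / "transcript_modules.tsv", chash, "feature_id")
                _write_table(tset.eigengenes, out / "transcript_eigengenes.tsv",
                             chash, "sample_id")
                account("modules_transcripts", n_modules=len(tset.module_labels))
            else:
                logger.warning("too few preselected transcripts for modules")

        # ---- association -----------------------------------------------
        n_total_modules = len(mset.module_labels) + (
            len(tset.module_labels) if tset is not None else 0)
        if imputations is not None:
            res_met = pooled_me_association(imputations, mset.assignment, pheno,
                                            n_tests=n_total_modules)
        else:
            res_met = assoc.fit_me_association(mset.eigengenes, pheno)
            res_met["n_tests"] = n_total_modules
            res_met["bonferroni_threshold"] = assoc.bonferroni_threshold(
                0.05, max(n_total_modules, 1))
            res_met["significant"] = res_met["p"] < res_met["bonferroni_threshold"]
        results = [res_met.assign(model="base_metabolite")]
        if tset is not None and len(tset.module_labels) > 0:
            sub = pheno.loc[tset.eigengenes.index]
            res_tr = assoc.fit_me_association(tset.eigengenes, sub)
            res_tr["n_tests"] = n_total_modules
            res_tr["bonferroni_threshold"] = assoc.bonferroni_threshold(
                0.05, max(n_total_modules, 1))
            res_tr["significant"] = res_tr["p"] < res_tr["bonferroni_threshold"]
            results.append(res_tr.assign(model="base_transcript"))
        association_table = pd.concat(results, ignore_index=True)
        _write_table(association_table, out / "association.tsv", chash)
        account("associate", n_tests=n_total_modules,
                n_significant=int(association_table["significant"].sum()))

        # ---- enrichment ------------------------------------------------
        if config.run_enrichment and len(mset.module_labels) > 0:
            for level in ("super_pathway", "sub_pathway"):
                pathway_of = metab.annotation[level].replace(
                    "", "unannotated").astype(str)
                enr = enrichment.weighted_enrichment(
                    mset.kme, mset.assignment, pathway_of,
                    n_perm=config.n_perm_enrichment, seed=config.seed_enrichment)
                _write_table(enr, out / f"enrichment_{level}.tsv", chash)
            account("enrich", n_perm=config.n_perm_enrichment)

        # ---- network ----------------------------------------------------
        all_me = mset.eigengenes
        layer_of = {c: "metabolite" for c in mset.eigengenes.columns}
        if tset is not None and len(tset.module_labels) > 0:
            aligned = tset.eigengenes.reindex(all_me.index).dropna()
            if len(aligned) == len(all_me):
                all_me = pd.concat([all_me, aligned], axis=1)
                layer_of.update({c: "transcript" for c in aligned.columns})
        if config.run_network and all_me.shape[1] >= 3:
            net = module_network.partial_correlation_network(
                all_me, pheno, strong=config.edge_strong, weak=config.edge_weak,
                marginal_min=config.marginal_min, layer_of=layer_of)
            _write_table(net.edges, out / "network_edges.tsv", chash)
            import networkx as nx

            nx.write_graphml(net.to_networkx(), out / "network.graphml")
            account("network", n_edges=int(net.edges["drawn"].sum()))

        # ---- connectivity -----------------------------------------------
        if config.run_connectivity and len(mset.module_labels) > 0:
            flag = pheno[config.connectivity_group]
            conn = []
            for kind in ("intra", "inter"):
                if kind == "inter" and len(mset.module_labels) < 2:
                    continue
                conn.append(module_network.connectivity_permutation_test(
                    complete, mset, flag, kind=kind,
                    n_perm=config.n_perm_connectivity,
                    seed=config.seed_connectivity))
            conn_table = pd.concat(conn, ignore_index=True)
            _write_table(conn_table, out / "connectivity.tsv", chash)
            account("connectivity", n_perm=config.n_perm_connectivity)
    except Exception as exc:
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "setup"
        manifest["failed_after_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out
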