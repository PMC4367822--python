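"""Synthetic multi-omic weight-change cohorts with planted structure.

The generator emulates the statistical skeleton of a population cohort with
two-platform serum metabolomics and blood transcriptomics measured at
follow-up, and an annual percentage body-weight-change phenotype:

* metabolite modules are latent-factor blocks: feature ``i`` in module ``m``
  equals ``sqrt(w) * L_m + sqrt(1 - w) * eps_i`` on the log10 scale, where
  ``w`` is the within-module correlation, so every within-module pair has
  population correlation exactly ``w``;
* for associated modules the latent is ``a * z(dbw) + sqrt(1 - a^2) * eta``
  with standardized slope ``a`` per unit weight change, unit variance either
  way; signs alternate across associated modules;
* transcripts mix a module latent with weight ``transcript_link_strength``;
* run-day batch effects are multiplicative per (day, feature) lognormal
  factors on the concentration scale;
* missingness is MCAR plus per-feature left-censoring (the lowest-rank
  values are masked, a scale-free stand-in for detection limits).

Everything is driven by one :class:`numpy.random.Generator` seeded from
``spec.seed``: identical spec and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, GroundTruth, OmicsMatrix, default_annotation

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "inject_batch_effects",
    "inject_missingness",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort; defaults are the reference cohort.

    Units: ``dbw_mean``/``dbw_sd`` are percent body weight per year;
    ``batch_sd`` is the SD of the per-(day, feature) batch factor on the
    log10 scale; ``assoc_effect`` is a standardized slope per unit dbw.
    """

    n_samples: int = 200
    n_metabolites: int = 100
    n_transcripts: int = 60
    n_modules: int = 4
    module_sizes: tuple = (15, 15, 15, 15)
    within_module_cor: float = 0.7
    n_assoc_modules: int = 2
    assoc_effect: float = 0.5
    dbw_mean: float = 0.3
    dbw_sd: float = 1.0
    n_run_days: int = 10
    batch_sd: float = 0.2
    mcar_rate: float = 0.03
    censor_rate: float = 0.07
    transcript_link_strength: float = 0.5
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "module_sizes", tuple(self.module_sizes))
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if len(self.module_sizes) != self.n_modules:
            raise ConfigurationError(
                "module_sizes must list exactly n_modules entries"
            )
        if sum(self.module_sizes) > self.n_metabolites:
            raise ConfigurationError(
                "module_sizes: sum exceeds n_metabolites"
            )
        if not (0.0 < self.within_module_cor <= 1.0):
            raise ConfigurationError("within_module_cor must be in (0, 1]")
        if self.n_assoc_modules > self.n_modules:
            raise ConfigurationError("n_assoc_modules exceeds n_modules")
        for name in ("mcar_rate", "censor_rate", "transcript_link_strength"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1)")
        if self.mcar_rate + self.censor_rate >= 1.0:
            raise ConfigurationError("mcar_rate + censor_rate must be < 1")
        if self.n_run_days < 1:
            raise ConfigurationError("n_run_days must be >= 1")
        if self.n_run_days > self.n_samples:
            raise ConfigurationError("n_run_days exceeds n_samples")
        if self.batch_sd < 0 or self.dbw_sd <= 0:
            raise ConfigurationError("batch_sd must be >= 0 and dbw_sd > 0")

    def replace(self, **kwargs) -> "CohortSpec":
        return dataclasses.replace(self, **kwargs)


def _signed_effects(spec: CohortSpec) -> dict:
    """Module label -> planted signed standardized effect (alternating sign)."""
    return {
        m + 1: spec.assoc_effect * (1 if m % 2 == 0 else -1)
        for m in range(spec.n_assoc_modules)
    }


def _generate_phenotype(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_samples
    sample_ids = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample_id")
    age = np.round(rng.normal(61.0, 9.0, n)).clip(25, 90)
    sex = rng.integers(0, 2, n)  # 0/1, reference level 0
    height = rng.normal(1.68, 0.09, n).clip(1.40, 2.05)
    weight_s4 = rng.normal(76.0, 13.0, n).clip(42.0, None)
    followup_years = rng.normal(7.0, 0.25, n).clip(5.5, 8.5)
    dbw = rng.normal(spec.dbw_mean, spec.dbw_sd, n)
    weight_f4 = weight_s4 * (1.0 + dbw * followup_years / 100.0)
    fasting_h = rng.uniform(8.0, 14.0, n)
    bmi = weight_s4 / height**2
    whr = rng.normal(0.90, 0.08, n)

    pheno = pd.DataFrame(
        {
            "weight_s4": weight_s4,
            "weight_f4": weight_f4,
            "followup_years": followup_years,
            "dbw": dbw,
            "age": age,
            "sex": sex,
            "fasting_h": fasting_h,
            "bmi": bmi,
            "whr": whr,
            # subgroup flags
            "grp_weight_gain": (dbw >= 0).astype(int),
            "grp_obese": (bmi > 30).astype(int),
            "grp_central_obese": (whr > 0.90).astype(int),
            "grp_older": (age > 55).astype(int),
            # change-covariate blocks (independent of dbw by default)
            "lifestyle_smoking_change": rng.integers(0, 2, n),
            "lifestyle_activity_change": rng.normal(0, 1, n),
            "incident_diabetes": rng.binomial(1, 0.06, n),
            "incident_cvd": rng.binomial(1, 0.05, n),
            "medication_change_lipid": rng.binomial(1, 0.10, n),
            "medication_change_antihyp": rng.binomial(1, 0.15, n),
            # medication covariates for clinical-trait models
            "med_lipid": rng.binomial(1, 0.15, n),
            "med_statin": rng.binomial(1, 0.12, n),
            "med_fibrate": rng.binomial(1, 0.03, n),
            "med_antihyp": rng.binomial(1, 0.30, n),
            "med_antidiab": rng.binomial(1, 0.08, n),
            "med_corticoid": rng.binomial(1, 0.04, n),
            # clinical traits (null by default: independent of the omics)
            "trait_hdl": np.exp(rng.normal(np.log(1.4), 0.25, n)),
            "trait_ldl": np.exp(rng.normal(np.log(3.5), 0.25, n)),
            "trait_fglc": np.exp(rng.normal(np.log(5.5), 0.12, n)),
            "trait_2hglc": np.exp(rng.normal(np.log(6.5), 0.25, n)),
            "trait_hba1c": np.exp(rng.normal(np.log(5.5), 0.08, n)),
            "trait_sbp": np.exp(rng.normal(np.log(130.0), 0.13, n)),
            "trait_dbp": np.exp(rng.normal(np.log(80.0), 0.12, n)),
            "trait_crp": np.exp(rng.normal(np.log(1.5), 0.9, n)),
            "trait_mets": rng.binomial(1, 0.25, n),
            "trait_mi": rng.binomial(1, 0.05, n),
            "trait_stroke": rng.binomial(1, 0.04, n),
        },
        index=sample_ids,
    )
    pheno["run_day"] = np.arange(n) % spec.n_run_days + 1
    return pheno


def generate_cohort(spec: CohortSpec):
    """Generate one cohort: (phenotype, metabolites, transcripts, truth).

    The metabolite matrix is on the raw concentration scale (``10**log10``)
    with batch effects and missingness already injected according to the
    spec; the transcript matrix is on the (already normalized) expression
    scale and left complete, mirroring array data.  The returned
    :class:`GroundTruth` retains clean and complete matrices, the planted
    assignment and effects, and the pathway map aligned to the modules.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    pheno = _generate_phenotype(spec, rng)
    n = spec.n_samples
    z_dbw = (pheno["dbw"].to_numpy() - spec.dbw_mean) / spec.dbw_sd

    # module latents, unit variance
    effects = _signed_effects(spec)
    latents = np.empty((n, spec.n_modules))
    for m in range(spec.n_modules):
        label = m + 1
        eta = rng.normal(0.0, 1.0, n)
        if label in effects:
            a = effects[label]
            latents[:, m] = a * z_dbw + np.sqrt(max(0.0, 1.0 - a * a)) * eta
        else:
            latents[:, m] = eta

    # metabolites: block members then noise features, on log10 scale
    w = spec.within_module_cor
    met_ids, assignment, log_values = [], [], []
    for m in range(spec.n_modules):
        for j in range(spec.module_sizes[m]):
            met_ids.append(f"MET{len(met_ids) + 1:03d}")
            assignment.append(m + 1)
            eps = rng.normal(0.0, 1.0, n)
            log_values.append(np.sqrt(w) * latents[:, m] + np.sqrt(1.0 - w) * eps)
    n_noise = spec.n_metabolites - sum(spec.module_sizes)
    for j in range(n_noise):
        met_ids.append(f"MET{len(met_ids) + 1:03d}")
        assignment.append(0)
        log_values.append(rng.normal(0.0, 1.0, n))
    met_log = pd.DataFrame(
        np.column_stack(log_values), index=pheno.index,
        columns=pd.Index(met_ids, name="feature_id"),
    )
    met_assignment = pd.Series(assignment, index=met_log.columns, name="module")

    # pathway map aligned with the planted modules; noise features spread
    # over their own pathways so label permutation has something to permute
    annotation = default_annotation(met_log.columns, platform="M")
    super_pw = np.where(
        met_assignment > 0,
        [f"SP_module{m}" for m in met_assignment],
        [f"SP_noise{(i % 4) + 1}" for i in range(len(met_assignment))],
    )
    sub_pw = np.where(
        met_assignment > 0,
        [f"SUB_module{m}" for m in met_assignment],
        [f"SUB_noise{(i % 8) + 1}" for i in range(len(met_assignment))],
    )
    annotation["super_pathway"] = super_pw
    annotation["sub_pathway"] = sub_pw
    # tag half the metabolites as NMR to emulate the two platforms
    annotation.loc[annotation.index[1::2], "platform"] = "N"

    metab = OmicsMatrix(10.0 ** met_log, annotation)
    clean_values = metab.values.copy()

    # transcripts: round-robin over module latents, normal scale
    link = spec.transcript_link_strength
    tr_ids = [f"TR{j + 1:03d}" for j in range(spec.n_transcripts)]
    tr_assignment, tr_values = [], []
    for j in range(spec.n_transcripts):
        m = j % spec.n_modules if link > 0 else -1
        eps = rng.normal(0.0, 1.0, n)
        if m >= 0:
            tr_values.append(np.sqrt(link) * latents[:, m] + np.sqrt(1 - link) * eps)
            tr_assignment.append(m + 1)
        else:
            tr_values.append(eps)
            tr_assignment.append(0)
    tr_frame = pd.DataFrame(
        np.column_stack(tr_values) if tr_values else np.empty((n, 0)),
        index=pheno.index, columns=pd.Index(tr_ids, name="feature_id"),
    )
    tr_annotation = default_annotation(tr_frame.columns, platform="T")
    tr_annotation["sub_pathway"] = [f"GENE{j + 1:03d}" for j in range(spec.n_transcripts)]
    transcripts = OmicsMatrix(tr_frame, tr_annotation)

    truth = GroundTruth(
        module_assignment=met_assignment,
        assoc_effects=effects,
        pathway_map=annotation[["super_pathway", "sub_pathway"]].copy(),
        batch_factors=None,
        clean_values=clean_values,
        transcript_assignment=pd.Series(tr_assignment, index=tr_frame.columns,
                                        name="module"),
        latents=pd.DataFrame(latents, index=pheno.index,
                             columns=[f"L{m + 1}" for m in range(spec.n_modules)]),
    )

    if spec.batch_sd > 0 and spec.n_run_days > 1:
        metab, factors = inject_batch_effects(
            metab, spec.n_run_days, spec.batch_sd,
            seed=int(rng.integers(2**31)), pheno=pheno,
        )
        truth.batch_factors = factors
    truth.complete_values = metab.values.copy()

    if spec.mcar_rate > 0 or spec.censor_rate > 0:
        metab, censored, mcar = inject_missingness(
            metab, spec.mcar_rate, spec.censor_rate, seed=int(rng.integers(2**31))
        )
        truth.censored_cells = censored
        truth.mcar_cells = mcar

    return pheno, metab, transcripts, truth


def inject_batch_effects(matrix: OmicsMatrix, n_run_days: int, batch_sd: float,
                         seed: int, pheno: pd.DataFrame | None = None):
    """Multiply each cell by a per-(run day, feature) lognormal factor.

    Samples are assigned to days round-robin; the factor is
    ``10**Normal(0, batch_sd)``.  Returns the perturbed matrix and the
    day x feature factor table.  If ``pheno`` is given its ``run_day``
    column is (re)written in place.
    """
    if n_run_days < 1:
        raise ConfigurationError("n_run_days must be >= 1")
    if n_run_days > matrix.n_samples:
        raise ConfigurationError("n_run_days exceeds number of samples")
    rng = np.random.default_rng(seed)
    days = np.arange(matrix.n_samples) % n_run_days + 1
    factors = pd.DataFrame(
        10.0 ** rng.normal(0.0, batch_sd, (n_run_days, matrix.n_features)),
        index=pd.Index(np.arange(1, n_run_days + 1), name="run_day"),
        columns=matrix.feature_ids,
    )
    values = matrix.values * factors.to_numpy()[days - 1, :]
    if pheno is not None:
        pheno["run_day"] = days
    return OmicsMatrix(values, matrix.annotation.copy()), factors


def inject_missingness(matrix: OmicsMatrix, mcar_rate: float, censor_rate: float,
                       seed: int):
    """Mask cells: per-feature left-censoring first, then MCAR.

    Censoring masks, for each feature, the ``floor(censor_rate * n_samples)``
    lowest observed values (rank-based, hence scale-free); MCAR then masks
    each remaining observed cell independently with probability
    ``mcar_rate``.  Returns ``(matrix, censored_cells, mcar_cells)`` with
    cells as (sample_id, feature_id) pairs.
    """
    for name, rate in (("mcar_rate", mcar_rate), ("censor_rate", censor_rate)):
        if not (0.0 <= rate < 1.0):
            raise ConfigurationError(f"{name} must be in [0, 1)")
    if mcar_rate + censor_rate >= 1.0:
        raise ConfigurationError("combined missingness must be < 1 per feature")
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    arr = values.to_numpy()
    n, p = arr.shape
    censored, mcar = [], []

    n_censor = int(np.floor(censor_rate * n))
    if n_censor > 0:
        order = np.argsort(arr, axis=0, kind="stable")
        for j in range(p):
            rows = order[:n_censor, j]
            for i in rows:
                censored.append((values.index[i], values.columns[j]))
            arr[rows, j] = np.nan
    if mcar_rate > 0:
        hit = rng.random((n, p)) < mcar_rate
        hit &= ~np.isnan(arr)
        for i, j in zip(*np.nonzero(hit)):
            mcar.append((values.index[i], values.columns[j]))
        arr[hit] = np.nan
    values.iloc[:, :] = arr
    return OmicsMatrix(values, matrix.annotation.copy()), censored, mcar
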