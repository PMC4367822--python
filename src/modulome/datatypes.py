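"""Core in-memory containers shared by all pipeline stages.

The package works on three tables:

* an :class:`OmicsMatrix` — a samples x features numeric matrix with an
  explicit missing mask (NaN-backed) and per-feature annotation
  (platform tag, super-/sub-pathway or gene symbol);
* a phenotype table — a plain :class:`pandas.DataFrame` keyed by sample id
  with the clinical record (two weight measurements, follow-up years, the
  derived annual percentage weight change ``dbw``, age, sex, run day, ...);
* a :class:`ModuleSet` — the output of module detection (assignment,
  eigengenes, membership), defined in :mod:`modulome.comodule`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: platform tags: M = MS metabolomics, N = NMR metabolomics, T = transcript
PLATFORMS = ("M", "N", "T")

ANNOTATION_COLUMNS = ("platform", "super_pathway", "sub_pathway", "display_name")


class ConfigurationError(ValueError):
    """An invalid parameter or specification field, named in the message."""


@dataclass
class OmicsMatrix:
    """Samples x features matrix with missing mask and feature annotation.

    ``values`` holds floats with ``NaN`` marking missing cells; the boolean
    ``missing_mask`` view is derived from it, so mask and values can never
    disagree.  ``annotation`` is indexed by feature id and carries at least
    the columns in :data:`ANNOTATION_COLUMNS`.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids in OmicsMatrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature ids in OmicsMatrix")
        if self.annotation is None:
            self.annotation = default_annotation(self.values.columns)
        else:
            missing = self.values.columns.difference(self.annotation.index)
            if len(missing):
                raise ValueError(
                    f"annotation does not cover features: {list(missing[:5])}"
                )
            self.annotation = self.annotation.loc[self.values.columns]

    # -- basic views ---------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean samples x features frame, True where the value is missing."""
        return self.values.isna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        return not bool(self.values.isna().any().any())

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.values.copy(), self.annotation.copy())

    def subset(self, samples=None, features=None) -> "OmicsMatrix":
        """Return a new matrix restricted to the given ids (order preserved)."""
        values = self.values
        if samples is not None:
            values = values.loc[samples]
        if features is not None:
            values = values[features]
        return OmicsMatrix(values.copy(), self.annotation.loc[values.columns].copy())


def default_annotation(feature_ids, platform: str = "M") -> pd.DataFrame:
    """Minimal annotation frame (empty pathways) for bare matrices."""
    return pd.DataFrame(
        {
            "platform": platform,
            "super_pathway": "",
            "sub_pathway": "",
            "display_name": list(feature_ids),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )


#: phenotype columns every stage may rely on
PHENOTYPE_CORE_COLUMNS = (
    "weight_s4",
    "weight_f4",
    "followup_years",
    "dbw",
    "age",
    "sex",
    "run_day",
    "fasting_h",
)


def validate_phenotype(pheno: pd.DataFrame, required=PHENOTYPE_CORE_COLUMNS) -> None:
    """Raise ``ValueError`` naming any missing required phenotype column."""
    missing = [c for c in required if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks required columns: {missing}")
    if pheno.index.has_duplicates:
        raise ValueError("duplicate sample ids in phenotype table")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort, for recovery tests.

    ``module_assignment`` maps every feature to a module label (0 = noise
    feature); ``assoc_effects`` maps associated module labels to their signed
    standardized effect per unit weight change; ``censored_cells`` and
    ``mcar_cells`` are lists of (sample_id, feature_id) pairs;
    ``batch_factors`` holds the per-(run day, feature) multiplicative factor;
    ``clean_values``/``complete_values`` retain the matrices before
    missingness was injected (before/after batch effects).
    """

    module_assignment: pd.Series
    assoc_effects: dict = field(default_factory=dict)
    pathway_map: pd.DataFrame = None
    censored_cells: list = field(default_factory=list)
    mcar_cells: list = field(default_factory=list)
    batch_factors: pd.DataFrame = None
    clean_values: pd.DataFrame = None
    complete_values: pd.DataFrame = None
    transcript_assignment: pd.Series = None
    latents: pd.DataFrame = None
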