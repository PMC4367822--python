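"""Pipeline configuration: one plain-text (YAML) file, strict keys,
explicit seeds for every stochastic stage.

``PipelineConfig.replay`` carries the original analysis defaults so a
configuration can bypass data-driven parameter selection: soft powers 13
(metabolite network) and 8 (transcript network), minimum module size 5,
module-merge height 0.25, 20 imputed datasets x 10 iterations, 100,000
enrichment permutations, and the transcript preselection threshold 1e-5.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .datatypes import ConfigurationError

__all__ = ["PipelineConfig", "ReplayDefaults", "load_config", "config_hash"]


@dataclass(frozen=True)
class ReplayDefaults:
    power_metabolite: int = 13
    power_transcript: int = 8
    min_module_size: int = 5
    merge_height: float = 0.25
    m: int = 20
    iterations: int = 10
    n_perm: int = 100_000
    preselect_p: float = 1e-5


@dataclass
class PipelineConfig:
    # --- cohort / inputs ------------------------------------------------
    out_dir: str = "run"
    metabolites_path: str | None = None     # None -> simulate
    transcripts_path: str | None = None
    phenotype_path: str | None = None
    cohort: dict = field(default_factory=dict)   # CohortSpec overrides
    # --- stage toggles --------------------------------------------------
    run_preprocess: bool = True
    run_impute: bool = True
    run_transcripts: bool = True
    run_enrichment: bool = True
    run_network: bool = True
    run_connectivity: bool = True
    # --- stage parameters ----------------------------------------------
    outlier_k: float = 4.0
    feature_max_missing: float = 0.5
    sample_max_missing: float = 0.2
    min_fasting_h: float = 8.0
    dbw_sd_limit: float = 5.0
    m: int = 20
    n_iterations: int = 10
    power_metabolite: int | None = None     # None -> scale-free scan
    power_transcript: int | None = None
    min_module_size: int = 5
    merge_height: float = 0.25
    cut_height_quantile: float = 0.92
    preselect_p: float = 1e-5
    n_perm_enrichment: int = 100_000
    n_perm_connectivity: int = 10_000
    connectivity_group: str = "grp_weight_gain"
    marginal_min: float = 0.05
    edge_strong: float = 0.1
    edge_weak: float = 0.05
    # --- seeds (every stochastic stage must have one) -------------------
    seed_simulate: int | None = None
    seed_impute: int | None = None
    seed_enrichment: int | None = None
    seed_connectivity: int | None = None
    replay: ReplayDefaults = field(default_factory=ReplayDefaults)

    STOCHASTIC_SEEDS = ("seed_simulate", "seed_impute", "seed_enrichment",
                        "seed_connectivity")

    def validate(self) -> None:
        for name in self.STOCHASTIC_SEEDS:
            if getattr(self, name) is None:
                raise ConfigurationError(
                    f"{name} is required: every stochastic stage needs an "
                    "explicit seed")
        if self.m < 1 or self.n_iterations < 1:
            raise ConfigurationError("m and n_iterations must be >= 1")
        if self.n_perm_enrichment < 100:
            raise ConfigurationError("n_perm_enrichment must be >= 100")

    def use_replay_powers(self) -> None:
        """Adopt the recorded soft powers instead of scanning."""
        self.power_metabolite = self.replay.power_metabolite
        self.power_transcript = self.replay.power_transcript

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["replay"] = dataclasses.asdict(self.replay)
        return d


def load_config(path) -> PipelineConfig:
    """Load YAML into a :class:`PipelineConfig`; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    replay = raw.pop("replay", None)
    cfg = PipelineConfig(**raw)
    if replay:
        known_r = {f.name for f in fields(ReplayDefaults)}
        unknown_r = set(replay) - known_r
        if unknown_r:
            raise ConfigurationError(f"unknown replay keys: {sorted(unknown_r)}")
        cfg.replay = ReplayDefaults(**replay)
    return cfg


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the analysis configuration.

    The output directory is excluded: two runs of the same analysis into
    different locations carry the same hash (and identical result tables).
    """
    payload = config.to_dict()
    payload.pop("out_dir", None)
    blob = yaml.safe_dump(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
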