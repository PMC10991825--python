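"""Structured pipeline configuration with YAML round-trip and seed derivation.

Every stage parameter lives here with a default equal to the published
workflow setting (BMR = 1 control SD, filter thresholds p > 0.001 and
BMDU/BMDL <= 40, BMC <= 50 µM, GSEA permutation seed 149 with q < 0.1,
free fraction from the equilibrium mass balance, 3 000 virtual individuals,
CES 0.05, 200 bootstrap replicates, 90% confidence, UF 3.16).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "BMCConfig",
    "GSEAConfig",
    "MassBalanceConfig",
    "QIVIVEConfig",
    "HBGVConfig",
    "SyntheticConfig",
    "PipelineConfig",
    "stage_seed",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed from the global seed.

    Uses a stable hash (SHA-256) of ``"<seed>:<stage>"`` truncated below
    2**31 so each stage is independently reproducible and independent of
    Python's randomized ``hash``.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class BMCConfig:
    """Per-gene benchmark-concentration modelling settings."""

    bmr_type: str = "1sd"           # BMR = 1 control standard deviation
    fit_p_min: float = 0.001        # keep genes with lack-of-fit p > this
    max_bmdu_bmdl_ratio: float = 40.0
    max_bmc: float = 50.0           # µM; highest retained nominal conc
    n_boot: int = 200
    confidence_level: float = 0.90  # two-sided bootstrap interval
    n_starts: int = 6               # multi-start NLS grid size


@dataclass
class GSEAConfig:
    """Pre-ranked gene set enrichment settings (GSEA defaults)."""

    weight: float = 1.0
    n_perm: int = 1000
    min_set_size: int = 15
    max_set_size: int = 500
    q_threshold: float = 0.1
    seed: int = 149                 # fixed permutation seed of the workflow


@dataclass
class MassBalanceConfig:
    """Sub-model constants of the equilibrium in vitro fate model.

    Grouped here so the partitioning regressions can be recalibrated
    without touching code.
    """

    ion_logkow_offset: float = -3.5      # ionic D_OW penalty, log10 units
    protein_slope: float = 0.71          # log K_protein-w regression on logD_OW
    protein_intercept: float = 0.42
    ion_albumin_offset: float = -1.15    # ionic albumin binding vs neutral
    plastic_slope: float = 0.97          # log K_plastic-w on log KOW,N (L/m²)
    plastic_intercept: float = -6.94
    report_decimals: int = 2             # rounding of reported free concs


@dataclass
class QIVIVEConfig:
    """Virtual population and reverse-dosimetry settings."""

    population_size: int = 3000
    cv_anatomical: float = 0.20
    cv_chemical: float = 0.30
    truncate_sd: float = 3.0            # lognormal truncation, log-scale SDs
    inverse_method: str = "bisection"   # or "abc"
    inverse_rtol: float = 1e-3          # 0.1% relative on the target conc
    abc_epsilon: float = 0.05
    abc_n_samples: int = 2000
    target_output: str = "liver_efferent_free"  # or "venous_free"


@dataclass
class HBGVConfig:
    """Final model-averaged benchmark-dose / TDI settings."""

    ces: float = 0.05
    n_boot: int = 200
    confidence_level: float = 0.90
    aic_window: float = 2.0
    uf: float = 3.16


@dataclass
class SyntheticConfig:
    """Synthetic data-generation defaults mirroring the study design."""

    n_genes: int = 300
    concentrations: list[float] = field(
        default_factory=lambda: [0.0, 0.02, 0.1, 0.2, 1.0, 2.0, 10.0, 20.0, 50.0]
    )
    n_replicates: int = 3
    responsive_fraction: float = 0.14
    noise_sd: float = 0.15          # log2 units
    effect_size: float = 1.0        # log2 units
    n_sets: int = 20
    set_size_range: tuple[int, int] = (15, 50)
    enriched_sets: int = 2


@dataclass
class PipelineConfig:
    """Bundle of all stage configurations plus global seed and output dir."""

    seed: int = 1
    out_dir: str = "results"
    exclude_cytotoxic: list[float] = field(default_factory=lambda: [100.0])
    bmc: BMCConfig = field(default_factory=BMCConfig)
    gsea: GSEAConfig = field(default_factory=GSEAConfig)
    mass_balance: MassBalanceConfig = field(default_factory=MassBalanceConfig)
    qivive: QIVIVEConfig = field(default_factory=QIVIVEConfig)
    hbgv: HBGVConfig = field(default_factory=HBGVConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d.pop(f.name)
            sub = {
                "bmc": BMCConfig,
                "gsea": GSEAConfig,
                "mass_balance": MassBalanceConfig,
                "qivive": QIVIVEConfig,
                "hbgv": HBGVConfig,
                "synthetic": SyntheticConfig,
            }.get(f.name)
            if sub is not None and isinstance(v, dict):
                if sub is SyntheticConfig and "set_size_range" in v:
                    v["set_size_range"] = tuple(v["set_size_range"])
                v = sub(**v)
            kwargs[f.name] = v
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    def write_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        d["synthetic"]["set_size_range"] = list(
            d["synthetic"]["set_size_range"]
        )
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def read_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)
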