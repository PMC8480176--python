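"""Configuration objects for simulation and the end-to-end pipeline.

Both configs are plain dataclasses that validate on construction and can be
round-tripped through YAML, so a run is fully described by one small file plus
a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

#: Pseudoautosomal region of the bovine X chromosome (UMD3.1), 1-based
#: inclusive bp bounds.  Non-PAR X is hemizygous in males.
DEFAULT_PAR_INTERVAL = (143_861_798, 148_823_899)

#: Default chromosome lengths (bp) for simulated cohorts: two autosome-scale
#: chromosomes plus an X long enough to contain the PAR.
DEFAULT_CHROM_LENGTHS = {
    "1": 158_534_110,
    "2": 136_231_102,
    "X": 148_823_899,
}


@dataclass
class FixedEffectSpec:
    """Levels and between-level SD (trait units) for one fixed-effect factor."""

    n_levels: int
    sd: float

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("fixed-effect factor needs >= 1 level")
        if self.sd < 0:
            raise ValueError("fixed-effect SD must be >= 0")


def _default_fixed_effects() -> dict[str, FixedEffectSpec]:
    # Herd-by-scoring-date contemporary groups dominate the environmental
    # structure of field-scored type traits; age-in-months and dam parity are
    # smaller systematic effects.
    return {
        "hsd": FixedEffectSpec(n_levels=40, sd=0.5),
        "age_class": FixedEffectSpec(n_levels=11, sd=0.25),
        "dam_parity": FixedEffectSpec(n_levels=5, sd=0.15),
    }


@dataclass
class SimConfig:
    """Generative settings for a cattle-like genotype/phenotype cohort.

    The defaults mirror the structure of a single-breed subjective-score
    cohort: ~70% males (the field data are male-biased), one trait scored on
    a bounded scale, herd-by-date / age / parity fixed effects, a polygenic
    background with GRM-structured covariance at narrow-sense heritability
    ``h2``, and a handful of causal SNPs whose allele substitution effects may
    differ between the sexes in size and/or sign.
    """

    n_males: int = 1400
    n_females: int = 600
    n_snps_per_chrom: int = 500
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    maf_low: float = 0.002
    maf_high: float = 0.5
    missing_rate: float = 0.0
    n_causal_shared: int = 0
    n_causal_male_only: int = 0
    n_causal_female_only: int = 0
    n_causal_opposite: int = 0
    effect_size_sd: float = 0.3
    h2: float = 0.4
    trait: str = "trait"
    trait_mean: float = 8.0
    sex_effect: float = 0.5  # male mean minus female mean, trait units
    breed: str = "SIM"
    fixed_effects: dict[str, FixedEffectSpec] = field(
        default_factory=_default_fixed_effects
    )
    n_classifiers: int = 4
    years: tuple[int, int] = (2000, 2016)
    par_interval: tuple[int, int] = DEFAULT_PAR_INTERVAL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males < 0 or self.n_females < 0:
            raise ValueError("sample counts must be >= 0")
        if self.n_males + self.n_females == 0:
            raise ValueError("cohort must contain at least one sample")
        if self.n_snps_per_chrom <= 0 or not self.chrom_lengths:
            raise ValueError("need at least one SNP on at least one chromosome")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("MAF spectrum must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be a proportion in [0, 1]")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie strictly inside (0, 1)")
        for name in (
            "n_causal_shared",
            "n_causal_male_only",
            "n_causal_female_only",
            "n_causal_opposite",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total_causal > self.n_snps_total:
            raise ValueError("causal counts exceed the total SNP count")
        lo, hi = self.par_interval
        if not (1 <= lo <= hi):
            raise ValueError("PAR interval must be a well-formed 1-based bp range")
        if "X" in self.chrom_lengths and hi > self.chrom_lengths["X"]:
            raise ValueError("PAR interval extends past the X chromosome length")

    @property
    def n_samples(self) -> int:
        return self.n_males + self.n_females

    @property
    def n_snps_total(self) -> int:
        return self.n_snps_per_chrom * len(self.chrom_lengths)

    @property
    def total_causal(self) -> int:
        return (
            self.n_causal_shared
            + self.n_causal_male_only
            + self.n_causal_female_only
            + self.n_causal_opposite
        )

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["fixed_effects"] = {
            k: {"n_levels": v.n_levels, "sd": v.sd}
            for k, v in self.fixed_effects.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "fixed_effects" in data:
            data["fixed_effects"] = {
                k: FixedEffectSpec(**v) for k, v in data["fixed_effects"].items()
            }
        for key in ("chrom_lengths",):
            if key in data:
                data[key] = {str(k): int(v) for k, v in data[key].items()}
        for key in ("par_interval", "years"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PipelineConfig:
    """Thresholds, filters and paths for an end-to-end scan.

    The screening constants default to the study's values: contrast
    significance at 1e-5 (suggestive) / 1e-8 (significant), variant and sample
    call rate >= 0.90, exclusion of MAF <= 0.002, contemporary groups of at
    least five records, and the bovine X PAR bounds.
    """

    genotypes: Optional[str] = None
    phenotypes: Optional[str] = None
    out_dir: str = "results/pipeline"
    suggestive: float = 1e-5
    significant: float = 1e-8
    af_alpha: float = 0.05
    min_call_rate: float = 0.90
    maf_floor: float = 0.002
    min_group_size: int = 5
    min_stratum_n: int = 30
    par_interval: tuple[int, int] = DEFAULT_PAR_INTERVAL
    seed: int = 0
    sim: Optional[SimConfig] = None
    run_windows: bool = True
    run_calibration: bool = False
    calibration_replicates: int = 10

    def __post_init__(self) -> None:
        for name in ("suggestive", "significant", "af_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.suggestive < self.significant:
            raise ValueError(
                "suggestive threshold must be >= significant threshold"
            )
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0, 1]")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")
        lo, hi = self.par_interval
        if not (1 <= lo <= hi):
            raise ValueError("PAR interval must be a well-formed 1-based bp range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("sim") is not None:
            sim = data["sim"]
            if "fixed_effects" in sim:
                sim["fixed_effects"] = {
                    k: FixedEffectSpec(**v) for k, v in sim["fixed_effects"].items()
                }
            for key in ("par_interval", "years"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            data["sim"] = SimConfig(**sim)
        if "par_interval" in data:
            data["par_interval"] = tuple(data["par_interval"])
        return cls(**data)
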