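"""Simulate the study cohort and persist it as VCF + phenotype TSV.

Generates a single-breed cohort of 2,000 animals (1,400 males, 600 females)
with 5,000 SNPs over three autosomes and the X, a polygenic background at
h2 = 0.4, herd-by-date / age / parity fixed effects, and 20 causal SNPs
with opposite-sign allele substitution effects in the two sexes.  Outputs
go to scratch/cohort/ (large files) and results/analysis/ (summary).
"""

import json
from pathlib import Path

from dimorphscan import io, simulate
from dimorphscan.config import SimConfig

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results" / "analysis"

CFG = SimConfig(
    n_males=1400,
    n_females=600,
    n_snps_per_chrom=1250,
    chrom_lengths={"1": 158_534_110, "2": 136_231_102,
                   "3": 121_005_158, "X": 148_823_899},
    maf_low=0.02,
    missing_rate=0.01,
    n_causal_opposite=20,
    effect_size_sd=0.3,
    h2=0.4,
    seed=2024,
)


def main() -> None:
    COHORT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    dataset = simulate.simulate_genotypes(CFG)
    effects = simulate.assign_effects(CFG, dataset)
    frame = simulate.simulate_phenotypes(dataset, effects, CFG)
    io.write_dataset(dataset, frame,
                     COHORT / "genotypes.vcf", COHORT / "phenotypes.tsv")
    io.write_table(effects, COHORT / "true_effects.tsv")
    CFG.to_yaml(COHORT / "sim_config.yaml")
    summary = {
        "n_samples": dataset.n_samples,
        "n_snps": dataset.n_snps,
        "n_causal_opposite": int((effects["class"] == "opposite").sum()),
        "mean_maf": float(dataset.maf().mean()),
        "trait_mean": float(frame[CFG.trait].mean()),
        "trait_sd": float(frame[CFG.trait].std()),
    }
    (RESULTS / "01_cohort_summary.json").write_text(json.dumps(summary, indent=1))
    print("cohort written to", COHORT)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
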