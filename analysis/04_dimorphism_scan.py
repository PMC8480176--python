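"""Between-sex effect contrast over all SNPs segregating in both sexes.

Joins the male and female association summaries, computes the contrast
statistic and its classification at the 1e-5 / 1e-8 thresholds, the
allele-frequency-divergence screen and the minor-allele-concordance flag,
and reports how well the scan recovers the simulated dimorphic SNPs.
Run 01-03 first.
"""

import json
from pathlib import Path

import pandas as pd

from dimorphscan import dimorphism, io

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results" / "analysis"


def main() -> None:
    male = pd.read_csv(COHORT / "assoc_male.tsv", sep="\t")
    female = pd.read_csv(COHORT / "assoc_female.tsv", sep="\t")
    joined, mono = dimorphism.join_sex_summaries(male, female)
    io.write_table(joined, COHORT / "dimorphism.tsv")
    io.write_table(mono, COHORT / "monomorphic_in_one_sex.tsv")

    truth = pd.read_csv(COHORT / "true_effects.tsv", sep="\t")
    dimorphic_truth = set(truth.loc[truth["class"] != "shared", "snp"])
    flagged = set(joined.loc[joined["classification"] != "none", "snp"])
    top = (joined.sort_values("p_dimorph")
           .head(10)[["snp", "chrom", "pos", "b_m", "b_f", "p_dimorph",
                      "classification"]])
    io.write_table(top, RESULTS / "04_top_dimorphic_snps.tsv")
    summary = {
        "n_joined": len(joined),
        "n_monomorphic_one_sex": len(mono),
        "n_suggestive": int((joined["p_dimorph"] <= 1e-5).sum()),
        "n_significant": int((joined["p_dimorph"] <= 1e-8).sum()),
        "pct_minor_allele_concordant":
            100 * float(joined["minor_allele_concordant"].mean()),
        "pct_af_divergent_p05": 100 * float((joined["af_p"] <= 0.05).mean()),
        "n_true_dimorphic_recovered": len(dimorphic_truth & flagged),
        "n_true_dimorphic": len(dimorphic_truth),
    }
    (RESULTS / "04_dimorphism_summary.json").write_text(
        json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
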