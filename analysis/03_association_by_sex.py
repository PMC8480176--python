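"""Sex-stratified mixed-model association on the adjusted cohort.

Each sex gets its own variant QC (call rate >= 0.90, MAF > 0.002), autosomal
GRM, REML variance components, and per-SNP GLS scan; the X is analyzed with
non-PAR males coded homozygous.  Run 01 and 02 first.
"""

import json
from pathlib import Path

import numpy as np

from dimorphscan import io, mlma

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results" / "analysis"


def main() -> None:
    dataset = io.read_vcf(COHORT / "genotypes.vcf")
    adjusted = io.read_phenotypes(COHORT / "adjusted_phenotypes.tsv")
    keep = set(adjusted["animal_id"])
    mask = np.array([s in keep for s in dataset.samples])
    dataset = dataset.subset_samples(mask)
    adjusted = adjusted.set_index("animal_id").loc[dataset.samples].reset_index()

    results = mlma.run_sex_stratified(dataset, adjusted)
    summary = {}
    for sex, table in results.items():
        io.write_table(table, COHORT / f"assoc_{sex}.tsv")
        vc = table.attrs["variance_components"]
        summary[sex] = {
            "n_snps_tested": len(table),
            "sigma_u2": vc.sigma_u2,
            "sigma_e2": vc.sigma_e2,
            "h2": vc.h2,
            "min_assoc_p": float(table["p"].min()),
        }
    (RESULTS / "03_association_summary.json").write_text(
        json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
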