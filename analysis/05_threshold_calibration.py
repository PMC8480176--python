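"""Split-half empirical null for the genome-wide dimorphism threshold.

Repeatedly splits the cohort into two mixed-sex halves (each with half the
males and half the females), reruns the per-group association and effect
contrast, and records the genome-wide minimum contrast p.  Because the
halves share a sex composition, minima comfortably above 1e-8 support that
threshold for declaring significant dimorphism.  Run 01-02 first.
"""

import json
from pathlib import Path

import numpy as np

from dimorphscan import dimorphism, io

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results" / "analysis"

N_REPLICATES = 10
SEED = 2024


def main() -> None:
    dataset = io.read_vcf(COHORT / "genotypes.vcf")
    adjusted = io.read_phenotypes(COHORT / "adjusted_phenotypes.tsv")
    keep = set(adjusted["animal_id"])
    mask = np.array([s in keep for s in dataset.samples])
    dataset = dataset.subset_samples(mask)
    adjusted = adjusted.set_index("animal_id").loc[dataset.samples].reset_index()

    mins = []
    for rep in range(N_REPLICATES):
        res = dimorphism.split_half_calibration(dataset, adjusted,
                                                seed=SEED + rep)
        mins.append(res["min_p"])
        print(f"replicate {rep}: min p = {res['min_p']:.3e}")
    summary = {
        "n_replicates": N_REPLICATES,
        "min_p_per_replicate": mins,
        "overall_min_p": min(mins),
        "n_at_or_above_1e-8": int(sum(m >= 1e-8 for m in mins)),
    }
    (RESULTS / "05_calibration.json").write_text(json.dumps(summary, indent=1))
    print(json.dumps({k: v for k, v in summary.items()
                      if k != "min_p_per_replicate"}, indent=1))


if __name__ == "__main__":
    main()
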