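"""1-kb window overlap of dimorphic regions across two traits.

Simulates a second trait on the same genotypes whose dimorphic SNPs partly
coincide with the first trait's, scans both, flags 1-kb windows containing
at least one suggestive SNP, and intersects the window sets.  Run 01-02
first (the first trait's dimorphism table comes from 04 if present,
otherwise it is recomputed).
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from dimorphscan import dimorphism, io, mlma, simulate, windows
from dimorphscan.config import SimConfig

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results" / "analysis"


def scan_trait(dataset, frame, trait_col):
    res = mlma.run_sex_stratified(dataset, frame, trait_col=trait_col)
    joined, _ = dimorphism.join_sex_summaries(res["male"], res["female"],
                                              af_test=False)
    return joined


def main() -> None:
    dataset = io.read_vcf(COHORT / "genotypes.vcf")
    frame = io.read_phenotypes(COHORT / "phenotypes.tsv")
    cfg = SimConfig.from_yaml(COHORT / "sim_config.yaml")
    effects_a = io.read_phenotypes(COHORT / "true_effects.tsv")

    # second trait: keep half the dimorphic SNPs, redraw the rest
    cfg_b = dataclasses.replace(cfg, seed=cfg.seed + 1)
    effects_b = simulate.assign_effects(cfg_b, dataset)
    half = len(effects_a) // 2
    effects_b = effects_b.iloc[half:].copy()
    effects_b = pd.concat([effects_a.iloc[:half], effects_b]).reset_index(drop=True)
    frame_b = simulate.simulate_phenotypes(dataset, effects_b, cfg_b)

    frame["adjusted"] = frame["trait"]
    frame_b["adjusted"] = frame_b[cfg.trait]
    hits = {}
    for tag, (ds, fr) in {
        ("SIM", "trait_a"): (dataset, frame),
        ("SIM", "trait_b"): (dataset, frame_b),
    }.items():
        joined = scan_trait(ds, fr, "adjusted")
        flagged = windows.flag_windows(joined, threshold=1e-5)
        windows.write_bed(flagged, RESULTS / f"06_windows_{tag[1]}.bed",
                          tags=":".join(tag))
        hits[tag] = flagged
    table = windows.overlap_hits(hits)
    shared = windows.shared_by_at_least(table, 2)
    io.write_table(shared, RESULTS / "06_shared_windows.tsv")
    summary = {
        "n_windows_trait_a": len(hits[("SIM", "trait_a")]),
        "n_windows_trait_b": len(hits[("SIM", "trait_b")]),
        "n_shared_windows": len(shared),
        "shared_labels": [
            f"{r.chrom}:{windows.mb_label(r.window_index)}"
            for r in shared.itertuples(index=False)
        ],
    }
    (RESULTS / "06_overlap_summary.json").write_text(
        json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
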