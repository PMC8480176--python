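"""End-to-end orchestration: simulate -> preprocess -> association -> contrast
-> windows, with a run manifest and a recomputable summary report."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dimorphism, grm, io, mlma, preprocess, simulate, windows
from .config import PipelineConfig, SimConfig

log = logging.getLogger(__name__)


def _stage(manifest: dict, name: str, t0: float, **counts) -> None:
    manifest["stages"].append(
        {"name": name, "seconds": round(time.time() - t0, 3), **counts}
    )


def prepare_cohort(sim_cfg: SimConfig):
    """Simulate genotypes, effects and phenotypes for one cohort."""
    dataset = simulate.simulate_genotypes(sim_cfg)
    effects = simulate.assign_effects(sim_cfg, dataset)
    frame = simulate.simulate_phenotypes(dataset, effects, sim_cfg)
    return dataset, effects, frame


def adjust_cohort(frame: pd.DataFrame, dataset, trait: str,
                  min_group_size: int = 5) -> pd.DataFrame:
    """Apply the phenotype edits and mixed-model pre-adjustment.

    Returns the surviving rows of ``frame`` with an ``adjusted`` column,
    aligned to a (possibly subset) sample order of ``dataset``.
    """
    edited = preprocess.recode_parity_column(frame)
    edited = preprocess.filter_contemporary_groups(edited, min_size=min_group_size)
    edited = edited.reset_index(drop=True)
    edited["cls_year"] = edited["classifier"].astype(str) + "_" + edited["year"].astype(str)
    edited[trait] = preprocess.standardize_within_group(
        edited[trait], edited["cls_year"]
    )
    keep_ids = set(edited["animal_id"])
    keep_mask = np.array([s in keep_ids for s in dataset.samples])
    sub = dataset.subset_samples(keep_mask)
    edited = edited.set_index("animal_id").loc[sub.samples].reset_index()
    K = grm.compute_grm(sub, autosomes_only=True)
    fit = preprocess.fit_adjustment_model(edited, K, trait)
    adjusted = preprocess.adjust_phenotypes(edited, fit, trait)
    edited["adjusted"] = adjusted["adjusted"].to_numpy()
    edited.attrs["adjustment_fit"] = fit
    return edited, sub


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest.

    All stage outputs are TSV/JSON under ``cfg.out_dir``.  With a simulation
    config the cohort is generated in-process; otherwise genotypes and
    phenotypes are read from the configured paths.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "seed": cfg.seed, "stages": [],
    }

    t0 = time.time()
    if cfg.sim is not None:
        dataset, effects, frame = prepare_cohort(cfg.sim)
        trait = cfg.sim.trait
        io.write_table(effects, out / "true_effects.tsv")
    else:
        if not cfg.genotypes or not cfg.phenotypes:
            raise ValueError("either a sim config or genotype+phenotype paths")
        dataset = io.read_vcf(cfg.genotypes)
        frame = io.read_phenotypes(cfg.phenotypes)
        trait_cols = [c for c in frame.columns if c not in {
            "animal_id", "sex", "breed", "hsd", "age_class", "dam_parity",
            "classifier", "year"} and not c.startswith("true_")]
        trait = trait_cols[0]
    _stage(manifest, "cohort", t0, n_samples=dataset.n_samples,
           n_snps=dataset.n_snps)

    t0 = time.time()
    dataset = grm.sample_call_rate_filter(dataset, min_rate=cfg.min_call_rate)
    frame = (frame.set_index("animal_id").loc[dataset.samples].reset_index())
    adjusted, dataset = adjust_cohort(
        frame, dataset, trait, min_group_size=cfg.min_group_size
    )
    fit = adjusted.attrs["adjustment_fit"]
    io.write_table(preprocess.solutions_table(fit), out / "fixed_effect_solutions.tsv")
    (out / "variance_components.json").write_text(json.dumps({
        "sigma_a2": fit.vc.sigma_u2, "sigma_e2": fit.vc.sigma_e2,
        "log_likelihood": fit.vc.log_likelihood,
    }, indent=1))
    _stage(manifest, "preprocess", t0, n_records=len(adjusted))

    t0 = time.time()
    results = mlma.run_sex_stratified(
        dataset, adjusted,
        min_call_rate=cfg.min_call_rate, maf_floor=cfg.maf_floor,
        min_stratum_n=cfg.min_stratum_n, par_interval=cfg.par_interval,
    )
    for sex, summary in results.items():
        io.write_table(summary, out / f"assoc_{sex}.tsv")
    _stage(manifest, "association", t0,
           n_male=len(results["male"]), n_female=len(results["female"]))

    t0 = time.time()
    dim, mono = dimorphism.join_sex_summaries(
        results["male"], results["female"],
        suggestive=cfg.suggestive, significant=cfg.significant,
    )
    io.write_table(dim, out / "dimorphism.tsv")
    io.write_table(mono, out / "monomorphic_in_one_sex.tsv")
    _stage(manifest, "dimorphism", t0, n_joined=len(dim), n_monomorphic=len(mono))

    if cfg.run_windows:
        t0 = time.time()
        hits = windows.flag_windows(dim, threshold=cfg.suggestive)
        windows.write_bed(hits, out / "windows_suggestive.bed")
        _stage(manifest, "windows", t0, n_windows=len(hits))

    if cfg.run_calibration:
        t0 = time.time()
        mins = []
        for rep in range(cfg.calibration_replicates):
            res = dimorphism.split_half_calibration(
                dataset, adjusted, seed=cfg.seed * 1000 + rep,
                min_call_rate=cfg.min_call_rate, maf_floor=cfg.maf_floor,
                min_stratum_n=cfg.min_stratum_n, par_interval=cfg.par_interval,
            )
            mins.append(res["min_p"])
        (out / "calibration.json").write_text(json.dumps({
            "replicates": cfg.calibration_replicates,
            "min_p": mins,
            "n_at_least_1e-8": int(sum(m >= cfg.significant for m in mins)),
        }, indent=1))
        _stage(manifest, "calibration", t0, n_replicates=len(mins))

    t0 = time.time()
    summary = report(out, suggestive=cfg.suggestive,
                     significant=cfg.significant, af_alpha=cfg.af_alpha)
    (out / "report.json").write_text(json.dumps(summary, indent=1))
    _stage(manifest, "report", t0)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def report(out_dir: str | Path, suggestive: float = 1e-5,
           significant: float = 1e-8, af_alpha: float = 0.05) -> dict:
    """Summary counts recomputed from the persisted dimorphism TSV.

    Suggestive counts are inclusive of significant SNPs (the nested
    "suggestive (significant in parenthesis)" presentation); concordance and
    allele-frequency-divergence percentages are over all joined SNPs.
    """
    path = Path(out_dir) / "dimorphism.tsv"
    if not path.exists():
        raise FileNotFoundError(f"no dimorphism table at {path}")
    dim = pd.read_csv(path, sep="\t")
    n = len(dim)
    n_sig = int((dim["p_dimorph"] <= significant).sum())
    n_sug = int((dim["p_dimorph"] <= suggestive).sum())  # includes significant
    out = {
        "n_snps_joined": n,
        "n_suggestive": n_sug,
        "n_significant": n_sig,
        "pct_minor_allele_concordant": (
            100.0 * float(dim["minor_allele_concordant"].mean()) if n else float("nan")
        ),
        "pct_af_divergent": (
            100.0 * float((dim["af_p"] <= af_alpha).mean()) if n else float("nan")
        ),
    }
    wpath = Path(out_dir) / "windows_suggestive.bed"
    if wpath.exists():
        n_windows = sum(
            1 for line in wpath.read_text().splitlines() if not line.startswith("#")
        )
        out["n_windows_suggestive"] = n_windows
    return out
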