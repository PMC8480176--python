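import numpy as np
import pandas as pd
import pytest

from dimorphscan import pipeline
from dimorphscan.config import SimConfig


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-animal, 360-SNP cohort with dimorphic and shared causal SNPs."""
    cfg = SimConfig(
        n_males=210,
        n_females=90,
        n_snps_per_chrom=120,
        maf_low=0.05,
        n_causal_shared=2,
        n_causal_opposite=3,
        effect_size_sd=0.5,
        h2=0.4,
        seed=11,
    )
    dataset, effects, frame = pipeline.prepare_cohort(cfg)
    return cfg, dataset, effects, frame


def make_assoc(snps, betas, ses, freqs, n=100, stratum="male",
               counted=None, other=None):
    """Hand-build an association summary frame for join/contrast tests."""
    m = len(snps)
    counted = counted or ["A"] * m
    other = other or ["G"] * m
    z = np.asarray(betas) / np.asarray(ses)
    from scipy import stats
    return pd.DataFrame({
        "snp": snps,
        "chrom": ["1"] * m,
        "pos": np.arange(1, m + 1) * 100,
        "counted_allele": counted,
        "other_allele": other,
        "freq": freqs,
        "n": [n] * m,
        "beta": betas,
        "se": ses,
        "p": 2 * stats.norm.sf(np.abs(z)),
        "stratum": stratum,
    })
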