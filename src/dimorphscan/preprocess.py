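"""Phenotype edits, within-classifier standardization, and mixed-model
pre-adjustment.

The association stage consumes "adjusted" phenotypes: the raw (standardized)
score minus the fixed-effect solutions for contemporary group
(herd-by-scoring-date, HSD), age-in-months class (AM) and dam parity class
(DP), estimated once per trait from the animal model

    y = mu + HSD + AM + DP + animal + e,    animal ~ N(0, K sigma_a2)

fitted by REML with a genomic relationship matrix standing in for the
pedigree numerator matrix.  Only the fixed-effect solutions are subtracted:
the overall mean and the animal genetic effect stay in the adjusted value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lmm
from .datatypes import VarianceComponents

log = logging.getLogger(__name__)

ADJUSTMENT_FACTORS = ("hsd", "age_class", "dam_parity")


def recode_dam_parity(parity) -> int:
    """Collapse dam parity into classes 1, 2, 3, 4 and 5 (= parity >= 5).

    A missing parity is a removal condition for the record, signalled here
    with ``ValueError`` so callers can drop and log it.
    """
    if parity is None or (isinstance(parity, float) and np.isnan(parity)):
        raise ValueError("dam parity not recorded")
    parity = int(parity)
    if parity < 1:
        raise ValueError(f"invalid dam parity {parity}")
    return min(parity, 5)


def recode_parity_column(frame: pd.DataFrame, column: str = "dam_parity") -> pd.DataFrame:
    """Vectorized parity recoding; rows with missing parity are dropped."""
    out = frame.copy()
    missing = out[column].isna()
    if missing.any():
        log.info("dropping %d records with unrecorded dam parity", int(missing.sum()))
        out = out[~missing]
    out[column] = out[column].astype(int).clip(upper=5)
    if (out[column] < 1).any():
        raise ValueError("dam parity below 1 encountered")
    return out.reset_index(drop=True)


def filter_contemporary_groups(
    frame: pd.DataFrame,
    min_size: int = 5,
    group_cols: tuple[str, ...] = ("breed", "hsd"),
) -> pd.DataFrame:
    """Keep only records whose herd-by-scoring-date group (within breed) has
    at least ``min_size`` records."""
    sizes = frame.groupby(list(group_cols))[group_cols[-1]].transform("size")
    keep = sizes >= min_size
    n_removed = int((~keep).sum())
    if n_removed:
        log.info(
            "contemporary-group filter removed %d/%d records "
            "(groups with < %d records)", n_removed, len(frame), min_size,
        )
    if not keep.any():
        log.warning("contemporary-group filter removed every record")
    return frame[keep].reset_index(drop=True)


def standardize_within_group(
    values: pd.Series, groups: pd.Series
) -> pd.Series:
    """Rescale each classifier-by-year group to the pooled within-group variance.

    Each group keeps its mean; its deviations are multiplied by
    ``s_pooled / s_group`` so every group ends with the same (pooled)
    variance.  Groups with fewer than two records or zero variance are passed
    through unchanged with a warning.
    """
    values = values.astype(float)
    df = pd.DataFrame({"v": values, "g": groups})
    stats = df.groupby("g")["v"].agg(["mean", "var", "count"])
    usable = stats[(stats["count"] >= 2) & (stats["var"] > 0)]
    if usable.empty:
        log.warning("no group with positive variance; standardization skipped")
        return values.copy()
    weights = usable["count"] - 1
    pooled_var = float((usable["var"] * weights).sum() / weights.sum())
    out = values.copy()
    for g, row in stats.iterrows():
        mask = groups == g
        if row["count"] < 2 or row["var"] <= 0:
            log.warning("degenerate classifier-by-year group %r passed through", g)
            continue
        scale = np.sqrt(pooled_var / row["var"])
        out[mask] = row["mean"] + (values[mask] - row["mean"]) * scale
    return out


@dataclass
class AdjustmentFit:
    """Fixed-effect solutions and variance components of the animal model."""

    solutions: dict[str, dict[str, float]]  # factor -> level -> effect
    reference_levels: dict[str, str]
    vc: VarianceComponents
    intercept: float


def _design(frame: pd.DataFrame, factors) -> tuple[np.ndarray, list[tuple[str, str]], dict[str, str]]:
    """Intercept + treatment-coded dummies, first observed level as reference."""
    n = len(frame)
    cols = [np.ones(n)]
    names: list[tuple[str, str]] = [("intercept", "")]
    refs: dict[str, str] = {}
    for factor in factors:
        levels = list(dict.fromkeys(frame[factor].astype(str)))
        refs[factor] = levels[0]
        values = frame[factor].astype(str).to_numpy()
        for lev in levels[1:]:
            cols.append((values == lev).astype(float))
            names.append((factor, lev))
    X = np.column_stack(cols)
    return X, names, refs


def fit_adjustment_model(
    frame: pd.DataFrame,
    K: np.ndarray,
    trait: str,
    factors=ADJUSTMENT_FACTORS,
) -> AdjustmentFit:
    """REML fit of the animal model; returns fixed-effect solutions.

    ``K`` is the relationship matrix over the rows of ``frame`` (order must
    match).  Raises if the design is confounded (aliased factor levels) or
    the likelihood is degenerate.
    """
    y = frame[trait].to_numpy(dtype=float)
    X, names, refs = _design(frame, factors)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"confounded fixed effects for trait {trait!r}: design matrix "
            "is rank deficient after reference-level constraints"
        )
    try:
        fit = lmm.reml(y, X, K=K)
    except FloatingPointError as err:
        raise RuntimeError(f"REML failed for trait {trait!r}: {err}") from err
    solutions: dict[str, dict[str, float]] = {f: {} for f in factors}
    intercept = 0.0
    for (factor, level), b in zip(names, fit.beta):
        if factor == "intercept":
            intercept = float(b)
        else:
            solutions[factor][level] = float(b)
    for factor in factors:
        solutions[factor].setdefault(refs[factor], 0.0)
    vc = VarianceComponents(
        sigma_u2=fit.sigma_u2, sigma_e2=fit.sigma_e2,
        log_likelihood=fit.log_likelihood,
    )
    return AdjustmentFit(
        solutions=solutions, reference_levels=refs, vc=vc, intercept=intercept
    )


def adjust_phenotypes(
    frame: pd.DataFrame,
    fit: AdjustmentFit,
    trait: str,
    factors=ADJUSTMENT_FACTORS,
) -> pd.DataFrame:
    """Subtract the fixed-effect solutions from the raw trait.

    ``adjusted = raw - HSD_sol - AM_sol - DP_sol``; the intercept and the
    animal genetic effect are deliberately left in.  An unseen factor level
    raises.
    """
    adjusted = frame[trait].to_numpy(dtype=float).copy()
    for factor in factors:
        sols = fit.solutions[factor]
        levels = frame[factor].astype(str)
        unseen = set(levels) - set(sols)
        if unseen:
            raise KeyError(
                f"levels {sorted(unseen)} of factor {factor!r} have no solution"
            )
        adjusted -= levels.map(sols).to_numpy(dtype=float)
    out = frame[["animal_id", "sex", "breed"]].copy()
    out["trait"] = trait
    out["adjusted"] = adjusted
    if not np.all(np.isfinite(adjusted)):
        raise ValueError("non-finite adjusted phenotype produced")
    return out


def solutions_table(fit: AdjustmentFit) -> pd.DataFrame:
    rows = [
        (factor, level, est)
        for factor, sols in fit.solutions.items()
        for level, est in sorted(sols.items())
    ]
    return pd.DataFrame(rows, columns=["factor", "level", "estimate"])
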