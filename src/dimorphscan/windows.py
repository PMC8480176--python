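"""1-kb genomic windowing of dimorphic SNPs and cross-trait/breed overlap.

Windows tile each chromosome from base 1 in 1,000-bp steps; a 1-based
position ``pos`` falls in window ``(pos - 1) // 1000``, spanning
``[index*1000 + 1, index*1000 + 1000]`` inclusive.  BED output converts to
the 0-based half-open convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

WINDOW_BP = 1000


def assign_window(pos) -> np.ndarray | int:
    """Window index of a 1-based bp position."""
    p = np.asarray(pos)
    if np.any(p <= 0):
        raise ValueError("positions are 1-based; got a value <= 0")
    idx = (p - 1) // WINDOW_BP
    return int(idx) if idx.ndim == 0 else idx.astype(int)


def flag_windows(
    records: pd.DataFrame,
    threshold: float,
    p_col: str = "p_dimorph",
) -> pd.DataFrame:
    """Windows containing at least one SNP at or below the threshold.

    Returns one row per (chrom, window_index) with ``start``/``end`` (1-based
    inclusive bp), ``n_snps`` and ``best_p``.
    """
    hits = records[records[p_col] <= threshold]
    if hits.empty:
        return pd.DataFrame(
            columns=["chrom", "window_index", "start", "end", "n_snps", "best_p"]
        )
    df = hits[["chrom", "pos", p_col]].copy()
    df["window_index"] = assign_window(df["pos"].to_numpy())
    grouped = (
        df.groupby(["chrom", "window_index"])[p_col]
        .agg(n_snps="size", best_p="min")
        .reset_index()
    )
    grouped["start"] = grouped["window_index"] * WINDOW_BP + 1
    grouped["end"] = grouped["start"] + WINDOW_BP - 1
    return grouped[["chrom", "window_index", "start", "end", "n_snps", "best_p"]]


def overlap_hits(hitsets: dict) -> pd.DataFrame:
    """Windows shared across (breed, trait)-tagged hit sets.

    ``hitsets`` maps a tag (any hashable, e.g. ``("CH", "CW")``) to a
    ``flag_windows`` table.  The result has one row per window that appears
    in at least one set, with the attached tags and their count, so queries
    like "windows shared by >= k traits" are a filter on ``n_tags``.
    """
    if len(hitsets) < 2:
        raise ValueError("overlap needs at least two hit sets")
    rows: dict[tuple, set] = {}
    for tag, hits in hitsets.items():
        for rec in hits.itertuples(index=False):
            rows.setdefault((rec.chrom, rec.window_index), set()).add(tag)
    out = pd.DataFrame(
        [
            {
                "chrom": chrom,
                "window_index": idx,
                "start": idx * WINDOW_BP + 1,
                "end": idx * WINDOW_BP + WINDOW_BP,
                "tags": tuple(sorted(map(str, tags))),
                "n_tags": len(tags),
            }
            for (chrom, idx), tags in sorted(rows.items(), key=lambda kv: (str(kv[0][0]), kv[0][1]))
        ]
    )
    return out


def shared_by_at_least(overlap: pd.DataFrame, k: int) -> pd.DataFrame:
    return overlap[overlap["n_tags"] >= k].reset_index(drop=True)


def write_bed(hits: pd.DataFrame, path: str | Path, tags: str = "") -> None:
    """Persist window hits as BED (0-based half-open)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("# 1-kb windows, 0-based half-open; internal convention is "
                 "1-based tiling from base 1\n")
        fh.write("#chrom\tstart\tend\tn_snps\tbest_p\ttags\n")
        for rec in hits.itertuples(index=False):
            bed_start = rec.start - 1
            bed_end = rec.end
            fh.write(
                f"{rec.chrom}\t{bed_start}\t{bed_end}\t{rec.n_snps}\t"
                f"{rec.best_p:.3g}\t{tags}\n"
            )


def mb_label(window_index: int) -> str:
    """Window start in Mb with three decimals (reporting style)."""
    return f"{window_index * WINDOW_BP / 1e6:.3f} Mb"
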