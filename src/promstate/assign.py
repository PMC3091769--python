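"""Peak-to-promoter assignment and TSS-anchored metaprofiles."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .normalize import NormalizedTrack
from .peaks import map_probes_to_windows


def assign_peaks(
    peaks: pd.DataFrame,
    windows: pd.DataFrame,
    cell_type: str = "",
    modification: str = "",
) -> pd.DataFrame:
    """Mark each gene whose promoter window overlaps ≥1 peak by ≥1 bp.

    Half-open intervals: a peak ending exactly at the window start does
    not overlap. Returns one row per gene (gene_id, cell_type,
    modification, marked, score); score is the best (max) overlapping
    peak score, NaN when unmarked.
    """
    marked = pd.Series(False, index=pd.Index(windows["gene_id"], name="gene_id"))
    score = pd.Series(np.nan, index=marked.index)
    for chrom, win in windows.groupby("chrom", sort=False):
        pk = peaks[peaks["chrom"] == chrom] if not peaks.empty else peaks
        if pk.empty:
            continue
        ws = win["start"].to_numpy()[:, None]
        we = win["end"].to_numpy()[:, None]
        ps = pk["start"].to_numpy()[None, :]
        pe = pk["end"].to_numpy()[None, :]
        overlap = (ps < we) & (pe > ws)  # ≥1 bp in half-open coords
        any_hit = overlap.any(axis=1)
        pk_scores = pk["score"].to_numpy()[None, :]
        best = np.where(overlap, pk_scores, -np.inf).max(axis=1)
        gids = win["gene_id"].to_numpy()
        marked.loc[gids[any_hit]] = True
        score.loc[gids[any_hit]] = best[any_hit]
    return pd.DataFrame(
        {
            "gene_id": marked.index,
            "cell_type": cell_type,
            "modification": modification,
            "marked": marked.to_numpy(),
            "score": score.to_numpy(),
        }
    )


def metaprofile(
    track: NormalizedTrack,
    probes: pd.DataFrame,
    windows: pd.DataFrame,
    bin_size: int = 50,
    upstream: int = 2000,
    downstream: int = 500,
) -> pd.DataFrame:
    """Average track value as a function of signed distance to the TSS.

    Each probe midpoint is converted to a strand-aware TSS-relative
    coordinate (upstream negative); per-bin means over all genes give
    the promoter-average profile. Returns (bin_center, mean, n).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    mapped = map_probes_to_windows(probes, windows)
    w = windows.set_index("gene_id")
    mid = (mapped["start"] + mapped["end"]) // 2
    tss = w.loc[mapped["gene_id"], "tss"].to_numpy()
    strand = w.loc[mapped["gene_id"], "strand"].to_numpy()
    rel = np.where(strand == "+", mid - tss, tss - mid)
    vals = track.values.reindex(mapped["probe_id"]).to_numpy()
    edges = np.arange(-upstream, downstream + bin_size, bin_size)
    which = np.digitize(rel, edges) - 1
    ok = (which >= 0) & (which < len(edges) - 1)
    df = pd.DataFrame({"bin": which[ok], "val": vals[ok]})
    agg = df.groupby("bin")["val"].agg(["mean", "count"])
    centers = (edges[:-1] + edges[1:]) / 2.0
    out = pd.DataFrame({"bin_center": centers, "mean": np.nan, "n": 0})
    out.loc[agg.index, "mean"] = agg["mean"].to_numpy()
    out.loc[agg.index, "n"] = agg["count"].to_numpy()
    return out
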