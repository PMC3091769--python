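"""Sliding-window permutation peak calling on tiled promoter tracks.

The commercial scanner the emulated platform shipped with is a black
box; this module is a transparent stand-in. Each promoter tile is
scanned with windows of ``min_probes`` consecutive probes scored by
their mean log2 ratio. A null distribution of window scores is built by
permuting probe values within each chromosome (seeded) and re-scanning;
windows whose score strictly exceeds the smallest threshold with
estimated false-discovery proportion ≤ ``fdr`` are kept, and
overlapping significant windows are merged into peaks. Ties at the
threshold are non-significant (conservative).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .normalize import NormalizedTrack


def map_probes_to_windows(probes: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Assign non-background probes to promoter windows by ≥1 bp overlap.

    Windows are assumed non-overlapping (one promoter per gene, as on
    the tiled array). Returns the probe rows that hit a window, with a
    ``gene_id`` column, sorted by (gene, start).
    """
    prom = probes[~probes["is_background"]].copy()
    out = []
    for chrom, grp in prom.groupby("chrom", sort=False):
        win = windows[windows["chrom"] == chrom].sort_values("start")
        if win.empty:
            continue
        wstart = win["start"].to_numpy()
        wend = win["end"].to_numpy()
        # candidate window: last one starting before the probe ends
        idx = np.searchsorted(wstart, grp["end"].to_numpy(), side="left") - 1
        valid = idx >= 0
        hit = valid.copy()
        hit[valid] &= wend[idx[valid]] > grp["start"].to_numpy()[valid]
        g = grp.loc[hit].copy()
        g["gene_id"] = win["gene_id"].to_numpy()[idx[hit]]
        out.append(g)
    if not out:
        return prom.iloc[0:0].assign(gene_id=pd.Series(dtype=str))
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["gene_id", "start"], kind="stable").reset_index(drop=True)


def _tile_arrays(track: NormalizedTrack, mapped: pd.DataFrame):
    """Concatenate tiles into flat arrays for cumsum window scoring.

    Returns (values, tile_id, chrom_codes, mapped_sorted); windows that
    would cross a tile boundary are masked out downstream.
    """
    vals = track.values.reindex(mapped["probe_id"]).to_numpy()
    if np.isnan(vals).any():
        raise ValueError("track is missing values for mapped probes")
    tile_id = pd.factorize(mapped["gene_id"])[0]
    chrom_codes = pd.factorize(mapped["chrom"])[0]
    return vals, tile_id, chrom_codes


def _window_scores(vals: np.ndarray, tile_id: np.ndarray, k: int):
    """Mean over every run of k consecutive probes inside one tile.

    Returns (scores, start_index) where start_index[i] is the position
    of the window's first probe in the flat array.
    """
    n = len(vals)
    if n < k:
        return np.empty(0), np.empty(0, dtype=int)
    cs = np.concatenate([[0.0], np.cumsum(vals)])
    starts = np.arange(n - k + 1)
    scores = (cs[starts + k] - cs[starts]) / k
    same_tile = tile_id[starts] == tile_id[starts + k - 1]
    return scores[same_tile], starts[same_tile]


def permutation_null(
    vals: np.ndarray,
    tile_id: np.ndarray,
    chrom_codes: np.ndarray,
    k: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pooled window scores under within-chromosome permutation of
    probe values; the empirical null for peak thresholding."""
    groups = [np.flatnonzero(chrom_codes == c) for c in np.unique(chrom_codes)]
    pooled = []
    perm_vals = vals.copy()
    for _ in range(n_permutations):
        for idx in groups:
            perm_vals[idx] = vals[idx][rng.permutation(len(idx))]
        s, _ = _window_scores(perm_vals, tile_id, k)
        pooled.append(s)
    return np.concatenate(pooled) if pooled else np.empty(0)


def _fdr_threshold(obs: np.ndarray, null_sorted: np.ndarray, n_permutations: int, fdr: float):
    """Smallest observed-score threshold t with estimated FDR ≤ fdr for
    the rule 'keep windows with score > t'. Returns (t, q_at_t) or
    (None, None) when no threshold achieves the target."""
    if len(obs) == 0:
        return None, None
    obs_sorted = np.sort(obs)
    candidates = np.unique(obs_sorted)
    # windows kept at threshold t: #obs > t ; expected false: (#null > t)/B
    n_obs_gt = len(obs) - np.searchsorted(obs_sorted, candidates, side="right")
    n_null_gt = len(null_sorted) - np.searchsorted(null_sorted, candidates, side="right")
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (n_null_gt / n_permutations) / np.maximum(n_obs_gt, 1)
    ok = (q <= fdr) & (n_obs_gt > 0)
    if not ok.any():
        return None, None
    i = int(np.argmax(ok))  # smallest candidate meeting the target
    return float(candidates[i]), float(q[i])


def call_peaks(
    track: NormalizedTrack,
    probes: pd.DataFrame,
    windows: pd.DataFrame,
    min_probes: int = 4,
    fdr: float = 0.05,
    n_permutations: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Detect enriched regions on one normalized track.

    Returns a peak table (chrom, start, end, name, score, n_probes,
    fdr_q); score is the mean track value over the peak's probes.
    """
    if min_probes < 2:
        raise ValueError("min_probes must be ≥ 2")
    if n_permutations < 50:
        raise ValueError("need at least 50 permutations")
    mapped = map_probes_to_windows(probes, windows)
    empty = pd.DataFrame(
        columns=["chrom", "start", "end", "name", "score", "n_probes", "fdr_q"]
    )
    if len(mapped) < min_probes:
        return empty
    vals, tile_id, chrom_codes = _tile_arrays(track, mapped)
    obs, starts = _window_scores(vals, tile_id, min_probes)
    if len(obs) == 0:
        return empty
    rng = np.random.default_rng(seed)
    null = permutation_null(vals, tile_id, chrom_codes, min_probes, n_permutations, rng)
    null_sorted = np.sort(null)
    thr, q_at_thr = _fdr_threshold(obs, null_sorted, n_permutations, fdr)
    if thr is None:
        return empty
    sig = obs > thr
    if not sig.any():
        return empty

    # merge significant windows sharing ≥1 probe (within one tile)
    probe_sig = np.zeros(len(vals), dtype=bool)
    for s in starts[sig]:
        probe_sig[s : s + min_probes] = True
    peaks = []
    pid = 0
    boundary = np.flatnonzero(np.diff(tile_id) != 0) + 1
    tile_edges = np.concatenate([[0], boundary, [len(vals)]])
    mstart = mapped["start"].to_numpy()
    mend = mapped["end"].to_numpy()
    mchrom = mapped["chrom"].to_numpy()
    for a, b in zip(tile_edges[:-1], tile_edges[1:]):
        run_start = None
        for i in range(a, b + 1):
            active = i < b and probe_sig[i]
            if active and run_start is None:
                run_start = i
            elif not active and run_start is not None:
                lo, hi = run_start, i
                score = float(vals[lo:hi].mean())
                peaks.append(
                    (
                        mchrom[lo],
                        int(mstart[lo:hi].min()),
                        int(mend[lo:hi].max()),
                        f"peak_{pid:05d}",
                        score,
                        hi - lo,
                        q_at_thr,
                    )
                )
                pid += 1
                run_start = None
    return pd.DataFrame(
        peaks, columns=["chrom", "start", "end", "name", "score", "n_probes", "fdr_q"]
    )


def gene_delta_score(
    delta_track: NormalizedTrack,
    probes: pd.DataFrame,
    windows: pd.DataFrame,
    min_probes: int = 4,
) -> pd.Series:
    """Per-gene extreme windowed mean of a differentiation-delta track.

    For each promoter, the sliding-window mean with the largest
    magnitude (sign kept: positive = gain, negative = loss of the
    modification relative to the progenitor). Genes whose promoter holds
    fewer than ``min_probes`` probes get NaN (uncallable).
    """
    if delta_track.mode != "delta":
        raise ValueError("gene_delta_score requires a delta-mode track")
    mapped = map_probes_to_windows(probes, windows)
    out = pd.Series(np.nan, index=pd.Index(windows["gene_id"], name="gene_id"))
    if mapped.empty:
        return out
    vals, tile_id, _ = _tile_arrays(delta_track, mapped)
    scores, starts = _window_scores(vals, tile_id, min_probes)
    if len(scores) == 0:
        return out
    genes = mapped["gene_id"].to_numpy()[starts]
    df = pd.DataFrame({"gene_id": genes, "score": scores})
    idx = df.groupby("gene_id")["score"].apply(lambda s: s.iloc[np.argmax(np.abs(s.to_numpy()))])
    out.loc[idx.index] = idx.to_numpy()
    return out
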