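"""Three-stage probe normalization for promoter ChIP-chip channels.

Stage 1 scales every (cell type, antibody) channel so its random-genomic
background probes share a common median (the grand median over channels).
Stage 2 forms the per-probe log2 ratio of a modification channel over the
matched H3 channel — controlling for nucleosome occupancy. Stage 3
subtracts the progenitor (monocyte) track from a differentiated track,
yielding per-probe gain/loss of the modification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class NormalizedTrack:
    """Per-probe log2 values for one modification in one cell type.

    mode='ratio' → log2(modification/H3) after background scaling;
    mode='delta' → difference of two ratio tracks (differentiation).
    """

    values: pd.Series  # index: probe_id
    cell_type: str
    modification: str
    mode: str = "ratio"

    def __post_init__(self):
        if self.mode not in ("ratio", "delta"):
            raise ValueError(f"unknown track mode {self.mode!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("track contains non-finite values")


def background_normalize(
    table: pd.DataFrame, background_mask: pd.Series
) -> pd.DataFrame:
    """Scale each channel so background-probe medians agree.

    The common reference is the grand median of all channels' background
    medians; each column is divided by (its background median / reference).
    Multiplicative by construction, so values stay positive.
    """
    mask = background_mask.reindex(table.index).fillna(False).astype(bool)
    if not mask.any():
        raise ValueError("no background probes in table")
    if (table.values <= 0).any():
        raise ValueError("intensities must be strictly positive")
    bg_medians = table.loc[mask].median(axis=0)
    reference = float(np.median(bg_medians.to_numpy()))
    factors = bg_medians / reference
    return table / factors


def h3_normalize(table: pd.DataFrame, cell_type: str, modification: str) -> NormalizedTrack:
    """Per-probe log2(modification) − log2(H3) for one cell type."""
    if (cell_type, "H3") not in table.columns:
        raise ValueError(f"missing H3 channel for {cell_type}")
    if (cell_type, modification) not in table.columns:
        raise ValueError(f"missing {modification} channel for {cell_type}")
    mod = table[(cell_type, modification)]
    h3 = table[(cell_type, "H3")]
    if (mod <= 0).any() or (h3 <= 0).any():
        raise ValueError("intensities must be strictly positive")
    values = np.log2(mod) - np.log2(h3)
    return NormalizedTrack(values=values, cell_type=cell_type, modification=modification)


def differentiation_delta(
    track_cell: NormalizedTrack, track_mo: NormalizedTrack
) -> NormalizedTrack:
    """Per-probe difference of two ratio tracks: positive = gain of the
    modification in the differentiated cell, negative = loss."""
    if track_cell.modification != track_mo.modification:
        raise ValueError("tracks carry different modifications")
    if not track_cell.values.index.equals(track_mo.values.index):
        raise ValueError("probe sets differ between tracks")
    return NormalizedTrack(
        values=track_cell.values - track_mo.values,
        cell_type=f"{track_cell.cell_type}-{track_mo.cell_type}",
        modification=track_cell.modification,
        mode="delta",
    )


def normalize_all(
    table: pd.DataFrame,
    background_mask: pd.Series,
    cell_types,
    modifications,
) -> dict:
    """Background-scale once, then H3-normalize every (cell, modification)
    channel. Returns {(cell_type, modification): NormalizedTrack}."""
    scaled = background_normalize(table, background_mask)
    return {
        (ct, mod): h3_normalize(scaled, ct, mod)
        for ct in cell_types
        for mod in modifications
    }
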