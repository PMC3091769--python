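"""Combinatorial promoter states and their statistics.

Three boolean mark calls (H3K4me3, AcH3, H3K27me3) per promoter define
one of eight states — from "none" through single marks and the active
H3K4me3/AcH3 double mark to the bivalent H3K4me3/H3K27me3 combination.
This module classifies states, tabulates their frequencies, computes
cross-mark Pearson correlations, and tests mark enrichment among the
most/least expressed genes with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MODIFICATIONS, STATES, STATE_BITS

_BITS_TO_STATE = {bits: name for name, bits in STATE_BITS.items()}


def classify_states(mark_calls: pd.DataFrame) -> pd.DataFrame:
    """Deterministic 3-bit → 8-state mapping per (gene, cell type).

    ``mark_calls`` holds one row per (gene_id, cell_type, modification)
    with a boolean ``marked``; all three modifications must be present
    for every (gene, cell type) pair.
    """
    wide = mark_calls.pivot_table(
        index=["gene_id", "cell_type"],
        columns="modification",
        values="marked",
        aggfunc="first",
    )
    missing = [m for m in MODIFICATIONS if m not in wide.columns]
    if missing or wide.isna().any().any():
        bad = missing or sorted(
            wide.index[wide.isna().any(axis=1)].get_level_values("gene_id").unique()
        )
        raise ValueError(f"missing modification calls: {bad}")
    state = [
        _BITS_TO_STATE[(bool(r["H3K4me3"]), bool(r["AcH3"]), bool(r["H3K27me3"]))]
        for _, r in wide.iterrows()
    ]
    out = wide.index.to_frame(index=False)
    out["state"] = state
    return out


def split_states(states: pd.DataFrame) -> pd.DataFrame:
    """Inverse of classify_states: expand each state into three boolean
    mark calls (round-trip identity)."""
    rows = []
    for r in states.itertuples(index=False):
        bits = STATE_BITS[r.state]
        for mod, flag in zip(MODIFICATIONS, bits):
            rows.append((r.gene_id, r.cell_type, mod, flag))
    return pd.DataFrame(rows, columns=["gene_id", "cell_type", "modification", "marked"])


def state_frequencies(states: pd.DataFrame, gene_subset=None) -> pd.Series:
    """Percentage of genes in each of the 8 states over a gene subset.

    Sums to 100 (up to rounding). Expects states for a single cell type
    or an explicit pre-filtered frame.
    """
    df = states
    if gene_subset is not None:
        subset = set(gene_subset)
        unknown = subset - set(states["gene_id"])
        if unknown:
            raise ValueError(f"genes not in universe: {sorted(unknown)[:5]}")
        df = states[states["gene_id"].isin(subset)]
    if df.empty:
        raise ValueError("empty gene subset")
    counts = df["state"].value_counts().reindex(STATES, fill_value=0)
    return counts / counts.sum() * 100.0


def mark_correlation(
    mark_calls: pd.DataFrame, use_scores: bool = False
) -> pd.DataFrame:
    """Pearson correlation across all (modification × cell type) pairs.

    Columns of the gene × (cell, mark) matrix are the boolean calls
    (default) or the continuous peak scores (``use_scores=True``, with
    unmarked genes at 0). Zero-variance columns yield NaN entries —
    flagged, not silently zeroed.
    """
    value_col = "score" if use_scores else "marked"
    wide = mark_calls.pivot_table(
        index="gene_id",
        columns=["cell_type", "modification"],
        values=value_col,
        aggfunc="first",
    )
    if use_scores:
        wide = wide.fillna(0.0)
    wide = wide.astype(float)
    if len(wide) < 3:
        raise ValueError("need at least 3 genes for correlation")
    corr = wide.corr(method="pearson")
    # pandas returns 1.0 on the diagonal even for constant columns; keep
    # the off-diagonal NaN flagging but make constant-vs-self explicit
    const = wide.std(axis=0) == 0
    for c in corr.columns[const]:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return corr


@dataclass
class EnrichmentResult:
    """Mark frequency among an expression-defined gene set."""

    modification: str
    set_label: str
    frequency: float  # percent of the set carrying the mark
    n_marked: int
    n_set: int


def expression_enrichment(
    mark_calls: pd.DataFrame,
    expression_ranks: pd.Series,
    modification: str,
    n: int = 2000,
    cell_type: str | None = None,
):
    """Mark frequency in the top-n vs bottom-n expressed genes, with a
    two-sided Fisher exact P from the 2×2 (top/bottom × marked/unmarked)
    table.

    ``expression_ranks`` maps gene_id → expression value; ties are
    broken by stable gene-id order. When ``mark_calls`` spans several
    cell types, ``cell_type`` selects one. Returns
    (top EnrichmentResult, bottom EnrichmentResult, p_value).
    """
    calls = mark_calls[mark_calls["modification"] == modification]
    if cell_type is not None:
        calls = calls[calls["cell_type"] == cell_type]
    if calls["gene_id"].duplicated().any():
        raise ValueError(
            "mark calls cover several cell types; pass cell_type to select one"
        )
    calls = calls.set_index("gene_id")["marked"]
    ranked = expression_ranks.loc[sorted(expression_ranks.index)]
    ranked = ranked.sort_values(ascending=False, kind="stable")
    if 2 * n > len(ranked):
        raise ValueError(f"n={n} exceeds half the universe ({len(ranked)} genes)")
    top = ranked.index[:n]
    bottom = ranked.index[-n:]
    t_marked = int(calls.loc[top].sum())
    b_marked = int(calls.loc[bottom].sum())
    table = [[t_marked, n - t_marked], [b_marked, n - b_marked]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    top_res = EnrichmentResult(modification, f"top-{n}", 100.0 * t_marked / n, t_marked, n)
    bot_res = EnrichmentResult(
        modification, f"bottom-{n}", 100.0 * b_marked / n, b_marked, n
    )
    return top_res, bot_res, float(p)


def expressed_gene_split(
    expression: pd.DataFrame, cell_type: str, quantile: float = 0.75
) -> tuple[list, list]:
    """Split genes into expressed / inactive by mean signal against a
    quantile threshold (default 75th percentile of the overall signal
    distribution, standing in for platform detection calls)."""
    mean_sig = expression[cell_type].mean(axis=1)
    thr = mean_sig.quantile(quantile)
    expressed = mean_sig.index[mean_sig > thr].tolist()
    inactive = mean_sig.index[mean_sig <= thr].tolist()
    return expressed, inactive
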