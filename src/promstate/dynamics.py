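"""Histone-mark state dynamics across differentiation.

Joint 8×8 contingency tables of promoter states between two cell
populations (progenitor → differentiated), and per-starting-state
persistence summaries such as the fraction of promoters that keep,
convert or lose a mark combination.
"""

from __future__ import annotations

import pandas as pd

from .simulate import STATES


def transitions(states_from: pd.DataFrame, states_to: pd.DataFrame) -> pd.DataFrame:
    """8×8 contingency of joint states over the shared gene universe.

    Rows = state in the first population, columns = state in the
    second. Genes present in only one input are excluded (the caller
    can diff the universes to count them).
    """
    a = states_from.set_index("gene_id")["state"]
    b = states_to.set_index("gene_id")["state"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("disjoint gene universes")
    joint = pd.crosstab(a.loc[common], b.loc[common])
    return joint.reindex(index=STATES, columns=STATES, fill_value=0)


def transition_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Row-normalized transition table; rows with zero genes are NaN."""
    totals = table.sum(axis=1)
    return table.div(totals.where(totals > 0), axis=0)


def persistence_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per starting state: genes at start, fraction retained, fraction
    converted to each other state, and the fraction that left the state
    (1 − retained). Undefined rows (no genes) carry NaN fractions."""
    frac = transition_fractions(table)
    out = pd.DataFrame(index=table.index)
    out["n_start"] = table.sum(axis=1)
    out["retained"] = pd.Series(
        {s: frac.loc[s, s] for s in table.index}, index=table.index
    )
    out["left"] = 1.0 - out["retained"]
    for s in table.columns:
        out[f"to_{s}"] = frac[s]
    return out


def k4_alone_fate(table: pd.DataFrame) -> float:
    """Fraction of promoters carrying H3K4me3 alone in the progenitor
    that either lost it or gained acetylation (moved to the K4+Ac
    double mark) in the differentiated population — the hallmark
    instability of the lone K4 mark."""
    row = table.loc["K4"]
    total = row.sum()
    if total == 0:
        raise ValueError("no genes start in state K4")
    moved = total - row["K4"]
    return float(moved / total)
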