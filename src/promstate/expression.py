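"""Expression-array normalization, differential calls and overlap
accounting.

Rank-invariant normalization scales each sample by the median signal
ratio over genes whose expression rank matches a reference sample.
Differential expression uses the study-style criterion: ≥2-fold change
of linear means and Welch P < 0.05 on log2 replicate values, with no
multiple-testing correction by default (a Benjamini–Hochberg flag is
provided for users who want one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def rank_invariant_normalize(
    matrix: pd.DataFrame,
    reference_column=None,
    rank_threshold_frac: float = 0.05,
    max_iter: int = 10,
) -> pd.DataFrame:
    """Scale each column to a reference using its rank-invariant gene set.

    Per column: genes whose rank differs from the reference by less
    than ``rank_threshold_frac`` × n_genes form the invariant set; the
    column is divided by the median column/reference signal ratio over
    that set, iterating until the factor converges (scaling preserves
    ranks, so this takes at most two passes).
    """
    if len(matrix) < 100:
        raise ValueError("need ≥100 genes for a stable rank-invariant set")
    if reference_column is None:
        reference_column = matrix.columns[0]
    ref = matrix[reference_column].astype(float)
    ref_rank = ref.rank(method="average")
    thr = rank_threshold_frac * len(matrix)
    out = matrix.astype(float).copy()
    for col in matrix.columns:
        if col == reference_column:
            continue
        values = out[col]
        for _ in range(max_iter):
            invariant = (values.rank(method="average") - ref_rank).abs() < thr
            if not invariant.any():
                raise ValueError(
                    f"empty rank-invariant set for column {col}; "
                    "increase rank_threshold_frac"
                )
            factor = float((values[invariant] / ref[invariant]).median())
            values = values / factor
            if abs(np.log(factor)) < 1e-12:
                break
        else:
            raise RuntimeError(f"rank-invariant scaling did not converge for {col}")
        out[col] = values
    return out


@dataclass
class DEResult:
    gene_id: str
    contrast: str
    fold_change: float
    p_value: float
    call: str  # up | down | unchanged


def call_differential(
    matrix: pd.DataFrame,
    cell_a: str,
    cell_b: str,
    fold: float = 2.0,
    alpha: float = 0.05,
    bh_correct: bool = False,
    welch: bool = False,
) -> pd.DataFrame:
    """Differential calls for cell_a vs cell_b.

    Fold change is the ratio of linear replicate means (a over b); the
    P value is a two-sided two-sample t test on log2 replicate values
    (pooled-variance by default — exact under a lognormal replicate
    model and correctly calibrated at small n, where the Welch variant
    is conservative; pass ``welch=True`` for unequal variances). A gene
    is 'up' iff fold ≥ ``fold`` and p < ``alpha``, 'down' iff fold ≤
    1/``fold`` and p < ``alpha``, else 'unchanged'.
    """
    a = matrix[cell_a].astype(float)
    b = matrix[cell_b].astype(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need ≥2 replicates per cell type")
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    floor = matrix.values[matrix.values > 0].min() if (matrix.values > 0).any() else 1.0
    if (mean_b <= 0).any() or (mean_a <= 0).any():
        warnings.warn("zero mean signal floored for fold-change computation")
        mean_a = mean_a.clip(lower=floor)
        mean_b = mean_b.clip(lower=floor)
    fc = mean_a / mean_b
    la = np.log2(a.clip(lower=floor))
    lb = np.log2(b.clip(lower=floor))
    _, p = stats.ttest_ind(la, lb, axis=1, equal_var=not welch)
    p = pd.Series(p, index=matrix.index)
    if bh_correct:
        order = np.argsort(p.to_numpy())
        m = len(p)
        adj = np.empty(m)
        ranked = p.to_numpy()[order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
        p = pd.Series(adj, index=p.index)
    call = np.where(
        (fc >= fold) & (p < alpha),
        "up",
        np.where((fc <= 1.0 / fold) & (p < alpha), "down", "unchanged"),
    )
    return pd.DataFrame(
        {
            "gene_id": matrix.index,
            "contrast": f"{cell_a} vs {cell_b}",
            "fold_change": fc.to_numpy(),
            "p_value": p.to_numpy(),
            "call": call,
        }
    ).reset_index(drop=True)


@dataclass
class OverlapTable:
    """Exclusive and shared differential-gene counts for two contrasts
    (e.g. macrophage vs monocyte and DC vs monocyte)."""

    up_a_only: int
    up_b_only: int
    up_shared: int
    down_a_only: int
    down_b_only: int
    down_shared: int

    def total(self, which: str, direction: str) -> int:
        """Total genes called in one contrast: exclusive + shared."""
        if direction == "up":
            only = self.up_a_only if which == "a" else self.up_b_only
            return only + self.up_shared
        if direction == "down":
            only = self.down_a_only if which == "a" else self.down_b_only
            return only + self.down_shared
        raise ValueError(f"unknown direction {direction!r}")

    def swapped(self) -> "OverlapTable":
        return OverlapTable(
            self.up_b_only,
            self.up_a_only,
            self.up_shared,
            self.down_b_only,
            self.down_a_only,
            self.down_shared,
        )


def overlap_table(de_a: pd.DataFrame, de_b: pd.DataFrame) -> OverlapTable:
    """Count exclusive and shared up/down genes between two contrasts
    over the same gene universe."""
    if set(de_a["gene_id"]) != set(de_b["gene_id"]):
        raise ValueError("contrasts cover different gene universes")
    a = de_a.set_index("gene_id")["call"]
    b = de_b.set_index("gene_id")["call"].reindex(a.index)
    counts = {}
    for direction in ("up", "down"):
        ina = a == direction
        inb = b == direction
        counts[direction] = (
            int((ina & ~inb).sum()),
            int((~ina & inb).sum()),
            int((ina & inb).sum()),
        )
    return OverlapTable(*counts["up"], *counts["down"])
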