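"""Synthetic promoter tiling-array and expression-array generator.

Emulates the design of a monocyte→macrophage/dendritic-cell promoter
ChIP-chip study: ~2.5 kb promoter tiles of 50-mer probes at 100 bp
spacing, four antibody channels (H3, H3K4me3, AcH3, H3K27me3), three
cell states with planted 3-bit histone-mark states and a transition
kernel describing differentiation, bimodal active-mark enrichment with
a dip at the TSS versus uniform repressive-mark enrichment, random
genomic background probes, and replicate expression values coupled to
the planted state.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import promoter_windows

#: The 8 combinatorial promoter states, indexed by the 3-bit pattern
#: (K4 = bit 0, Ac = bit 1, K27 = bit 2).
STATES = ["none", "K4", "Ac", "K27", "K4+Ac", "K4+K27", "Ac+K27", "K4+Ac+K27"]
STATE_BITS = {
    "none": (False, False, False),
    "K4": (True, False, False),
    "Ac": (False, True, False),
    "K27": (False, False, True),
    "K4+Ac": (True, True, False),
    "K4+K27": (True, False, True),
    "Ac+K27": (False, True, True),
    "K4+Ac+K27": (True, True, True),
}
MODIFICATIONS = ["H3K4me3", "AcH3", "H3K27me3"]
ANTIBODIES = ["H3"] + MODIFICATIONS

#: Monocyte state prior chosen so the single-mark marginals approximate
#: genome-wide promoter frequencies reported for human monocytes
#: (H3K4me3 ≈ 45%, AcH3 ≈ 30%, H3K27me3 ≈ 23–26%, no mark ≈ 36%,
#: K4∧Ac ≈ 26%, K4-alone ≈ 13%, K27-alone ≈ 16%). An emulation, not a fit.
DEFAULT_STATE_PRIORS = {
    "none": 0.36,
    "K4": 0.13,
    "Ac": 0.02,
    "K27": 0.16,
    "K4+Ac": 0.26,
    "K4+K27": 0.05,
    "Ac+K27": 0.01,
    "K4+Ac+K27": 0.01,
}

#: Differentiation kernel (rows = state in monocytes, columns = state in
#: the differentiated cell). Encodes the qualitative dynamics of the
#: system: the K4+Ac double mark persists; K4-alone and Ac-alone are
#: unstable (~75–85% leave, mostly to "none" or to the double mark);
#: K27-alone is stable; bivalent K4+K27 partially resolves.
DEFAULT_TRANSITION_KERNEL = pd.DataFrame(
    [
        # none   K4    Ac    K27  K4+Ac K4+K27 Ac+K27 triple
        [0.90, 0.02, 0.02, 0.02, 0.04, 0.00, 0.00, 0.00],  # none
        [0.40, 0.25, 0.05, 0.00, 0.30, 0.00, 0.00, 0.00],  # K4
        [0.60, 0.05, 0.15, 0.00, 0.20, 0.00, 0.00, 0.00],  # Ac
        [0.10, 0.00, 0.00, 0.85, 0.00, 0.05, 0.00, 0.00],  # K27
        [0.06, 0.08, 0.06, 0.00, 0.80, 0.00, 0.00, 0.00],  # K4+Ac
        [0.15, 0.15, 0.00, 0.20, 0.10, 0.40, 0.00, 0.00],  # K4+K27
        [0.20, 0.00, 0.20, 0.20, 0.00, 0.00, 0.40, 0.00],  # Ac+K27
        [0.00, 0.00, 0.00, 0.20, 0.20, 0.20, 0.00, 0.40],  # K4+Ac+K27
    ],
    index=STATES,
    columns=STATES,
)

#: Mean log2 expression per planted state. Ordering: active double mark
#: highest, single active marks next, bivalent poised intermediate,
#: unmarked low, K27-alone (silenced) lowest.
DEFAULT_EXPR_STATE_MEANS = {
    "K4+Ac": 10.0,
    "K4": 8.0,
    "Ac": 8.0,
    "K4+Ac+K27": 6.5,
    "K4+K27": 6.0,
    "Ac+K27": 5.5,
    "none": 5.0,
    "K27": 3.5,
}


@dataclass
class SimParams:
    """Parameters of the stated synthetic world.

    peak_height is the log2 enrichment of a marked promoter over H3;
    tss_dip_depth the fractional reduction of active-mark enrichment at
    the TSS (the bimodal dip); noise_sd / baseline_sd are log2-scale
    Gaussian standard deviations of the channel noise and the H3
    baseline; expr_state_means are mean log2 expression per state and
    expr_noise_sd the replicate sd on that scale.
    """

    n_genes: int = 2000
    n_chroms: int = 5
    cell_types: tuple[str, ...] = ("MO", "MF", "DC")
    state_priors: dict = field(default_factory=lambda: dict(DEFAULT_STATE_PRIORS))
    transition_kernel: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_TRANSITION_KERNEL.copy()
    )
    peak_height: float = 2.0
    tss_dip_depth: float = 0.6
    noise_sd: float = 0.3
    baseline_sd: float = 0.5
    baseline_geomean: float = 1000.0
    n_background_probes: int = 2000
    expr_state_means: dict = field(
        default_factory=lambda: dict(DEFAULT_EXPR_STATE_MEANS)
    )
    expr_noise_sd: float = 0.5
    n_replicates: int = 3
    seed: int = 0

    # promoter/probe geometry
    upstream: int = 2000
    downstream: int = 500
    probe_length: int = 50
    probe_spacing: int = 100
    # active-mark lobes, bp relative to the TSS (transcription direction)
    lobe_upstream: tuple[int, int] = (-800, -200)
    lobe_downstream: tuple[int, int] = (100, 400)

    def validate(self) -> "SimParams":
        if self.n_genes < 1 or self.n_chroms < 1:
            raise ValueError("n_genes and n_chroms must be positive")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 expression replicates")
        if self.noise_sd < 0 or self.baseline_sd < 0 or self.expr_noise_sd < 0:
            raise ValueError("noise sds must be nonnegative")
        pri = np.array([self.state_priors.get(s, 0.0) for s in STATES])
        if pri.min() < 0 or abs(pri.sum() - 1.0) > 1e-9:
            raise ValueError("state_priors must be a probability over the 8 states")
        kern = self.transition_kernel.loc[STATES, STATES].values
        if kern.min() < 0 or np.abs(kern.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("transition_kernel rows must each sum to 1")
        missing = set(STATES) - set(self.expr_state_means)
        if missing:
            raise ValueError(f"expr_state_means missing states: {sorted(missing)}")
        return self


@dataclass
class SimTruth:
    """Planted ground truth: per-gene per-cell-type state, planted
    enriched intervals per (gene, cell, modification), and the expected
    log2 expression mean per (gene, cell)."""

    states: pd.DataFrame  # gene_id, cell_type, state
    peaks: pd.DataFrame  # gene_id, cell_type, modification, chrom, start, end
    expr_means: pd.DataFrame  # gene_id, cell_type, log2_mean


def simulate_genome(n_genes: int, n_chroms: int, seed: int = 0) -> pd.DataFrame:
    """Gene annotation with non-overlapping promoter windows.

    Genes are laid out in 10 kb slots (round-robin blocks over
    chromosomes) with a jittered TSS at least 5 kb into the slot, so
    2.5 kb promoter windows can never collide; strands are ~50/50.
    """
    if n_genes < 1 or n_chroms < 1:
        raise ValueError("n_genes and n_chroms must be positive")
    rng = np.random.default_rng(seed)
    per_chrom = int(np.ceil(n_genes / n_chroms))
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    chroms, tsss = [], []
    for i in range(n_genes):
        c = i // per_chrom
        slot = i % per_chrom
        chroms.append(f"chr{c + 1}")
        tsss.append(5000 + slot * 10000 + int(rng.integers(0, 2000)))
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    return pd.DataFrame(
        {"gene_id": gene_ids, "chrom": chroms, "strand": strands, "tss": tsss}
    )


def tile_promoters(windows: pd.DataFrame, params: SimParams | None = None) -> pd.DataFrame:
    """Tile each promoter window with fixed-length probes at fixed spacing."""
    p = params or SimParams()
    rows = []
    for w in windows.itertuples(index=False):
        k = 0
        pos = w.start
        while pos + p.probe_length <= w.end:
            rows.append(
                (f"{w.gene_id}_p{k:02d}", w.chrom, pos, pos + p.probe_length, False, w.gene_id)
            )
            pos += p.probe_spacing
            k += 1
    return pd.DataFrame(
        rows, columns=["probe_id", "chrom", "start", "end", "is_background", "gene_id"]
    )


def add_background_probes(
    probes: pd.DataFrame, windows: pd.DataFrame, params: SimParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Append random-genomic background probes in the gaps between
    promoter windows (≥500 bp clear of any window)."""
    gaps = []
    for chrom, grp in windows.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        prev_end = 0
        for w in grp.itertuples(index=False):
            lo, hi = prev_end + 500, w.start - 500 - params.probe_length
            if hi > lo:
                gaps.append((chrom, lo, hi))
            prev_end = w.end
        gaps.append((chrom, prev_end + 500, prev_end + 5000))
    gaps_df = pd.DataFrame(gaps, columns=["chrom", "lo", "hi"])
    weights = (gaps_df["hi"] - gaps_df["lo"]).to_numpy(dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(gaps_df), size=params.n_background_probes, p=weights)
    rows = []
    for j, gi in enumerate(picks):
        g = gaps_df.iloc[gi]
        pos = int(rng.integers(g["lo"], g["hi"]))
        rows.append(
            (f"bg_{j:05d}", g["chrom"], pos, pos + params.probe_length, True, "")
        )
    bg = pd.DataFrame(
        rows, columns=["probe_id", "chrom", "start", "end", "is_background", "gene_id"]
    )
    return pd.concat([probes, bg], ignore_index=True)


def plant_states(annotation: pd.DataFrame, params: SimParams) -> pd.DataFrame:
    """Draw the per-gene 3-bit mark state for every cell type.

    The first cell type is drawn from ``state_priors``; every later cell
    type is drawn gene-wise from the first through ``transition_kernel``
    (both differentiated populations derive independently from the
    progenitor, as in a monocyte→macrophage / monocyte→DC design).
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    n = len(annotation)
    pri = np.array([params.state_priors[s] for s in STATES])
    first = rng.choice(len(STATES), size=n, p=pri)
    kern = params.transition_kernel.loc[STATES, STATES].to_numpy()
    out = {params.cell_types[0]: first}
    for ct in params.cell_types[1:]:
        nxt = np.empty(n, dtype=int)
        for s in range(len(STATES)):
            mask = first == s
            nxt[mask] = rng.choice(len(STATES), size=mask.sum(), p=kern[s])
        out[ct] = nxt
    rows = []
    for ct in params.cell_types:
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": annotation["gene_id"].to_numpy(),
                    "cell_type": ct,
                    "state": [STATES[i] for i in out[ct]],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _rel_positions(probes: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Signed probe-midpoint position relative to the owning gene's TSS
    (upstream negative, strand-aware)."""
    w = windows.set_index("gene_id")
    prom = probes[~probes["is_background"]].copy()
    mid = (prom["start"] + prom["end"]) // 2
    tss = w.loc[prom["gene_id"], "tss"].to_numpy()
    strand = w.loc[prom["gene_id"], "strand"].to_numpy()
    rel = np.where(strand == "+", mid - tss, tss - mid)
    prom["rel"] = rel
    return prom


def build_truth(
    annotation: pd.DataFrame, states: pd.DataFrame, params: SimParams
) -> SimTruth:
    """Assemble planted ground truth: enriched intervals per marked
    (gene, cell, modification) and expected log2 expression means."""
    windows = promoter_windows(annotation, params.upstream, params.downstream)
    w = windows.set_index("gene_id")
    peak_rows = []
    for row in states.itertuples(index=False):
        k4, ac, k27 = STATE_BITS[row.state]
        gw = w.loc[row.gene_id]
        for mod, flag in zip(MODIFICATIONS, (k4, ac, k27)):
            if not flag:
                continue
            if mod == "H3K27me3":
                lo, hi = int(gw["start"]), int(gw["end"])
            else:
                # enriched span covers both lobes and the dip between them
                a, b = params.lobe_upstream[0], params.lobe_downstream[1]
                if gw["strand"] == "+":
                    lo, hi = int(gw["tss"] + a), int(gw["tss"] + b)
                else:
                    lo, hi = int(gw["tss"] - b), int(gw["tss"] - a)
            peak_rows.append((row.gene_id, row.cell_type, mod, gw["chrom"], lo, hi))
    peaks = pd.DataFrame(
        peak_rows, columns=["gene_id", "cell_type", "modification", "chrom", "start", "end"]
    )
    em = states.copy()
    em["log2_mean"] = [params.expr_state_means[s] for s in em["state"]]
    expr_means = em.rename(columns={})[["gene_id", "cell_type", "log2_mean"]]
    return SimTruth(states=states, peaks=peaks, expr_means=expr_means)


def _enrichment_profile(rel: np.ndarray, mod: str, params: SimParams) -> np.ndarray:
    """Log2 enrichment at signed TSS-relative positions for one marked
    modification: two full-height lobes flanking a reduced-height dip for
    active marks, uniform across the window for H3K27me3."""
    if mod == "H3K27me3":
        return np.full(rel.shape, params.peak_height)
    lo_u, hi_u = params.lobe_upstream
    lo_d, hi_d = params.lobe_downstream
    in_lobe = ((rel >= lo_u) & (rel <= hi_u)) | ((rel >= lo_d) & (rel <= hi_d))
    in_dip = (rel > hi_u) & (rel < lo_d)
    out = np.zeros(rel.shape)
    out[in_lobe] = params.peak_height
    out[in_dip] = params.peak_height * (1.0 - params.tss_dip_depth)
    return out


def simulate_intensities(
    probes: pd.DataFrame,
    truth: SimTruth,
    params: SimParams,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Linear-scale probe intensities, columns (cell_type, antibody).

    The H3 channel is a lognormal baseline (geometric mean
    ``baseline_geomean``, log2-sd ``baseline_sd``) shared across cell
    types per probe; each modification channel multiplies the H3 signal
    by 2**(planted enrichment) and 2**(Gaussian log2 noise). Background
    probes carry baseline only.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    windows = promoter_windows(annotation, params.upstream, params.downstream)
    prom = _rel_positions(probes, windows)
    n = len(probes)
    probe_index = pd.Index(probes["probe_id"])
    pos_of = pd.Series(np.arange(n), index=probe_index)

    log2_base = np.log2(params.baseline_geomean) + rng.normal(0, params.baseline_sd, n)
    states_wide = truth.states.pivot(index="gene_id", columns="cell_type", values="state")

    cols = {}
    for ct in params.cell_types:
        h3_noise = rng.normal(0, params.noise_sd, n) if params.noise_sd > 0 else 0.0
        log2_h3 = log2_base + h3_noise
        cols[(ct, "H3")] = 2.0 ** log2_h3
        gene_states = states_wide[ct]
        for mod in MODIFICATIONS:
            enrich = np.zeros(n)
            st = gene_states.loc[prom["gene_id"]].to_numpy()
            bits = np.array([STATE_BITS[s][MODIFICATIONS.index(mod)] for s in st])
            rel = prom["rel"].to_numpy()
            prof = _enrichment_profile(rel, mod, params)
            idx = pos_of.loc[prom["probe_id"]].to_numpy()
            enrich[idx] = np.where(bits, prof, 0.0)
            noise = rng.normal(0, params.noise_sd, n) if params.noise_sd > 0 else 0.0
            cols[(ct, mod)] = 2.0 ** (log2_h3 + enrich + noise)
    table = pd.DataFrame(cols, index=probe_index)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["cell_type", "antibody"])
    return table


def simulate_expression(truth: SimTruth, params: SimParams) -> pd.DataFrame:
    """Replicate expression values, lognormal around the planted state
    mean: linear value = 2**(state mean + N(0, expr_noise_sd))."""
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 3]))
    wide = truth.expr_means.pivot(index="gene_id", columns="cell_type", values="log2_mean")
    cols = {}
    for ct in params.cell_types:
        mu = wide[ct].to_numpy()
        for r in range(1, params.n_replicates + 1):
            noise = (
                rng.normal(0, params.expr_noise_sd, len(mu))
                if params.expr_noise_sd > 0
                else 0.0
            )
            cols[(ct, f"r{r}")] = 2.0 ** (mu + noise)
    expr = pd.DataFrame(cols, index=wide.index)
    expr.columns = pd.MultiIndex.from_tuples(expr.columns, names=["cell_type", "replicate"])
    return expr


def simulate_all(params: SimParams):
    """Run the full generator: annotation, probes, truth, intensities,
    expression. Returns (annotation, probes, truth, intensities, expr)."""
    params.validate()
    annotation = simulate_genome(params.n_genes, params.n_chroms, params.seed)
    windows = promoter_windows(annotation, params.upstream, params.downstream)
    probes = tile_promoters(windows, params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 4]))
    probes = add_background_probes(probes, windows, params, rng)
    states = plant_states(annotation, params)
    truth = build_truth(annotation, states, params)
    intens = simulate_intensities(probes, truth, params, annotation)
    expr = simulate_expression(truth, params)
    return annotation, probes, truth, intens, expr
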