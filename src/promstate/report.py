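"""Integrated reporting and the end-to-end pipeline driver.

Combines the per-stage modules into one seeded run over synthetic (or
user-supplied) data and assembles the integrated gene-group and
cluster-level summaries that relate promoter mark states to expression.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_io
from .assign import assign_peaks
from .dynamics import persistence_summary, transitions
from .expression import call_differential, overlap_table, rank_invariant_normalize
from .normalize import differentiation_delta, normalize_all
from .peaks import call_peaks, gene_delta_score
from .simulate import MODIFICATIONS, STATE_BITS, SimParams, simulate_all
from .states import classify_states, state_frequencies

logger = logging.getLogger("promstate")


def gene_group_matrix(
    gene_list, states: pd.DataFrame, expression: pd.DataFrame, cell_type: str
) -> pd.DataFrame:
    """Per-gene grid of expression band and mark flags for one cell type.

    Expression bands are quartiles (low, mid-low, mid-high, high) of
    the cell type's mean normalized signal over all genes. Unknown gene
    ids raise, they are never dropped silently.
    """
    st = states[states["cell_type"] == cell_type].set_index("gene_id")["state"]
    mean_sig = expression[cell_type].mean(axis=1)
    unknown = [g for g in gene_list if g not in st.index or g not in mean_sig.index]
    if unknown:
        raise ValueError(f"unknown gene ids: {unknown[:5]}")
    qs = mean_sig.quantile([0.25, 0.5, 0.75])
    bands = ["low", "mid-low", "mid-high", "high"]
    rows = []
    for g in gene_list:
        k4, ac, k27 = STATE_BITS[st.loc[g]]
        sig = mean_sig.loc[g]
        band = bands[int(np.searchsorted(qs.to_numpy(), sig, side="right"))]
        rows.append((g, cell_type, band, k4, ac, k27))
    out = pd.DataFrame(
        rows, columns=["gene_id", "cell_type", "band", "K4", "Ac", "K27"]
    )
    out.attrs["n_double_marked"] = int((out["K4"] & out["Ac"]).sum())
    return out


def cluster_delta_summary(
    clusters: dict, delta_scores: pd.Series, de_results: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster gain fraction of a delta track and concordance with
    differential-expression direction.

    ``clusters`` maps label → gene list; gain fraction is the share of
    members with positive delta score; concordance the share whose
    delta sign matches their DE call (up↔gain, down↔loss).
    """
    de = de_results.set_index("gene_id")["call"]
    rows = []
    for label, members in clusters.items():
        if len(members) == 0:
            raise ValueError(f"empty cluster {label!r}")
        missing = [g for g in members if g not in delta_scores.index]
        if missing:
            raise ValueError(f"cluster {label!r}: unknown genes {missing[:5]}")
        deltas = delta_scores.loc[members]
        called = deltas.dropna()
        gain_frac = float((called > 0).mean()) if len(called) else np.nan
        conc = np.nan
        dirs = de.reindex(members)
        decided = dirs.isin(["up", "down"]) & deltas.notna()
        if decided.any():
            match = (
                ((dirs == "up") & (deltas > 0)) | ((dirs == "down") & (deltas < 0))
            )[decided]
            conc = float(match.mean())
        rows.append((label, len(members), gain_frac, conc))
    return pd.DataFrame(
        rows, columns=["cluster", "n_genes", "gain_fraction", "de_concordance"]
    )


def chip_mark_calls(
    intensities: pd.DataFrame,
    probes: pd.DataFrame,
    windows: pd.DataFrame,
    cell_types,
    min_probes: int = 4,
    fdr: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
):
    """Normalize, call peaks and assign marks for every (cell type,
    modification) channel. Returns (mark_calls, tracks, peaks_by_key)."""
    bg_mask = probes.set_index("probe_id")["is_background"]
    tracks = normalize_all(intensities, bg_mask, cell_types, MODIFICATIONS)
    calls, peaks_by_key = [], {}
    for i, ((ct, mod), track) in enumerate(sorted(tracks.items())):
        pk = call_peaks(
            track,
            probes,
            windows,
            min_probes=min_probes,
            fdr=fdr,
            n_permutations=n_permutations,
            seed=seed * 1009 + i,
        )
        peaks_by_key[(ct, mod)] = pk
        calls.append(assign_peaks(pk, windows, cell_type=ct, modification=mod))
    return pd.concat(calls, ignore_index=True), tracks, peaks_by_key


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config, outdir, seed: int | None = None) -> dict:
    """Execute the full synthetic pipeline and write all stage outputs.

    ``config`` is a YAML path or a dict with an optional ``simulate``
    section of SimParams overrides. Stages: simulate → normalize →
    callpeaks → assign → states → dynamics → express → report. Writes a
    manifest (JSON) listing every output file with a checksum, the
    parameters and the seed. Returns the manifest dict.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)

    sim_cfg = dict(config.get("simulate", {}))
    if seed is not None:
        sim_cfg["seed"] = seed
    params = SimParams(**sim_cfg).validate()
    stage = "simulate"
    try:
        logger.info("stage %s", stage)
        annotation, probes, truth, intensities, expression = simulate_all(params)
        windows = ann_io.promoter_windows(annotation, params.upstream, params.downstream)
        ann_io.write_annotation(annotation, outdir / "annotation.tsv")
        ann_io.write_probes_bed(probes, outdir / "probes.bed")
        ann_io.write_intensities(intensities, outdir / "intensities.tsv")
        ann_io.write_expression(expression, outdir / "expression.tsv")
        truth.states.to_csv(outdir / "truth_states.tsv", sep="\t", index=False)

        stage = "normalize/callpeaks/assign"
        logger.info("stage %s", stage)
        n_perm = int(config.get("n_permutations", 200))
        mark_calls, tracks, peaks_by_key = chip_mark_calls(
            intensities,
            probes,
            windows,
            params.cell_types,
            n_permutations=n_perm,
            seed=params.seed,
        )
        mark_calls.to_csv(outdir / "mark_calls.tsv", sep="\t", index=False)
        for (ct, mod), pk in peaks_by_key.items():
            ann_io.write_peaks_bed(pk, outdir / f"peaks_{ct}_{mod}.bed")

        stage = "states"
        logger.info("stage %s", stage)
        states = classify_states(mark_calls)
        states.to_csv(outdir / "states.tsv", sep="\t", index=False)
        freq = pd.DataFrame(
            {
                ct: state_frequencies(states[states["cell_type"] == ct])
                for ct in params.cell_types
            }
        )
        freq.to_csv(outdir / "state_frequencies.tsv", sep="\t", index_label="state")

        stage = "dynamics"
        logger.info("stage %s", stage)
        mo = params.cell_types[0]
        for ct in params.cell_types[1:]:
            tab = transitions(
                states[states["cell_type"] == mo], states[states["cell_type"] == ct]
            )
            tab.to_csv(outdir / f"transitions_{mo}_{ct}.tsv", sep="\t")
            persistence_summary(tab).to_csv(
                outdir / f"persistence_{mo}_{ct}.tsv", sep="\t"
            )

        stage = "express"
        logger.info("stage %s", stage)
        flat = expression.copy()
        flat.columns = [f"{c}:{r}" for c, r in flat.columns]
        norm = rank_invariant_normalize(flat)
        norm.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split(":")) for c in norm.columns], names=["cell_type", "replicate"]
        )
        de = {}
        for ct in params.cell_types[1:]:
            d = call_differential(norm, ct, mo)
            d.to_csv(outdir / f"de_{ct}_vs_{mo}.tsv", sep="\t", index=False)
            de[ct] = d
        if len(de) == 2:
            a, b = (de[ct] for ct in params.cell_types[1:])
            ov = overlap_table(a, b)
            pd.DataFrame([ov.__dict__]).to_csv(
                outdir / "overlap_table.tsv", sep="\t", index=False
            )

        stage = "report"
        logger.info("stage %s", stage)
        delta_scores = {}
        for ct in params.cell_types[1:]:
            delta = differentiation_delta(tracks[(ct, "H3K4me3")], tracks[(mo, "H3K4me3")])
            delta_scores[ct] = gene_delta_score(delta, probes, windows)
            delta_scores[ct].to_csv(outdir / f"delta_scores_{ct}.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001 - abort names the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": params.seed,
        "parameters": {
            k: v
            for k, v in params.__dict__.items()
            if isinstance(v, (int, float, str, tuple, list))
        },
        "files": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return manifest
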