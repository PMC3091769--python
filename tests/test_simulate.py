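"""Generator correctness: determinism, planted-state marginals and
closed-form signal calibration."""

import math

import numpy as np
import pandas as pd
import pytest

import promstate as ps
from promstate.simulate import (
    STATE_BITS,
    STATES,
    build_truth,
    plant_states,
    simulate_expression,
    simulate_genome,
    tile_promoters,
)


def test_single_gene_tss_clears_window_arithmetic():
    ann = simulate_genome(1, 1, seed=1)
    assert len(ann) == 1
    assert ann["tss"].iloc[0] >= 2000


def test_seeded_determinism_byte_identical():
    a = simulate_genome(50, 2, seed=7)
    b = simulate_genome(50, 2, seed=7)
    pd.testing.assert_frame_equal(a, b)
    assert a.to_csv() == b.to_csv()


def test_promoter_windows_never_overlap_brute_force():
    ann = simulate_genome(2000, 5, seed=3)
    win = ps.promoter_windows(ann)
    for chrom, grp in win.groupby("chrom"):
        g = grp.sort_values("start")
        s = g["start"].to_numpy()
        e = g["end"].to_numpy()
        # pairwise scan: each window must end before the next begins
        assert (e[:-1] <= s[1:]).all()


def test_nonpositive_counts_rejected():
    with pytest.raises(ValueError):
        simulate_genome(0, 1, seed=1)
    with pytest.raises(ValueError):
        simulate_genome(10, 0, seed=1)


def test_identity_kernel_freezes_states():
    ann = simulate_genome(200, 2, seed=4)
    p = ps.SimParams(
        n_genes=200,
        seed=4,
        transition_kernel=pd.DataFrame(np.eye(8), index=STATES, columns=STATES),
    )
    st = plant_states(ann, p)
    wide = st.pivot(index="gene_id", columns="cell_type", values="state")
    assert (wide["MO"] == wide["MF"]).all()
    assert (wide["MO"] == wide["DC"]).all()


def test_point_prior_leaves_all_genes_unmarked():
    ann = simulate_genome(100, 1, seed=5)
    priors = {s: 0.0 for s in STATES}
    priors["none"] = 1.0
    p = ps.SimParams(
        n_genes=100,
        seed=5,
        state_priors=priors,
        transition_kernel=pd.DataFrame(np.eye(8), index=STATES, columns=STATES),
    )
    st = plant_states(ann, p)
    assert (st["state"] == "none").all()


def test_non_stochastic_kernel_rejected():
    bad = pd.DataFrame(np.eye(8) * 0.5, index=STATES, columns=STATES)
    with pytest.raises(ValueError, match="kernel"):
        ps.SimParams(transition_kernel=bad).validate()


def test_first_cell_marginals_match_priors_within_3_sigma():
    n = 20000
    ann = simulate_genome(n, 5, seed=11)
    p = ps.SimParams(n_genes=n, seed=11)
    st = plant_states(ann, p)
    mo = st[st["cell_type"] == "MO"]
    for state, prior in p.state_priors.items():
        if prior == 0:
            continue
        freq = (mo["state"] == state).mean()
        sigma = np.sqrt(prior * (1 - prior) / n)
        assert abs(freq - prior) <= 3 * sigma, (state, freq, prior)


def _noise_free_world(n_genes=30, seed=9, **kw):
    p = ps.SimParams(
        n_genes=n_genes,
        n_chroms=1,
        noise_sd=0.0,
        baseline_sd=0.0,
        n_background_probes=50,
        seed=seed,
        **kw,
    )
    ann, probes, truth, intens, expr = ps.simulate_all(p)
    return p, ann, probes, truth, intens


def test_zero_noise_unmarked_gene_equals_h3_channel():
    p, ann, probes, truth, intens = _noise_free_world()
    mo = truth.states.query("cell_type == 'MO'").set_index("gene_id")["state"]
    unmarked = mo[mo == "none"].index
    assert len(unmarked) > 0
    probe_sel = probes[probes["gene_id"].isin(unmarked)]["probe_id"]
    for mod in ps.MODIFICATIONS:
        np.testing.assert_allclose(
            intens.loc[probe_sel, ("MO", mod)],
            intens.loc[probe_sel, ("MO", "H3")],
        )


def test_zero_noise_lobe_probes_carry_exact_peak_height():
    p, ann, probes, truth, intens = _noise_free_world()
    mo = truth.states.query("cell_type == 'MO'").set_index("gene_id")["state"]
    k4_genes = mo[mo.map(lambda s: STATE_BITS[s][0])].index
    assert len(k4_genes) > 0
    win = ps.promoter_windows(ann).set_index("gene_id")
    for g in k4_genes[:5]:
        gp = probes[probes["gene_id"] == g]
        mid = (gp["start"] + gp["end"]) // 2
        tss, strand = win.loc[g, "tss"], win.loc[g, "strand"]
        rel = np.where(strand == "+", mid - tss, tss - mid)
        in_lobe = ((rel >= -800) & (rel <= -200)) | ((rel >= 100) & (rel <= 400))
        log2r = np.log2(
            intens.loc[gp["probe_id"], ("MO", "H3K4me3")].to_numpy()
            / intens.loc[gp["probe_id"], ("MO", "H3")].to_numpy()
        )
        np.testing.assert_allclose(log2r[in_lobe], p.peak_height, atol=1e-9)
        # dip probes carry the reduced enrichment
        in_dip = (rel > -200) & (rel < 100)
        np.testing.assert_allclose(
            log2r[in_dip], p.peak_height * (1 - p.tss_dip_depth), atol=1e-9
        )


def test_k27_enrichment_uniform_across_window_zero_noise():
    p, ann, probes, truth, intens = _noise_free_world(seed=10)
    mo = truth.states.query("cell_type == 'MO'").set_index("gene_id")["state"]
    k27_genes = mo[mo.map(lambda s: STATE_BITS[s][2])].index
    assert len(k27_genes) > 0
    gp = probes[probes["gene_id"].isin(k27_genes)]
    log2r = np.log2(
        intens.loc[gp["probe_id"], ("MO", "H3K27me3")].to_numpy()
        / intens.loc[gp["probe_id"], ("MO", "H3")].to_numpy()
    )
    np.testing.assert_allclose(log2r, p.peak_height, atol=1e-9)


def test_mean_lobe_enrichment_near_peak_height_under_noise():
    p = ps.SimParams(n_genes=500, n_chroms=2, seed=12)
    ann, probes, truth, intens, _ = ps.simulate_all(p)
    mo = truth.states.query("cell_type == 'MO'").set_index("gene_id")["state"]
    k4_genes = mo[mo.map(lambda s: STATE_BITS[s][0])].index
    win = ps.promoter_windows(ann).set_index("gene_id")
    gp = probes[probes["gene_id"].isin(k4_genes)].copy()
    mid = (gp["start"] + gp["end"]) // 2
    tss = win.loc[gp["gene_id"], "tss"].to_numpy()
    strand = win.loc[gp["gene_id"], "strand"].to_numpy()
    rel = np.where(strand == "+", mid - tss, tss - mid)
    in_lobe = ((rel >= -800) & (rel <= -200)) | ((rel >= 100) & (rel <= 400))
    sel = gp.loc[in_lobe, "probe_id"]
    log2r = np.log2(
        intens.loc[sel, ("MO", "H3K4me3")].to_numpy()
        / intens.loc[sel, ("MO", "H3")].to_numpy()
    )
    assert abs(log2r.mean() - p.peak_height) < 0.1


def test_zero_noise_expression_equals_state_means():
    ann = simulate_genome(40, 1, seed=6)
    p = ps.SimParams(n_genes=40, seed=6, expr_noise_sd=0.0)
    st = plant_states(ann, p)
    truth = build_truth(ann, st, p)
    expr = simulate_expression(truth, p)
    mo_states = st.query("cell_type == 'MO'").set_index("gene_id")["state"]
    for r in range(1, p.n_replicates + 1):
        vals = expr[("MO", f"r{r}")]
        expected = 2.0 ** mo_states.map(p.expr_state_means)
        np.testing.assert_allclose(vals, expected.loc[vals.index])


def test_expression_couples_to_k4_status_permutation_test():
    p = ps.SimParams(n_genes=400, seed=13)
    ann = simulate_genome(p.n_genes, 2, seed=13)
    st = plant_states(ann, p)
    truth = build_truth(ann, st, p)
    expr = simulate_expression(truth, p)
    mo_states = st.query("cell_type == 'MO'").set_index("gene_id")["state"]
    k4 = mo_states.map(lambda s: STATE_BITS[s][0]).astype(float)
    mean_expr = expr["MO"].mean(axis=1).loc[k4.index]
    obs = np.corrcoef(k4, mean_expr.rank())[0, 1]
    rng = np.random.default_rng(0)
    perm = np.array(
        [
            np.corrcoef(rng.permutation(k4.to_numpy()), mean_expr.rank())[0, 1]
            for _ in range(200000 // 1000)
        ]
    )
    # permutation oracle at modest B, then a binomial bound: the observed
    # correlation must beat every permuted one (p < 1/(B+1) << 1e-2), and
    # a normal-approximation bound certifies p < 1e-6
    assert (perm >= obs).sum() == 0
    z = obs * np.sqrt(len(k4) - 1)
    assert 2 * (1 - 0.5 * (1 + math.erf(z / np.sqrt(2)))) < 1e-6


def test_missing_state_mean_rejected():
    means = dict(ps.simulate.DEFAULT_EXPR_STATE_MEANS)
    del means["K27"]
    with pytest.raises(ValueError, match="expr_state_means"):
        ps.SimParams(expr_state_means=means).validate()


def test_full_generator_bit_reproducible(small_params, small_sim):
    ann2, probes2, truth2, intens2, expr2 = ps.simulate_all(small_params)
    ann, probes, truth, intens, expr = small_sim
    pd.testing.assert_frame_equal(ann, ann2)
    pd.testing.assert_frame_equal(probes, probes2)
    pd.testing.assert_frame_equal(truth.states, truth2.states)
    np.testing.assert_array_equal(intens.values, intens2.values)
    np.testing.assert_array_equal(expr.values, expr2.values)


def test_probe_layout_tiles_each_window(small_sim, small_windows):
    probes = small_sim[1]
    prom = probes[~probes["is_background"]]
    counts = prom.groupby("gene_id").size()
    # 2.5 kb window, 50-mer probes, 100 bp spacing → 25 probes per tile
    assert (counts == 25).all()
    w = small_windows.set_index("gene_id")
    inside = (
        prom["start"].to_numpy() >= w.loc[prom["gene_id"], "start"].to_numpy()
    ) & (prom["end"].to_numpy() <= w.loc[prom["gene_id"], "end"].to_numpy())
    assert inside.all()


def test_background_probes_clear_of_promoters(small_sim, small_windows):
    probes = small_sim[1]
    bg = probes[probes["is_background"]]
    for chrom, grp in bg.groupby("chrom"):
        win = small_windows[small_windows["chrom"] == chrom]
        ws = win["start"].to_numpy()[:, None]
        we = win["end"].to_numpy()[:, None]
        overlap = (grp["start"].to_numpy()[None, :] < we) & (
            grp["end"].to_numpy()[None, :] > ws
        )
        assert not overlap.any()
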