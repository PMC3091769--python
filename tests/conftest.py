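import pandas as pd
import pytest

import promstate as ps


@pytest.fixture(scope="session")
def small_params():
    """Compact synthetic world: 400 genes, default signal parameters."""
    return ps.SimParams(n_genes=400, n_chroms=3, n_background_probes=600, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_params):
    """(annotation, probes, truth, intensities, expression) at 400 genes."""
    return ps.simulate_all(small_params)


@pytest.fixture(scope="session")
def small_windows(small_sim):
    annotation = small_sim[0]
    return ps.promoter_windows(annotation)


@pytest.fixture(scope="session")
def small_tracks(small_sim, small_params):
    """Background-scaled, H3-normalized tracks for every channel."""
    _, probes, _, intensities, _ = small_sim
    bg = probes.set_index("probe_id")["is_background"]
    return ps.normalize_all(
        intensities, bg, small_params.cell_types, ps.MODIFICATIONS
    )


def make_mark_calls(states_df):
    """Expand a states frame back into per-modification boolean calls."""
    return ps.split_states(states_df)


@pytest.fixture()
def three_gene_annotation():
    return pd.DataFrame(
        {
            "gene_id": ["a", "b", "c"],
            "chrom": ["chr1", "chr1", "chr2"],
            "strand": ["+", "-", "+"],
            "tss": [10000, 10000, 3000],
        }
    )
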