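"""Shared fixtures: the standard planted benchmark and its similarity graphs."""

import numpy as np
import pytest

from geel import SyntheticDatasetSpec, generate_dataset
from geel.similarity import lns_similarity, spectrum_matrix, topk_neighbor_graph


def build_benchmark(seed: int):
    """Standard planted benchmark (60 lncRNAs, 30 miRNAs, 3 blocks,
    within=0.5, cross=0.02, mutation 0.05) plus its LNS kNN graphs."""
    spec = SyntheticDatasetSpec(seed=seed)
    records, inter, blocks = generate_dataset(spec)
    lnc = [r for r in records if r.kind == "lncRNA"]
    mir = [r for r in records if r.kind == "miRNA"]
    W_l = topk_neighbor_graph(lns_similarity(spectrum_matrix(lnc)), 10)
    W_m = topk_neighbor_graph(lns_similarity(spectrum_matrix(mir)), 10)
    return {
        "spec": spec,
        "records": records,
        "lnc": lnc,
        "mir": mir,
        "inter": inter,
        "blocks": blocks,
        "W_l": W_l,
        "W_m": W_m,
    }


@pytest.fixture(scope="session")
def benchmark():
    return build_benchmark(seed=1)


@pytest.fixture(scope="session")
def small_graph():
    """Symmetric 6-node weighted test graph (connected)."""
    rng = np.random.default_rng(3)
    H = rng.random((6, 6))
    H = (H + H.T) / 2
    np.fill_diagonal(H, 0.0)
    H[H < 0.3] = 0.0
    # ensure connectivity via a ring
    for i in range(6):
        j = (i + 1) % 6
        H[i, j] = H[j, i] = max(H[i, j], 0.5)
    return H
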