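import numpy as np
import pytest

from epp.errors import WidenSignal
from epp.kde import compute_weights, kde_dct, kde_variance
from epp.modal_clustering import build_cluster_graph, modal_cluster, noise_floor
from epp.dbm_merging import dbm_merge
from epp.synthetic import make_fixture


@pytest.fixture(scope="session")
def two_blobs_small():
    """two_blobs at n = 8000: enough for clean recovery, fast to gate."""
    return make_fixture("two_blobs", n=8000, seed=11)


def run_pipeline_to_dbm(x, y, n, W=0.01, grid_size=257, sigma=3.0, z=3.0):
    """Single pass weights -> KDE -> floor -> clustering -> graph -> DBM.

    Returns the merged face count, or None when the pass yields no usable
    clustering (too few events, widening requested, single mode).
    """
    w = compute_weights(x, y, grid_size)
    d = kde_dct(w, W)
    floor = noise_floor(d, w, W, sigma)
    if not np.isfinite(floor):
        return None
    try:
        lab = modal_cluster(d, floor)
        if lab.n_clusters < 2:
            return 1 if lab.n_clusters else None
        graph = build_cluster_graph(lab, d)
    except WidenSignal:
        return None
    merged = dbm_merge(graph, lab, d, kde_variance(w, W), n, z=z)
    return merged.n_faces
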