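import numpy as np
import pytest

import nichedecay as nd

#: Seed of the canonical worked example used across recovery tests.
DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_run():
    """One full default-condition simulation and analysis, shared by the
    recovery and conservation tests (everything downstream is read-only)."""
    config = nd.SimulationConfig(seed=DEFAULT_SEED)
    bundle, truth = nd.generate_bundle(config)
    matrix = bundle["matrix"]
    model = nd.pca_fit(matrix, n_components=2)
    eps = nd.auto_eps(model.scores, min_pts=2)
    assignment = nd.binarise(nd.dbscan(model.scores, eps, min_pts=2,
                                       site_ids=matrix.site_ids))
    stats_df, class_counts = nd.volcano_table(matrix, assignment.binary_labels)
    dists = nd.pairwise_distances(bundle["sites"])
    decay_df = nd.decay_table(matrix, dists, assignment)
    return {
        "config": config,
        "bundle": bundle,
        "truth": truth,
        "matrix": matrix,
        "model": model,
        "assignment": assignment,
        "stats": stats_df,
        "class_counts": class_counts,
        "dists": dists,
        "decay": decay_df,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
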