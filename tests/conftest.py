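import numpy as np
import pytest

from mircluster.clustering import assign_clusters, name_clusters
from mircluster.io_types import ExpressionMatrix
from mircluster.preprocess import detection_filter, normalize_global_mean
from mircluster.synthetic import locus_labels, paper_default_config, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated 21+21 cohort under the default configuration."""
    config = paper_default_config(seed=11)
    ct, annotations, metadata, truth = simulate_cohort(config)
    return {
        "config": config,
        "ct": ct,
        "annotations": annotations,
        "metadata": metadata,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_cluster_map(default_cohort):
    cmap = assign_clusters(default_cohort["annotations"])
    return name_clusters(cmap, locus_labels(default_cohort["config"]))


@pytest.fixture(scope="session")
def default_expression(default_cohort):
    expr = normalize_global_mean(default_cohort["ct"])
    return detection_filter(expr, 30)


def raw_expression(truth, min_detected=30):
    """ExpressionMatrix built from the generator's −∆CT truth (censor mask
    applied, no per-sample centering)."""
    expr = ExpressionMatrix(
        sample_ids=list(truth.dct.index),
        mirna_ids=list(truth.dct.columns),
        dct=truth.dct.to_numpy(),
        missing=truth.censored.to_numpy(),
    )
    return detection_filter(expr, min_detected)


@pytest.fixture
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(2024)
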