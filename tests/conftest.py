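import numpy as np
import pytest

from csfnet.containers import AbundanceMatrix
from csfnet.simulate import generate_discovery_cohort


@pytest.fixture(scope="session")
def planted_small():
    """Small planted cohort: 3 modules of 40 among 200 proteins, 60 samples."""
    return generate_discovery_cohort(
        n_proteins=200, n_samples=60, module_sizes=(40, 40, 40), seed=1
    )


@pytest.fixture(scope="session")
def planted_default():
    """The default synthetic discovery cohort (800 x 140, 8 modules)."""
    return generate_discovery_cohort(seed=7)


@pytest.fixture(scope="session")
def noise_matrix():
    rng = np.random.default_rng(0)
    return AbundanceMatrix(
        rng.standard_normal((200, 60)),
        [f"N{i:03d}" for i in range(200)],
        [f"NG{i:03d}" for i in range(200)],
        [f"S{j:02d}" for j in range(60)],
    )


@pytest.fixture(scope="session")
def network_result(planted_default):
    """Full network chain on the default cohort: detect, merge, reassign."""
    from csfnet.network import (build_network, cluster_dendrogram, detect_modules,
                                enforce_kme_consistency, merge_close_modules)

    matrix, metadata, truth = planted_default
    net = build_network(matrix)
    linkage, d = cluster_dendrogram(net.tom)
    detected = detect_modules(linkage, d, matrix.protein_ids)
    merged = merge_close_modules(matrix, detected)
    final = enforce_kme_consistency(matrix, merged)
    return {
        "matrix": matrix, "metadata": metadata, "truth": truth,
        "network": net, "linkage": linkage, "dissimilarity": d,
        "detected": detected, "merged": merged, "final": final,
    }


def ari(labels_a, labels_b) -> float:
    from sklearn.metrics import adjusted_rand_score
    return adjusted_rand_score(labels_a, labels_b)
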