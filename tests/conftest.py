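import numpy as np
import pytest

from igc2n.core_io import CandidateLocus, CNClassModel, IntensityMatrix, MarkerMap


@pytest.fixture
def tiny_map():
    return MarkerMap(
        np.array(["m1", "m2", "m3", "m4"], dtype=object),
        np.array(["1", "1", "1", "1"], dtype=object),
        np.array([100, 200, 300, 400]),
    )


@pytest.fixture
def tiny_matrix(tiny_map):
    values = np.array(
        [
            [0.0, -1.2, 0.1, 0.0],
            [0.4, 0.1, -0.05, 0.02],
        ]
    )
    return IntensityMatrix(["s1", "s2"], values)


def make_model(centers, weights, labels, variances=None, family="gaussian"):
    """Convenience constructor for hand-built CN class models."""
    centers = np.asarray(centers, dtype=float)
    weights = np.asarray(weights, dtype=float)
    variances = (
        np.asarray(variances, dtype=float)
        if variances is not None
        else np.full(len(centers), 0.01)
    )
    return CNClassModel(
        centers=centers,
        variances=variances,
        weights=weights / weights.sum(),
        labels=np.asarray(labels, dtype=np.int64),
        family=family,
        n_comp=len(centers),
        bic=0.0,
        converged=True,
    )


def labels_for_counts(counts):
    """Label vector [0]*c0 + [1]*c1 + ..."""
    return np.concatenate([np.full(c, k, dtype=np.int64) for k, c in enumerate(counts)])
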