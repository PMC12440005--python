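import numpy as np
import pytest

import s3reg as s


@pytest.fixture
def path_graph4() -> s.SpatialGraph:
    """Four collinear unit-spaced points: the path graph 0-1-2-3."""
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
    return s.build_knn_graph(coords, k=1)


@pytest.fixture
def tiny_dataset() -> s.SpatialDataset:
    """n=2, p=1 section with unit predictor, used for hand-computed objectives."""
    return s.SpatialDataset(
        spot_ids=["a", "b"],
        coords=np.array([[0.0, 0.0], [1.0, 0.0]]),
        response=np.array([1.0, 2.0]),
        predictors=np.array([[1.0], [1.0]]),
        predictor_names=["x"],
    )


@pytest.fixture
def small_sim():
    """A small simulated section shared by several fitting tests."""
    return s.simulate_dataset(n=60, p=3, n_active=2, n_clusters=2, seed=0)
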