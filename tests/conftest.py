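import numpy as np
import pytest

from morphoflow import synthdata
from morphoflow.velocimetry import PivParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_piv_params():
    """Windows sized for quick tests on small volumes."""
    return PivParams(window=(16, 16, 5), overlap=(4, 4, 1), search_margin=(5, 5, 2))


@pytest.fixture(scope="session")
def textured_volume():
    """A noise-free periodic particle texture sized for one default window."""
    spec = synthdata.FlowSpec(kind="uniform", shape=(13, 52, 52), n_frames=2,
                              displacement=(0.0, 0.0, 0.0), seed=17)
    movie = synthdata.generate_flow_movie(spec)
    return movie.frames[0]


@pytest.fixture
def linear_cluster_tracks():
    spec = synthdata.ClusterDynamicsSpec(
        n_clusters=3, cells_per_cluster=6, model=("linear", 2.0, 1.0),
        jitter_sigma=0.0, dt=1.0, n_frames=5, seed=0)
    return synthdata.generate_cluster_trajectories(spec)


def wedge_labels(n_wedges: int, size: int = 41) -> np.ndarray:
    """n wedge-shaped cells meeting at the image centre."""
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    ang = np.arctan2(yy - c, xx - c)
    return (np.floor((ang + np.pi) / (2 * np.pi) * n_wedges) % n_wedges + 1).astype(int)
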