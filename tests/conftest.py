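import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fcspat as f

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def unit_window():
    return f.ObservationWindow(0.0, 0.0, 5.0, 5.0)


@pytest.fixture
def square_lattice(unit_window):
    """5x5 unit-spacing square lattice filling its 5x5 window (R = 2 exactly)."""
    pts = [(i + 0.5, j + 0.5) for i in range(5) for j in range(5)]
    return f.make_pattern(pts, unit_window, label="lattice")


@pytest.fixture
def plot_window():
    return f.ObservationWindow(0.0, 0.0, 500.0, 500.0)


@pytest.fixture
def random_pattern(plot_window):
    """A fixed CSR draw used wherever any generic pattern will do."""
    return f.simulate_csr(120, plot_window, seed=42, label="csr-120")


def brute_force_nn(points: np.ndarray) -> np.ndarray:
    """O(n^2) nearest-neighbor scan; the oracle for nn_distances."""
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def brute_force_k(pattern, r_values) -> np.ndarray:
    """Exhaustive uncorrected K estimator; the oracle for ripley_k."""
    pts = pattern.points
    n = pts.shape[0]
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    mask = ~np.eye(n, dtype=bool)
    scale = pattern.window.area / (n * (n - 1))
    return np.array([scale * np.sum((d <= r) & mask) for r in r_values])
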