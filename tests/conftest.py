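import numpy as np
import pytest

from polyquant.datatypes import LocalizationTable


@pytest.fixture
def disc_with_outliers():
    """25 points inside a 10 nm-radius disc plus 5 isolated points >= 1 um away."""
    rng = np.random.default_rng(42)
    r = 10.0 * np.sqrt(rng.uniform(size=25))
    theta = rng.uniform(0, 2 * np.pi, size=25)
    dense = 2000.0 + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    far = np.array([[100.0, 100.0], [5000.0, 100.0], [100.0, 5000.0],
                    [9000.0, 9000.0], [5000.0, 9000.0]])
    pts = np.vstack([dense, far])
    return LocalizationTable(
        frame=np.arange(len(pts)),
        x_nm=pts[:, 0],
        y_nm=pts[:, 1],
        field_width_nm=10000.0,
        field_height_nm=10000.0,
    )


def random_field(seed: int, n_max: int = 300, extent_nm: float = 500.0) -> LocalizationTable:
    """Random localization field mixing diffuse points and tight hotspots.

    The small extent relative to the 20 nm neighbourhood radius produces a
    mixture of core, border, and noise points, exercising every DBSCAN
    branch.
    """
    rng = np.random.default_rng(seed)
    n_diffuse = int(rng.integers(20, n_max // 2))
    pts = [rng.uniform(0, extent_nm, size=(n_diffuse, 2))]
    n_hot = int(rng.integers(1, 5))
    for _ in range(n_hot):
        c = rng.uniform(50, extent_nm - 50, size=2)
        k = int(rng.integers(10, 40))
        pts.append(c + rng.normal(scale=8.0, size=(k, 2)))
    pts = np.vstack(pts)[: n_max]
    pts = np.clip(pts, 0, extent_nm)
    return LocalizationTable(
        frame=rng.integers(0, 100, size=len(pts)),
        x_nm=pts[:, 0],
        y_nm=pts[:, 1],
        field_width_nm=extent_nm,
        field_height_nm=extent_nm,
    )
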