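import numpy as np
import pytest

from coversad import get_scale, log_likelihood


@pytest.fixture(scope="session")
def londo():
    return get_scale("londo")


def grid_search_1param(counts, model, lo=1.0, hi=500.0, n_grid=200, refinements=2):
    """Independent oracle for one-parameter fits: exhaustive log-spaced grid
    search over the single parameter, refined around the best point."""
    grid = np.geomspace(lo, hi, n_grid)
    best_ll, best_theta = -np.inf, None
    for _ in range(refinements + 1):
        lls = np.array([log_likelihood(counts, model, [t]) for t in grid])
        i = int(np.argmax(lls))
        if lls[i] > best_ll:
            best_ll, best_theta = float(lls[i]), float(grid[i])
        lo_i, hi_i = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
        grid = np.geomspace(lo_i, hi_i, n_grid)
    return best_theta, best_ll
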