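import numpy as np
import pytest

from hetaug import dataset_from_arrays


@pytest.fixture
def two_study():
    """Effects (0, 2) with unit variances: the hand-derivable toy case."""
    return dataset_from_arrays([0.0, 2.0], [1.0, 1.0])


@pytest.fixture
def six_study():
    """Fixed 6-study dataset used for cross-checks against an independent
    meta-analysis implementation."""
    return dataset_from_arrays(
        [0.12, -0.35, 0.51, 0.20, -0.08, 0.63],
        [0.04, 0.09, 0.06, 0.12, 0.05, 0.15],
    )


def direct_tau2_oracle(y, v, restricted: bool) -> float:
    """Independent brute-force maximizer of the (restricted) profile
    log-likelihood in tau2: dense grid scan then local refinement."""
    import math

    from scipy import optimize

    y = np.asarray(y, float)
    v = np.asarray(v, float)

    def nll(tau2):
        s = v + tau2
        w = 1.0 / s
        mu = np.sum(w * y) / np.sum(w)
        val = 0.5 * np.sum(np.log(2 * np.pi * s) + (y - mu) ** 2 / s)
        if restricted:
            val += 0.5 * math.log(np.sum(w))
        return float(val)

    grid = np.concatenate([[0.0], np.logspace(-8, math.log10(50.0), 400)])
    vals = [nll(t) for t in grid]
    i = int(np.argmin(vals))
    if i == 0:
        lo, hi = 0.0, grid[1]
    else:
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
    )
    best = float(res.x) if res.fun <= vals[i] else float(grid[i])
    return 0.0 if nll(0.0) <= nll(best) else best


def random_dataset(rng: np.random.Generator, k: int | None = None):
    """A small random meta-analysis with heterogeneous effects."""
    k = k or int(rng.integers(3, 9))
    v = rng.uniform(0.02, 0.5, k)
    theta = rng.normal(0.1, 0.4, k)
    y = rng.normal(theta, np.sqrt(v))
    return dataset_from_arrays(y, v)
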