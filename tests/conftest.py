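import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from waxstrace import defaults, l1_normalize, simulate_profile

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def control_params():
    return defaults.default_control_params()


@pytest.fixture(scope="session")
def q_grid():
    return defaults.default_q_grid()


@pytest.fixture(scope="session")
def noisy_profile_factory(control_params):
    """Seeded noisy control profiles, L1-normalized, ready for fitting."""

    def make(seed: int, params=None):
        prof, _ = simulate_profile(
            params if params is not None else control_params, seed=seed
        )
        return l1_normalize(prof)

    return make


def brute_force_integrate(counts, excluded, qmap, edges):
    """Per-pixel double-loop azimuthal integration oracle.

    Independent of the production binning: scans the bins one by one with
    the declared rule (half-open [lo, hi), final bin closed).
    """
    nb = len(edges) - 1
    sums = np.zeros(nb)
    ns = np.zeros(nb, dtype=int)
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            if excluded is not None and excluded[i, j]:
                continue
            q = qmap[i, j]
            for b in range(nb):
                lo, hi = edges[b], edges[b + 1]
                inside = lo <= q < hi or (b == nb - 1 and q == hi)
                if inside:
                    sums[b] += counts[i, j]
                    ns[b] += 1
                    break
    intensity = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    sigma = np.where(ns > 0, np.sqrt(np.maximum(sums, 0.0)) / np.maximum(ns, 1), np.nan)
    return intensity, sigma, ns
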