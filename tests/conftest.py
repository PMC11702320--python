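import numpy as np
import pytest

from mccstats import simulation


def interior_points(rng: np.random.Generator, d: int, k: int, min_cell: float = 0.02) -> np.ndarray:
    """k random probability vectors of length d bounded away from the
    simplex boundary (so every margin is comfortably positive)."""
    out = []
    while len(out) < k:
        p = rng.dirichlet(np.full(d, 2.0))
        if p.min() > min_cell:
            out.append(p)
    return np.asarray(out)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)


# Full-scale (m = 1e6) coverage runs at n = 50 for the four balance-
# constrained scenarios whose published coverage values are checked.
# Computed once per session; several tests read different slices.
_TABLE4_SPEC = {
    (0.5, 0.4): ("simple", "fisher", "naive"),
    (0.1, 0.4): ("simple", "fisher"),
    (0.1, 0.6): ("fisher", "naive"),
    (0.5, 0.8): ("fisher",),
}


@pytest.fixture(scope="session")
def table4_runs():
    runs = {}
    for (prev, rho), methods in _TABLE4_SPEC.items():
        sc = simulation.solve_single_scenario(prev, rho)
        res = simulation.run_coverage(sc, n=50, m=1_000_000, methods=methods, seed=0)
        runs[(prev, rho)] = {r.method: r for r in res}
    return runs
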