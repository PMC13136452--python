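import pytest

import holcair as h


@pytest.fixture(scope="session")
def truth():
    return h.SyntheticTruth(seed=0)


@pytest.fixture(scope="session")
def lattice_city(truth):
    """10x10 tract lattice with the default grade layout, scored."""
    tracts = h.generate_tracts(10, 10, 1000.0, seed=0)
    graded = h.generate_holc_map(tracts, truth.grade_layout, seed=0)
    scores = h.score_city(tracts, graded)
    return tracts, graded, scores


@pytest.fixture(scope="session")
def small_grid(truth, lattice_city):
    """Three-year daily grid on a 5x5 sub-lattice (fast)."""
    tracts = h.generate_tracts(5, 5, 1000.0, seed=1)
    graded = h.generate_holc_map(tracts, truth.grade_layout, seed=1)
    scores = h.score_city(tracts, graded)
    grid = h.generate_pollution_grid(tracts, scores, (2000, 2002), truth, seed=1)
    return tracts, scores, grid
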