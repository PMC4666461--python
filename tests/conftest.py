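import numpy as np
import pandas as pd
import pytest

import cnvsig


@pytest.fixture(scope="session")
def small_clone_map() -> cnvsig.CloneMap:
    return cnvsig.build_clone_map([30, 30], spacing_mb=1.0)


@pytest.fixture(scope="session")
def small_regions() -> list[cnvsig.RegionSpec]:
    return [
        cnvsig.RegionSpec(1, 5.0, 12.0, cnvsig.LOSS, prevalence=0.3,
                          effect_log_odds=4.0),
        cnvsig.RegionSpec(2, 10.0, 18.0, cnvsig.GAIN, prevalence=0.25,
                          effect_log_odds=4.0),
    ]


@pytest.fixture(scope="session")
def default_study() -> cnvsig.Study:
    """One reference-condition synthetic study shared across tests."""
    return cnvsig.simulate_study(seed=11)


@pytest.fixture(scope="session")
def default_run() -> cnvsig.StudyResult:
    """One full pipeline run at the reference conditions, shared (expensive)."""
    return cnvsig.run_study(seed=11)


def arc_cuts(i: int, j: int, n: int) -> frozenset:
    """Interior cut points induced by arc (i, j] on a length-n profile.

    An arc and its circular complement induce the same split, so comparisons
    of chosen arcs are made on this canonical form.
    """
    return frozenset({i, j} - {0, n})


def brute_force_max_arc(profile: np.ndarray, min_width: int = 1):
    """Independent exhaustive search over all arcs (i, j]."""
    n = len(profile)
    best = (-1.0, 0, n)
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            if i == 0 and j == n:
                continue
            w = j - i
            if w < min_width or n - w < min_width:
                continue
            stat = cnvsig.arc_statistic(profile, i, j)
            if stat > best[0]:
                best = (stat, i, j)
    return best
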