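"""Shared fixtures.

The expensive fixtures (a synthetic cohort with ground truth and its fits)
are session-scoped so the recovery and fitted-vs-default analyses share one
set of fibers and one fitting run per fiber.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from alifp import ALIFPParams
from alifp.fitting import FitConfig, fit_fiber
from alifp.synth import CohortSpec, generate_fiber

#: cohort conditions for the recovery / fitted-vs-default experiments:
#: 5 fibers, 5 amplitudes across the dynamic range, 30 repetitions,
#: the three trained pulse rates, realistic parameter priors constrained to
#: strictly positive property measures (ratio comparisons need them).
RECOVERY_SPEC = CohortSpec(
    n_fibers=5,
    seed=11,
    deviation_prob=0.0,
    measure_floors={"accommodation_ms": 0.3, "facilitation_ms": 0.05},
)
RECOVERY_N_AMPLITUDES = 5
RECOVERY_N_REPETITIONS = 30


@pytest.fixture(scope="session")
def default_params() -> ALIFPParams:
    return ALIFPParams()


@pytest.fixture(scope="session")
def recovery_cohort():
    """5 synthetic fibers with known ground truth."""
    rng = np.random.default_rng(RECOVERY_SPEC.seed)
    fibers, truths = [], []
    for i in range(RECOVERY_SPEC.n_fibers):
        fiber, truth = generate_fiber(
            RECOVERY_SPEC,
            f"SYN-{i:03d}",
            rng,
            n_amplitudes=RECOVERY_N_AMPLITUDES,
            n_repetitions=RECOVERY_N_REPETITIONS,
        )
        fibers.append(fiber)
        truths.append(truth)
    return fibers, truths


@pytest.fixture(scope="session")
def recovery_fits(recovery_cohort):
    """Full five-step fits of the cohort at reduced optimizer budget."""
    fibers, _ = recovery_cohort
    cfg = FitConfig.test_scale()
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fiber in fibers:
            results.append(fit_fiber(fiber, cfg))
    return results


@pytest.fixture(scope="session")
def tiny_fiber():
    """A small, fast fiber (30 ms trains, 3 amplitudes, 10 repetitions)."""
    spec = CohortSpec(seed=7, train_duration_ms=30.0, deviation_prob=0.0)
    rng = np.random.default_rng(spec.seed)
    fiber, truth = generate_fiber(
        spec, "TINY-000", rng, n_amplitudes=3, n_repetitions=10
    )
    return fiber, truth
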