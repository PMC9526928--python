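import pytest

from bsadesign.policy import PolicyConfig, TrialState
from bsadesign.scaling import DoseGrid

# the six-dose grid of the illustrative trial: original doses on a
# transformed scale, mapped into (0,1] by (x+1.5)/2, target rate 20%
ORIGINAL = (-1.47, -1.1, -0.69, -0.42, 0.0, 0.42)
SCALED = (0.015, 0.20, 0.405, 0.54, 0.75, 0.96)

# per-cohort (dose index, outcomes) of the illustrative search path
EXAMPLE_COHORTS = [
    (1, (0, 0, 0)),
    (2, (0, 0, 0)),
    (3, (0, 0, 0)),
    (4, (0, 0, 0)),
    (5, (0, 0, 0)),
    (6, (0, 0, 1)),
    (5, (0, 0, 0)),
    (5, (0, 0, 1)),
    (5, (0, 0, 0)),
    (5, (0, 0, 0)),
]


@pytest.fixture
def example_grid() -> DoseGrid:
    return DoseGrid(ORIGINAL, SCALED, alpha=0.2, s=3)


@pytest.fixture
def example_cfg() -> PolicyConfig:
    return PolicyConfig(alpha=0.2, s=3)


@pytest.fixture
def example_state(example_grid) -> TrialState:
    """Full accrual history of the illustrative trial."""
    state = TrialState(example_grid)
    for k, ys in EXAMPLE_COHORTS:
        state = state.add_cohort(k, ys)
    return state
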