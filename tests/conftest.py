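import pytest
from hypothesis import settings

from hrhsim import zambia_fixture, run_projection

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def zambia():
    return zambia_fixture()


@pytest.fixture(scope="session")
def base_trajectory(zambia):
    return run_projection(zambia)


def assert_conserved(traj, tol=1e-9):
    """Stock(Y+1) == stock(Y) - school - attrition + hires + immigration."""
    for c in traj.config.stock_classes:
        for i in range(1, len(traj.years)):
            pre = traj.stocks[c.id][i - 1] - traj.school_outflow[c.id][i]
            rhs = (pre - traj.attrition_total(c.id)[i]
                   + traj.hires[c.id][i] + traj.immigration[c.id][i])
            assert abs(traj.stocks[c.id][i] - rhs) < tol, \
                (c.id, int(traj.years[i]))
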