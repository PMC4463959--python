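import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def gelfand_run():
    """Order-2 Gelfand cascade (kappa=1, cubic truncation), exact mode."""
    from ghm import run_ghm
    from ghm.case_studies import get_case_study

    cs = get_case_study("gelfand")
    problem, config = cs.build(kappa=1, taylor_terms=4)
    return run_ghm(problem, config, cs.ansatz)


@pytest.fixture(scope="session")
def heat_run_symbolic():
    """Order-3 cooling cascade with both radiation coefficients symbolic."""
    from ghm import run_ghm
    from ghm.case_studies import get_case_study

    cs = get_case_study("heat_radiation")
    problem, config = cs.build()
    return run_ghm(problem, config, cs.ansatz)


@pytest.fixture(scope="session")
def heat_run_numeric():
    """Order-3 cooling cascade at eps1 = eps2 = 0.1."""
    from ghm import run_ghm
    from ghm.case_studies import get_case_study

    cs = get_case_study("heat_radiation")
    problem, config = cs.build(eps1="0.1", eps2="0.1")
    return run_ghm(problem, config, cs.ansatz)


@pytest.fixture(scope="session")
def smoking_case():
    from ghm.case_studies import get_case_study

    cs = get_case_study("smoking_spain")
    problem, config = cs.build()
    return cs, problem, config


@pytest.fixture(scope="session")
def smoking_run(smoking_case):
    """Order-12 even/odd smoking cascade, control parameter symbolic.

    The single expensive computation of the suite (under a minute); shared
    session-wide.
    """
    from ghm import run_ghm

    cs, problem, config = smoking_case
    return run_ghm(problem, config, cs.ansatz)


@pytest.fixture(scope="session")
def smoking_reference(smoking_case):
    from ghm.validation import reference_ivp

    _, problem, _ = smoking_case
    return reference_ivp(problem, abs_tol=1e-12, interval=(0, 50))
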