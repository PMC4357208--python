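import pytest

import mipflux as mf


@pytest.fixture(scope="session")
def system():
    return mf.load_default_system()


@pytest.fixture(scope="session")
def constraints():
    return mf.load_config()


@pytest.fixture(scope="session")
def bounds(constraints):
    return mf.build_bounds(constraints)


@pytest.fixture(scope="session")
def composition():
    return mf.parse_composition()


@pytest.fixture(scope="session")
def prior_load(composition, constraints):
    return mf.compute_load_vector(composition, mu=constraints.mu)


@pytest.fixture(scope="session")
def calibration(system, bounds, constraints, prior_load):
    printed = [
        s for s in mf.load_printed_scenarios(constraints=constraints)
        if s.name in ("1", "2", "5")
    ]
    return mf.calibrate_loads(
        system, bounds, printed, prior_load, mu=constraints.mu,
        po_nadh=constraints.po_nadh, po_fadh=constraints.po_fadh,
    )


@pytest.fixture(scope="session")
def scenario_table(system, calibration, bounds, constraints):
    return mf.enumerate_scenarios(
        system, calibration.load, bounds,
        po_nadh=constraints.po_nadh, po_fadh=constraints.po_fadh,
    )


@pytest.fixture(scope="session")
def printed_scenarios(constraints):
    return mf.load_printed_scenarios(constraints=constraints)
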