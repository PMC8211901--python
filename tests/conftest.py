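"""Shared fixtures: default parameter sets, scenarios, and cached simulations.

The long (150 d) fitted-scenario simulation is session-scoped and reused by
every test that only inspects the trajectory.
"""

import numpy as np
import pytest

from messim import (
    DomainSpec,
    ElectroParams,
    KineticParams,
    OperationSchedule,
    ReactorConfig,
    ReactorState,
    Segment,
    ThermoParams,
    simulate,
)
from messim.scenarios import load_scenario
from messim.thermo import ReactionStoichiometry


@pytest.fixture(scope="session")
def thermo():
    return ThermoParams()


@pytest.fixture(scope="session")
def stoich():
    return ReactionStoichiometry()


@pytest.fixture(scope="session")
def kparams():
    return KineticParams()


@pytest.fixture(scope="session")
def fitted_scenario():
    return load_scenario("jourdin2019_ftr2")


@pytest.fixture(scope="session")
def fitted_run(fitted_scenario):
    """Full 150 d simulation of the fitting scenario (quasi-equilibrium mediator)."""
    return simulate(
        fitted_scenario.config, fitted_scenario.schedule, mediator_mode="qe", dt_out=6.0
    )


@pytest.fixture(scope="session")
def fitted_run_ode(fitted_scenario):
    """Stiff-integrator counterpart of ``fitted_run``, truncated to 30 d."""
    return simulate(
        fitted_scenario.config,
        fitted_scenario.schedule,
        t_end=30 * 24.0,
        mediator_mode="ode",
        dt_out=6.0,
    )


def two_domain_config(
    C_X: float = 5.0, Q_recirc: float = 0.012, kLa: float = 2.5, **state_kw
) -> ReactorConfig:
    """Small gas-exchange + biofilm loop used by conservation/toy tests."""
    domains = [
        DomainSpec("tank", 300e-6, "gas-exchange"),
        DomainSpec("biofilm", 25e-6, "biofilm"),
    ]
    dilute = {"CO2": 10.0, "NH4": 10.0, "Ac": 30.0, "But": 0.0, "Cap": 0.0}
    dilute.update(state_kw)
    initial = ReactorState.uniform(domains, dilute, C_X=C_X)
    return ReactorConfig(
        domains=domains,
        initial=initial,
        Q_recirc=Q_recirc,
        v_ref_dilution=300e-6,
        kLa=kLa,
        feed_domain="tank",
        electro=ElectroParams(),
    )


@pytest.fixture()
def toy_config():
    return two_domain_config()


def single_segment(t_end_h: float = 48.0, **kw) -> OperationSchedule:
    defaults = dict(mode="batch", sparging=True, p_co2=0.3,
                    feed={"NH4": 10.0})
    defaults.update(kw)
    return OperationSchedule([Segment(0.0, t_end_h, **defaults)])
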