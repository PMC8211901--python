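"""Diagnostics: limitation profiles, inter-domain steps, characteristic times.

These reproduce the analyses used to interrogate the model: which Monod or
inhibition term limits the metabolism at each instant, how large the CO2
concentration steps between consecutive loop domains are (a check on the
well-mixed assumption), how the CO2 reaction time in the biofilm compares
with the convective residence time, and parameter sweeps over kLa, gas CO2
partial pressure or dilution rate.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import kinetics as kin
from .kinetics import KineticParams
from .reactor import (
    OperationSchedule,
    ReactorConfig,
    Segment,
    SimulationResult,
    simulate,
)

__all__ = [
    "limitation_profile",
    "domain_concentration_steps",
    "characteristic_times",
    "steady_state_window",
    "sweep",
]

SAT_COLUMNS = ("sat_co2", "sat_nh4", "sat_mh")
INH_COLUMNS = ("inh_ac", "inh_but", "inh_cap")


def limitation_profile(
    result: SimulationResult, params: KineticParams | None = None
) -> pd.DataFrame:
    """Hyperbolic uptake and product-inhibition terms over time, each in [0, 1].

    Evaluated pointwise from the stored biofilm states.  The ``limiting``
    column names the smallest term at each time — the main factor holding the
    microbial kinetics below their maximum.
    """
    p = params if params is not None else result.config.kinetics
    rows = []
    for k in range(len(result.t)):
        c = result.biofilm_state(k)
        terms = {
            "sat_co2": kin.saturation_term(c["CO2"], p.K_co2),
            "sat_nh4": kin.saturation_term(c["NH4"], p.K_nh4),
            "sat_mh": kin.saturation_term(c["MH"], p.K_mh),
            "inh_ac": kin.inhibition_term(c["Ac"], p.C_ac_star),
            "inh_but": kin.inhibition_term(c["But"], p.C_but_star),
            "inh_cap": kin.inhibition_term(c["Cap"], p.C_cap_star),
        }
        rows.append({"t_h": result.t[k], **terms,
                     "limiting": min(terms, key=terms.get)})
    return pd.DataFrame(rows)


def domain_concentration_steps(
    result: SimulationResult, species: str = "CO2"
) -> pd.DataFrame:
    """Percentage concentration change across each consecutive domain pair.

    For every interface (upstream -> downstream in the recirculation loop,
    including the wrap-around back to the first domain) and every output
    time: 100 (C_down - C_up)/C_up.  Positive = the species is added in the
    downstream domain (e.g. CO2 in the gas-exchange column), negative =
    consumed (biofilm).  Times where the upstream concentration is ~0 (e.g.
    the very first instant of a run started without dissolved CO2) yield 0.
    """
    domains = list(result.domains)
    if len(domains) < 2:
        return pd.DataFrame(columns=["t_h", "interface", "step_pct"])
    rows = []
    for i, down in enumerate(domains):
        up = domains[i - 1]
        c_up = result.domain_series(up, species)
        c_down = result.domain_series(down, species)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(c_up > 1e-12, 100.0 * (c_down - c_up) / c_up, 0.0)
        for t, v in zip(result.t, pct):
            rows.append({"t_h": t, "interface": f"{up}->{down}", "step_pct": v})
    return pd.DataFrame(rows)


def steady_state_window(result: SimulationResult, fraction: float = 0.1) -> np.ndarray:
    """Indices of the late-run evaluation window (final ``fraction`` of the run)."""
    t0 = result.t[-1] - fraction * (result.t[-1] - result.t[0])
    idx = np.nonzero(result.t >= t0)[0]
    return idx if idx.size else np.array([len(result.t) - 1])


def characteristic_times(
    result: SimulationResult, config: ReactorConfig | None = None
) -> tuple[float, float]:
    """Characteristic CO2 reaction and convection times, in minutes.

    tau_reaction = C_CO2 / |r_CO2| in the biofilm, evaluated at late steady
    state (mean over the final 10% of the run); infinite if the rate is zero.
    tau_convection = V_fc / Q_R, independent of the biological state.  A
    reaction time much longer than the convection time means concentration
    changes accrue over many recirculation passes, justifying the well-mixed
    domain assumption.
    """
    cfg = config if config is not None else result.config
    tau_conv = cfg.biofilm.volume / cfg.Q_recirc * 60.0  # h -> min
    derived = result.derived()
    idx = steady_state_window(result)
    bio = result.biofilm_domain()
    c_co2 = result.domain_series(bio, "CO2")[idx]
    r_co2 = np.abs(derived["q_co2"].to_numpy()[idx] * result.C_X[idx])  # mol/(m^3 h)
    r_mean = float(np.mean(r_co2))
    if r_mean <= 0.0:
        return float("inf"), tau_conv
    tau_rxn = float(np.mean(c_co2)) / r_mean * 60.0
    return tau_rxn, tau_conv


def _with_parameter(
    config: ReactorConfig, schedule: OperationSchedule, name: str, value: float
) -> tuple[ReactorConfig, OperationSchedule]:
    if name == "kLa":
        return replace(config, kLa=value), schedule
    if name == "p_CO2":
        segs = [replace(s, p_co2=value) for s in schedule.segments]
        return config, OperationSchedule(segs)
    if name == "D_RL":
        segs = [replace(s, D_rl=value) for s in schedule.segments]
        return config, OperationSchedule(segs)
    raise ValueError(f"unknown sweep parameter {name!r}; use kLa, p_CO2 or D_RL")


def sweep(
    config: ReactorConfig,
    schedule: OperationSchedule,
    parameter: str,
    values: Sequence[float],
    t_end: float | None = None,
    **sim_kwargs,
) -> pd.DataFrame:
    """One simulation per parameter value; biomass-production and titer summary.

    Returns per value: peak volumetric biomass production rate mu*C_X
    (mol/(m^3 h)), final biofilm biomass, final organics titers at the
    sampling port, and the CO2 saturation concentration of the (first
    segment's) feed gas.
    """
    rows = []
    for v in values:
        cfg, sched = _with_parameter(config, schedule, parameter, v)
        res = simulate(cfg, sched, t_end=t_end, **sim_kwargs)
        derived = res.derived()
        rows.append(
            {
                parameter: v,
                "peak_biomass_production": float(derived["r_x"].max()),
                "final_biomass": float(res.C_X[-1]),
                "final_Ac": float(res.observed_series("Ac")[-1]),
                "final_But": float(res.observed_series("But")[-1]),
                "final_Cap": float(res.observed_series("Cap")[-1]),
                "c_co2_sat": cfg.henry * sched.segments[0].p_co2,
            }
        )
    return pd.DataFrame(rows)
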