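"""Kinetic parameter estimation from organics concentration time series.

Five parameters are free: the three maximum specific rates (q_CO2_max,
q_But_max, q_Cap_max) and the two elongation thresholds (C_Ac_t, C_But_t).
They are estimated by minimising the residual sum of squares between observed
bulk concentrations of acetate, butyrate and caproate (at the sampling-port
domain) and the simulated trajectory, using Nelder-Mead.

Nelder-Mead is unconstrained, so the search runs in a log-transformed space
(log of each parameter magnitude) which enforces the sign constraints — the
CO2 rate stays an uptake, the elongation rates stay productions, thresholds
stay positive — without penalty terms.  The fit is deterministic for fixed
inputs and options.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .reactor import OperationSchedule, ReactorConfig, SimulationError, simulate

__all__ = [
    "Dataset",
    "FitResult",
    "THETA_NAMES",
    "residual_sum_squares",
    "fit_kinetic_parameters",
    "population_sd",
]

logger = logging.getLogger(__name__)

THETA_NAMES = ("q_co2_max", "q_but_max", "q_cap_max", "C_ac_t", "C_but_t")

#: RSS returned when a simulation fails inside the optimizer (mol^2/m^6).
FAILURE_PENALTY = 1e12


@dataclass(frozen=True)
class Dataset:
    """Observed concentration points: (time_h, species, conc_mol_m3) records."""

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"time_h", "species", "conc_mol_m3"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"dataset needs columns {sorted(required)}")
        if (self.frame["conc_mol_m3"] < 0).any():
            raise ValueError("observed concentrations must be >= 0")

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[float, str, float]], provenance: str = ""
    ) -> "Dataset":
        frame = pd.DataFrame(records, columns=["time_h", "species", "conc_mol_m3"])
        return cls(frame=frame, provenance=provenance)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        return cls(frame=pd.read_csv(path), provenance=str(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())


@dataclass
class FitResult:
    """Outcome of a parameter estimation."""

    theta: np.ndarray  # (q_co2_max, q_but_max, q_cap_max, C_ac_t, C_but_t)
    rss: float
    n_iter: int
    n_eval: int
    converged: bool
    population_sd: Mapping[str, float] = field(default_factory=dict)
    message: str = ""

    def as_dict(self) -> dict:
        out = {name: float(v) for name, v in zip(THETA_NAMES, self.theta)}
        out.update(
            rss=float(self.rss), n_iter=self.n_iter, n_eval=self.n_eval,
            converged=self.converged,
            population_sd={k: float(v) for k, v in self.population_sd.items()},
        )
        return out


def _predictions(
    result, dataset: Dataset
) -> np.ndarray:
    """Model values interpolated at each observation's time, in dataset order."""
    pred = np.empty(len(dataset))
    frame = dataset.frame
    for sp in frame["species"].unique():
        mask = (frame["species"] == sp).to_numpy()
        series = result.observed_series(sp)
        pred[mask] = np.interp(frame.loc[mask, "time_h"].to_numpy(), result.t, series)
    return pred


def _simulate_theta(theta, config: ReactorConfig, schedule: OperationSchedule,
                    sim_options: Mapping | None):
    cfg = replace(config, kinetics=config.kinetics.with_theta(theta))
    opts = dict(sim_options or {})
    opts.setdefault("mediator_mode", "qe")
    return simulate(cfg, schedule, **opts)


def residual_sum_squares(
    theta: Sequence[float],
    dataset: Dataset,
    config: ReactorConfig,
    schedule: OperationSchedule,
    weights: Mapping[str, float] | None = None,
    sim_options: Mapping | None = None,
) -> float:
    """RSS over all observations jointly (mol^2/m^6), equal species weights.

    A failed simulation returns a large penalty (with a logged warning) so the
    simplex can recover instead of aborting the fit.
    """
    if len(dataset) == 0:
        return 0.0
    try:
        result = _simulate_theta(theta, config, schedule, sim_options)
    except (SimulationError, ValueError) as exc:
        logger.warning("simulation failed at theta=%s: %s", np.asarray(theta), exc)
        return FAILURE_PENALTY
    residuals = dataset.frame["conc_mol_m3"].to_numpy() - _predictions(result, dataset)
    if weights:
        w = dataset.frame["species"].map(lambda s: weights.get(s, 1.0)).to_numpy()
        return float(np.sum(w * residuals**2))
    return float(np.sum(residuals**2))


def _to_x(theta: Sequence[float]) -> np.ndarray:
    """Parameter vector -> unconstrained search space (log magnitudes)."""
    t = np.asarray(theta, dtype=float)
    return np.array([np.log(-t[0]), np.log(t[1]), np.log(t[2]),
                     np.log(t[3]), np.log(t[4])])


def _from_x(x: np.ndarray) -> np.ndarray:
    return np.array([-np.exp(x[0]), np.exp(x[1]), np.exp(x[2]),
                     np.exp(x[3]), np.exp(x[4])])


def fit_kinetic_parameters(
    dataset: Dataset,
    config: ReactorConfig,
    schedule: OperationSchedule,
    theta0: Sequence[float] | None = None,
    max_iter: int = 600,
    xatol: float = 1e-3,
    fatol: float = 1e-8,
    weights: Mapping[str, float] | None = None,
    sim_options: Mapping | None = None,
) -> FitResult:
    """Nelder-Mead least-squares estimate of the five kinetic parameters.

    ``theta0`` defaults to the config's current values.  ``xatol`` acts on the
    log-transformed parameters (so it is a relative tolerance on each
    parameter); ``fatol`` is absolute on the RSS.  Non-convergence within
    ``max_iter`` returns the best point found, flagged.
    """
    if theta0 is None:
        k = config.kinetics
        theta0 = (k.q_co2_max, k.q_but_max, k.q_cap_max, k.C_ac_t, k.C_but_t)
    theta0 = np.asarray(theta0, dtype=float)
    if not np.all(np.isfinite(theta0)):
        raise ValueError("theta0 must be finite")

    def objective(x: np.ndarray) -> float:
        return residual_sum_squares(
            _from_x(x), dataset, config, schedule, weights, sim_options
        )

    opt = minimize(
        objective,
        _to_x(theta0),
        method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": xatol, "fatol": fatol,
                 "adaptive": True},
    )
    theta = _from_x(opt.x)
    sd: dict[str, float] = {}
    try:
        result = _simulate_theta(theta, config, schedule, sim_options)
        sd = population_sd(result, dataset)
    except (SimulationError, ValueError):  # pragma: no cover - penalized above
        pass
    return FitResult(
        theta=theta,
        rss=float(opt.fun),
        n_iter=int(opt.nit),
        n_eval=int(opt.nfev),
        converged=bool(opt.success),
        population_sd=sd,
        message=str(opt.message),
    )


def population_sd(result, dataset: Dataset) -> dict[str, float]:
    """Per-species root-mean-square model-data residual (mol/m^3).

    The "population standard deviation" of the model over the observation
    points; species with no observations are absent from the result.
    """
    pred = _predictions(result, dataset)
    frame = dataset.frame
    out: dict[str, float] = {}
    for sp in frame["species"].unique():
        mask = (frame["species"] == sp).to_numpy()
        res = frame.loc[mask, "conc_mol_m3"].to_numpy() - pred[mask]
        out[sp] = float(np.sqrt(np.mean(res**2)))
    return out
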