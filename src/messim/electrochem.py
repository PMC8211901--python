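"""Butler-Volmer reduction of the intracellular mediator at the cathode.

The cathode regenerates the reduced mediator via M+ + H+ + 2 e- -> MH.  The
net volumetric rate (per m^3 of biofilm, per second) is

    r_M_elec = kef * C_M+ * C_H+ - ker * C_MH

with potential-dependent rate coefficients

    kef = ke0 exp[-alpha n F (E_C - E_M) / (R T)]
    ker = ke0 exp[(1 - alpha) n F (E_C - E_M) / (R T)]

Unit note: concentrations are mol/m^3 internally, but the proton term C_H+ is
a mol/L concentration (10**-pH), matching the published parameterisation of
ke0 = 0.03 1/s; kef therefore carries units of L/(mol s).  This convention is
applied consistently wherever the rate is evaluated.

At the default cathode potential (-1.2 V vs SHE, 0.88 V overpotential against
the mediator) kef/ker ~ 1e29: the mediator pool relaxes toward the fully
reduced state on a sub-second timescale, which is why the reactor module
offers both a stiff integrator and a quasi-equilibrium mediator mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import FARADAY, R_J

__all__ = [
    "ElectroParams",
    "electron_transfer_coefficients",
    "mediator_reduction_rate",
    "cathode_current",
]


@dataclass(frozen=True)
class ElectroParams:
    """Cathode/mediator electron-transfer parameters.

    ke0 in 1/s (heterogeneous standard rate), potentials in V vs SHE,
    C_H in mol/L (fixed catholyte proton concentration).
    """

    ke0: float = 0.03
    alpha: float = 0.5
    n: int = 2
    E_C: float = -1.2
    E_M: float = -0.32
    C_H: float = 10.0 ** -5.8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("transfer coefficient alpha must lie in (0, 1)")
        if self.ke0 <= 0:
            raise ValueError("ke0 must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.C_H <= 0:
            raise ValueError("C_H must be positive")


def electron_transfer_coefficients(params: ElectroParams, T: float) -> tuple[float, float]:
    """Forward (reduction) and reverse (oxidation) rate coefficients at T (K)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    x = params.n * FARADAY * (params.E_C - params.E_M) / (R_J * T)
    kef = params.ke0 * math.exp(-params.alpha * x)
    ker = params.ke0 * math.exp((1.0 - params.alpha) * x)
    return kef, ker


def mediator_reduction_rate(
    kef: float, ker: float, C_Mox: float, C_MH: float, C_H: float
) -> float:
    """Net mediator reduction rate, mol_M+ reduced per m^3 biofilm per second.

    Positive = net reduction (MH production).  ``C_Mox``/``C_MH`` in mol/m^3,
    ``C_H`` in mol/L (see module unit note).
    """
    return kef * C_Mox * C_H - ker * C_MH


def cathode_current(r_M_elec: float, params: ElectroParams, V_fc: float) -> float:
    """Cathodic current I = n F r_M_elec V_fc (A); positive = net reduction."""
    if V_fc <= 0:
        raise ValueError("biofilm volume must be positive")
    return params.n * FARADAY * r_M_elec * V_fc
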