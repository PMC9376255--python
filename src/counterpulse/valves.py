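"""Pressure-actuated mitral and aortic valves.

A continuous opening state s(t) in [0, 1] (0 = fully closed) relaxes toward
open when the transvalvular pressure gradient is positive and toward closed
when it is negative:

    ds/dt = (1 − s)·K_open·dp   for dp > 0
    ds/dt = s·K_close·dp        for dp <= 0   (dp negative drives closure)

The dynamics cannot carry s outside [0, 1] (both boundary factors vanish).
Flow obeys a Bernoulli orifice law gated by s: dp = (b/s^2)·Q·|Q|, i.e.

    Q = sign(dp)·s·sqrt(|dp| / b)

with b the Bernoulli coefficient at full opening.  s is floored inside the
flow law only; flow is hard-zeroed below the floor so a fully closed valve
passes exactly zero flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ValveParams", "ValveState", "valve_state_rate", "valve_flow", "S_FLOOR"]

#: opening-state floor used only inside the flow law's division
S_FLOOR = 1e-6

#: blood density term for the Bernoulli coefficient, mmHg·s^2/mL^2 per cm^-4:
#: rho/2 = 0.53 g/cm^3 in CGS, divided by 1333.22 dyn/cm^2 per mmHg
_BERNOULLI_RHO = 0.53 / 1333.22


def bernoulli_coefficient(effective_area_cm2):
    """Bernoulli coefficient (mmHg·s^2/mL^2) for a given effective orifice area."""
    return _BERNOULLI_RHO / effective_area_cm2**2


def blood_inertance(effective_area_cm2, effective_length_cm=1.5):
    """Blood column inertance through the orifice, mmHg·s^2/mL."""
    return 1.06 * effective_length_cm / effective_area_cm2 / 1333.22


@dataclass
class ValveParams:
    """Rate constants, orifice area and the derived Bernoulli coefficient.

    ``inertance_coeff`` of ``None`` derives the physiological blood-column
    inertance from the orifice area; an explicit 0 selects the quasi-steady
    (inertance-free) flow law of :func:`valve_flow`.
    """

    K_open: float = 30.0  # 1/(mmHg·s)
    K_close: float = 60.0  # 1/(mmHg·s)
    A_eff_max: float = 3.5  # cm^2
    bernoulli_coeff: float = None  # mmHg·s^2/mL^2 at full opening
    inertance_coeff: float = None  # mmHg·s^2/mL
    label: str = "AV"

    def __post_init__(self):
        if self.bernoulli_coeff is None:
            self.bernoulli_coeff = bernoulli_coefficient(self.A_eff_max)
        if self.inertance_coeff is None:
            self.inertance_coeff = blood_inertance(self.A_eff_max)
        if min(self.K_open, self.K_close, self.A_eff_max, self.bernoulli_coeff) <= 0:
            raise ValueError(f"valve {self.label}: parameters must be positive")


@dataclass
class ValveState:
    s: float  # opening state in [0, 1]
    flow: float  # mL/s


def valve_state_rate(s, dp, params):
    """Rate of change of the opening state, 1/s."""
    if dp > 0:
        return (1.0 - s) * params.K_open * dp
    return s * params.K_close * dp


def valve_flow(dp, s, params):
    """Transvalvular flow (mL/s) through the gated Bernoulli orifice."""
    if s <= S_FLOOR:
        return 0.0
    return float(np.sign(dp)) * s * np.sqrt(abs(dp) / params.bernoulli_coeff)
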