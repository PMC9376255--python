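"""Time-varying elastance models of the left atrium and left ventricle.

Chamber pressure is the sum of a passive (diastolic, exponential) component
and an active component driven by a normalized activation function:

    P(V, t) = A_pas·(exp(B_pas·(V − V0)) − 1) + e(t)·E_act_max·(V − V0)

The activation e(t) is a half-cosine bump rising from 0 to exactly 1 and back
inside the window [t_onset, t_onset + t_sys], periodic in the cycle length.
A stiff passive curve (large B_pas) is the HFpEF phenotype: higher pressure
is needed to reach a given filling volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChamberParams", "ChamberState", "activation", "passive_pressure", "chamber_pressure"]


@dataclass
class ChamberParams:
    """Elastance-chamber parameters.

    E_act_max : mmHg/mL   peak active elastance (ESPVR slope)
    V0        : mL        unstressed volume (pressure-axis intercept)
    A_pas     : mmHg      passive-curve scale
    B_pas     : 1/mL      passive-curve exponent (diastolic stiffness)
    t_onset   : s         activation start within the cycle
    t_sys     : s         activation window duration
    """

    E_act_max: float
    V0: float
    A_pas: float
    B_pas: float
    t_onset: float
    t_sys: float
    peak_frac: float = 0.5  # position of the activation peak within the window
    rise_power: float = 1.0  # exponent on the rising limb (<1: faster upstroke)
    label: str = "LV"

    def validate(self, cycle_length):
        if self.E_act_max <= 0 or self.A_pas < 0 or self.B_pas <= 0:
            raise ValueError(f"{self.label}: invalid elastance parameters")
        if not (0 <= self.t_onset < cycle_length) or not (0 < self.t_sys < cycle_length):
            raise ValueError(f"{self.label}: activation timing outside the cycle")
        return self


@dataclass
class ChamberState:
    volume: float  # mL
    pressure: float  # mmHg


def activation(t_cycle, params, cycle_length=None):
    """Normalized activation e(t) in [0, 1]; C1 cosine bump, periodic.

    Zero outside the window [t_onset, t_onset + t_sys]; rises smoothly to
    exactly 1 at ``peak_frac·t_sys`` into the window and returns smoothly to
    0 at the window end.  The default ``peak_frac = 0.5`` is the symmetric
    half-cosine bump 0.5·(1 − cos(2π·rel/t_sys)); a late peak emulates the
    physiological elastance waveform (slow pressure build-up through
    ejection, rapid relaxation).  Accepts scalar or array time.
    """
    t = np.asarray(t_cycle, dtype=float)
    if cycle_length is not None:
        t = np.mod(t, cycle_length)
        # window may wrap the cycle boundary
        rel = np.mod(t - params.t_onset, cycle_length)
    else:
        rel = t - params.t_onset
    tp = params.peak_frac * params.t_sys
    rise = 0.5 * (1.0 - np.cos(np.pi * np.divide(rel, tp, where=tp > 0,
                                                 out=np.zeros_like(rel + 0.0))))
    rise = np.power(np.clip(rise, 0.0, 1.0), params.rise_power)
    fall = 0.5 * (1.0 + np.cos(np.pi * (rel - tp) / max(params.t_sys - tp, 1e-12)))
    e = np.where((rel >= 0) & (rel <= params.t_sys),
                 np.where(rel <= tp, rise, fall), 0.0)
    return float(e) if np.isscalar(t_cycle) else e


def passive_pressure(volume, params):
    """Passive (diastolic) pressure, mmHg: A_pas·(exp(B_pas·(V − V0)) − 1)."""
    return params.A_pas * (np.exp(params.B_pas * (np.asarray(volume, float) - params.V0)) - 1.0)


def chamber_pressure(volume, t_cycle, params, cycle_length=None):
    """Total chamber pressure: passive plus activation-scaled linear ESPVR."""
    e = activation(t_cycle, params, cycle_length)
    return passive_pressure(volume, params) + e * params.E_act_max * (np.asarray(volume, float) - params.V0)
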