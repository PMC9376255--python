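"""Extra-aortic McKibben counterpulsation element.

The pneumatic actuator wrapped around the ascending aorta is represented by an
experimentally parameterized pressure source p_sr coupled into the aortic node
through a capacitance.  Per actuation cycle p_sr has a contraction branch and
a relaxation branch:

    p_sr(t_norm) = g_act · p_aorta · (1 − exp(−k1·t_norm))        0 <= t_norm <= t_on
                 = c · exp(−k2·(t_norm − t_on)) + d               t_on < t_norm <= t_off
                 = 0                                              otherwise

with (c, d) solving continuity at t_on and p_sr(t_off) = 0.  The dimensionless
gain g_act is a quadratic surface in the loop pressure and the actuation
pressure,

    g_act = a1·p_aorta^2 + a2·p_aorta + a3·p_act + a4 + a5·p_aorta·p_act,

fitted by least squares (minimum RMSE) to a bench characterization grid.  The
actuation pressure p_act is kept in psi end to end, matching the bench sweeps
(6–12 psi); p_aorta is in mmHg.

A synthetic bench-data generator emulates the silicone-loop characterization
experiment (loop pressures 50–150 mmHg, 60 bpm) and is the packaged stand-in
for the unavailable measured grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "DeviceParams",
    "BenchGrid",
    "normalize_time",
    "gain",
    "fit_gain_surface",
    "relaxation_constants",
    "source_pressure",
    "device_flow_contribution",
    "timing_lookup",
    "synth_bench_data",
    "calibrate_correction",
    "DEFAULT_GAIN_COEFFS",
    "BENCH_P_AORTA",
    "BENCH_P_ACT",
]

#: loop pressures (mmHg) and actuation pressures (psi) of the bench protocol
BENCH_P_AORTA = (50.0, 60.0, 70.0, 80.0, 90.0, 100.0, 125.0, 150.0)
BENCH_P_ACT = (6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0)

#: exponential time constants of the contraction / relaxation branches, 1/s
K1_DEFAULT = 13.04
K2_DEFAULT = 34.66

#: peak pocket displacement (mL) of the synthetic bench characterization at
#: a 100 mmHg loop pressure: the in-vivo correction factor is calibrated so
#: the coupled model reproduces this displacement
BENCH_PEAK_DISPLACEMENT_ML = 10.0

#: hidden quadratic surface behind the synthetic bench generator; chosen so
#: the gain is in (0, 1), strictly increasing in p_act and strictly
#: decreasing in p_aorta over the whole bench grid
DEFAULT_GAIN_COEFFS = (2.0e-6, -2.4e-3, 2.8e-2, 0.30, -4.0e-5)


class DeviceError(ValueError):
    """Invalid device parameters or degenerate bench data."""


@dataclass
class DeviceParams:
    """Actuation settings, fitted constants and the aortic coupling.

    p_act      : psi   actuator pressure (0 disables the device)
    dt_act     : s     actuation delay from the R-wave (cycle start)
    t_act      : s     commanded contraction duration (0.3 s)
    t_on/t_off : s     measured contraction / full-actuation durations
    k1, k2     : 1/s   contraction / relaxation exponents
    gain_coeffs: a1..a5 of the gain surface
    C_sr       : mL/mmHg  coupling capacitance into the aortic node
    correction : dimensionless λ scaling p_sr to the in-vivo setting
    R_sr       : mmHg·s/mL  small series resistance of the coupling
    """

    p_act: float = 12.0
    dt_act: float = 0.65
    t_act: float = 0.3
    t_on: float = 0.3
    t_off: float = 0.5
    k1: float = K1_DEFAULT
    k2: float = K2_DEFAULT
    gain_coeffs: tuple = DEFAULT_GAIN_COEFFS
    C_sr: float = 0.05
    correction: float = 1.0
    R_sr: float = 0.01

    def __post_init__(self):
        if self.p_act < 0:
            raise DeviceError("p_act must be non-negative")
        if not (0 < self.t_on < self.t_off):
            raise DeviceError("need 0 < t_on < t_off")
        if min(self.k1, self.k2, self.C_sr, self.R_sr) <= 0 or self.correction < 0:
            raise DeviceError("k1, k2, C_sr, R_sr must be positive and correction >= 0")

    @property
    def active(self):
        return self.p_act > 0


@dataclass
class BenchGrid:
    """Bench characterization rows: (p_aorta, p_act, g_exp, t_on, t_off)."""

    p_aorta: np.ndarray
    p_act: np.ndarray
    g_exp: np.ndarray
    t_on: np.ndarray
    t_off: np.ndarray

    def __len__(self):
        return len(self.g_exp)

    def to_frame(self):
        return pd.DataFrame({
            "p_aorta_mmHg": self.p_aorta, "p_act_psi": self.p_act,
            "g_exp": self.g_exp, "t_on_s": self.t_on, "t_off_s": self.t_off,
        })

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        return cls(
            p_aorta=df["p_aorta_mmHg"].to_numpy(float),
            p_act=df["p_act_psi"].to_numpy(float),
            g_exp=df["g_exp"].to_numpy(float),
            t_on=df["t_on_s"].to_numpy(float),
            t_off=df["t_off_s"].to_numpy(float),
        )


def normalize_time(t, dt_act, hr):
    """Time within the actuation cycle, s; in [0, 60/hr).

    t_norm = t − floor((t − δt_act)·HR/60)·60/HR − δt_act
    """
    if hr <= 0:
        raise DeviceError("hr must be positive")
    period = 60.0 / hr
    return t - math.floor((t - dt_act) / period) * period - dt_act


def gain(p_aorta, p_act, coeffs):
    """Dimensionless gain surface g_act(p_aorta, p_act) — raw, unclamped."""
    a1, a2, a3, a4, a5 = coeffs
    return a1 * p_aorta**2 + a2 * p_aorta + a3 * p_act + a4 + a5 * p_aorta * p_act


def clamped_gain(p_aorta, p_act, coeffs):
    """Gain clamped to [0, 1) before use in the pressure source."""
    return min(max(gain(p_aorta, p_act, coeffs), 0.0), 1.0 - 1e-9)


def fit_gain_surface(grid):
    """Least-squares fit of the gain surface to bench data.

    Returns ``(coeffs, rmse)`` where coeffs = (a1..a5).  Raises
    :class:`DeviceError` for rank-deficient designs (fewer than five distinct
    (p_aorta, p_act) points, or degenerate layouts such as a single loop
    pressure).
    """
    pa = np.asarray(grid.p_aorta, float)
    pc = np.asarray(grid.p_act, float)
    g = np.asarray(grid.g_exp, float)
    pts = {(a, c) for a, c in zip(pa, pc)}
    if len(pts) < 5:
        raise DeviceError("degenerate fit: need at least 5 distinct (p_aorta, p_act) points")
    X = np.column_stack([pa**2, pa, pc, np.ones_like(pa), pa * pc])
    if np.linalg.matrix_rank(X) < 5:
        raise DeviceError("degenerate fit: rank-deficient design (single p_aorta or p_act level?)")
    coeffs, *_ = np.linalg.lstsq(X, g, rcond=None)
    rmse = float(np.sqrt(np.mean((X @ coeffs - g) ** 2)))
    return tuple(coeffs), rmse


def relaxation_constants(p_on, k2, t_on, t_off):
    """(c, d) making the relaxation branch continuous at t_on and zero at t_off."""
    e2 = math.exp(-k2 * (t_off - t_on))
    c = p_on / (1.0 - e2)
    d = -p_on * e2 / (1.0 - e2)
    return c, d


def source_pressure(t_norm, p_aorta, dev):
    """Pressure source p_sr (mmHg) at normalized time t_norm within the cycle.

    Piecewise contraction/relaxation with continuity at t_on and a zero tail
    after t_off.  Raises for t_off <= t_on (checked at construction too).
    """
    if dev.t_off <= dev.t_on:
        raise DeviceError("need t_off > t_on")
    g = clamped_gain(p_aorta, dev.p_act, dev.gain_coeffs)
    if t_norm < 0:
        return 0.0
    if t_norm <= dev.t_on:
        return g * p_aorta * (1.0 - math.exp(-dev.k1 * t_norm))
    if t_norm <= dev.t_off:
        p_on = g * p_aorta * (1.0 - math.exp(-dev.k1 * dev.t_on))
        c, d = relaxation_constants(p_on, dev.k2, dev.t_on, dev.t_off)
        return c * math.exp(-dev.k2 * (t_norm - dev.t_on)) + d
    return 0.0


def device_flow_contribution(p_node, p_sr, x, dev, p_ref=0.0):
    """Flow into the aortic node (mL/s) and pocket-volume rate dx/dt.

    The element is a capacitance C_sr referenced to the external pressure
    λ·p_sr, with a small series resistance R_sr regularizing the coupling.
    ``x`` is the volume displaced into the device pocket, measured relative
    to the unpressurized rest state at the baseline node pressure ``p_ref``;
    at equilibrium x = C_sr·(p_node − p_ref − λ·p_sr), and the flow injected
    into the node is −dx/dt, so the net volume exchanged per periodic cycle
    is zero.
    """
    dxdt = (p_node - p_ref - dev.correction * p_sr - x / dev.C_sr) / dev.R_sr
    return -dxdt, dxdt


def timing_lookup(p_act, p_aorta, grid):
    """Bilinear interpolation of (t_on, t_off) over the bench grid, edge-clamped."""
    if len(grid) == 0:
        raise DeviceError("empty bench grid")
    pas = np.unique(grid.p_aorta)
    pcs = np.unique(grid.p_act)
    ton = np.full((len(pas), len(pcs)), np.nan)
    toff = np.full((len(pas), len(pcs)), np.nan)
    for a, c, on, off in zip(grid.p_aorta, grid.p_act, grid.t_on, grid.t_off):
        ton[np.searchsorted(pas, a), np.searchsorted(pcs, c)] = on
        toff[np.searchsorted(pas, a), np.searchsorted(pcs, c)] = off

    def interp1(xs, x):
        x = min(max(x, xs[0]), xs[-1])  # clamp at grid edges
        j = np.searchsorted(xs, x)
        if j == 0:
            return 0, 0, 0.0
        if xs[j - 1] == x:
            return j - 1, j - 1, 0.0
        w = (x - xs[j - 1]) / (xs[j] - xs[j - 1])
        return j - 1, j, w

    ia0, ia1, wa = interp1(pas, p_aorta)
    ic0, ic1, wc = interp1(pcs, p_act)

    def blend(M):
        v00, v01 = M[ia0, ic0], M[ia0, ic1]
        v10, v11 = M[ia1, ic0], M[ia1, ic1]
        return float((1 - wa) * ((1 - wc) * v00 + wc * v01) + wa * ((1 - wc) * v10 + wc * v11))

    return blend(ton), blend(toff)


def synth_bench_data(seed=0, noise_sd=0.0, coeffs=DEFAULT_GAIN_COEFFS):
    """Synthetic bench characterization grid (silicone-loop experiment stand-in).

    Gains come from a hidden quadratic surface of the fitted form — monotone
    increasing in p_act and decreasing in p_aorta over the protocol grid —
    plus optional Gaussian noise; t_on sits near 0.3 s and t_off near 0.5 s
    with a mild p_act dependence.  Reproducible for a fixed seed.
    """
    if noise_sd < 0:
        raise DeviceError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    pa, pc = np.meshgrid(BENCH_P_AORTA, BENCH_P_ACT, indexing="ij")
    pa, pc = pa.ravel(), pc.ravel()
    g = np.array([gain(a, c, coeffs) for a, c in zip(pa, pc)])
    g = g + rng.normal(0.0, noise_sd, size=g.shape)
    t_on = 0.30 + 0.004 * (pc - 9.0)
    t_off = 0.50 + 0.006 * (pc - 9.0)
    return BenchGrid(p_aorta=pa, p_act=pc, g_exp=g, t_on=t_on, t_off=t_off)


def peak_displacement(model_run, dev):
    """Peak-to-trough device pocket displacement (mL) of a coupled model run."""
    x = model_run.column("x_dev")
    return float(x.max() - x.min())


def calibrate_correction(bench_peak_displacement, model_run_fn, lam_bracket=(0.0, 50.0), tol=0.01):
    """Correction factor λ matching the in-model peak device displacement.

    ``model_run_fn(lam)`` must run the coupled model at mean aortic pressure
    near 100 mmHg and return the peak pocket displacement (mL).  λ is found
    so the displacement matches the bench target within ``tol`` (relative).
    """
    if bench_peak_displacement == 0:
        return 0.0
    f = lambda lam: model_run_fn(lam) - bench_peak_displacement
    lo, hi = lam_bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise DeviceError("calibration failure: correction-factor root not bracketed")
    return float(brentq(f, lo, hi, rtol=tol * 0.5))
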