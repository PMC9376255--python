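"""Closed-loop assembly and fixed-step integration.

The loop runs LA -> mitral valve -> LV -> aortic valve -> aortic tree ->
Windkessel terminals -> common venous node -> venous resistance -> LA.  State
variables are the two chamber volumes, the two valve opening states, one
capacitor pressure per terminal and (with the device coupled) the device
pocket volume; everything else — node pressures, branch flows — is solved
algebraically from the rigid resistive tree at every evaluation.

Default integration mirrors the study conditions: explicit RK4 with a 0.1 ms
step over 10 cardiac cycles.  Initial conditions are refined from a
literature guess by a fixed-point minimum-squared-mismatch iteration on
single cycles, and a time-periodic state is detected from cycle-start values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel
from .chambers import ChamberParams
from .device import DeviceParams
from .network import OUTLET_NAMES, NetworkTopology
from .valves import ValveParams, blood_inertance

#: opening-state gate below which a valve passes no flow (also bounds the
#: stiffness of the orifice term), and the flow-decay time constant there
S_GATE = 0.05
TAU_GATE = 2e-3


def _physio_L(valve):
    return blood_inertance(valve.A_eff_max)

__all__ = [
    "SystemState",
    "Trajectory",
    "CardiovascularModel",
    "SimulationError",
    "NotPeriodicError",
    "detect_periodicity",
    "default_heart",
    "literature_initial_state",
]


class SimulationError(RuntimeError):
    """Integration diverged or the model could not be assembled."""


class NotPeriodicError(RuntimeError):
    """No periodic cycle found within the trajectory."""


@dataclass
class SystemState:
    """Full closed-loop state at one instant."""

    V_LA: float  # mL
    V_LV: float  # mL
    s_MV: float = 0.0
    s_AV: float = 0.0
    Q_MV: float = 0.0  # mL/s, transvalvular (inertial) flow
    Q_AV: float = 0.0  # mL/s
    terminal_pressures: dict = field(default_factory=dict)  # mmHg per terminal
    device_volume: float = 0.0  # mL
    t: float = 0.0

    def to_vector(self, terminal_order=OUTLET_NAMES):
        pc = [self.terminal_pressures.get(name, 0.0) for name in terminal_order]
        return np.array([self.V_LA, self.V_LV, self.s_MV, self.s_AV,
                         self.Q_MV, self.Q_AV, *pc, self.device_volume], dtype=float)

    @classmethod
    def from_vector(cls, y, terminal_order=OUTLET_NAMES, t=0.0):
        nt = len(terminal_order)
        return cls(
            V_LA=float(y[0]), V_LV=float(y[1]), s_MV=float(y[2]), s_AV=float(y[3]),
            Q_MV=float(y[4]), Q_AV=float(y[5]),
            terminal_pressures={name: float(y[6 + i]) for i, name in enumerate(terminal_order)},
            device_volume=float(y[6 + nt]), t=t,
        )


def literature_initial_state(terminal_pressure=80.0):
    """Literature-based first guess for the initial conditions."""
    return SystemState(
        V_LA=60.0, V_LV=120.0, s_MV=0.5, s_AV=0.0,
        terminal_pressures={name: terminal_pressure for name in OUTLET_NAMES},
    )


def default_heart(hr=60.0):
    """Default LA/LV elastance parameters at a given heart rate.

    LV activation starts at the cycle origin (R-wave convention); the atrial
    kick sits in late diastole and ends just before ventricular onset.
    """
    T = 60.0 / hr
    lv = ChamberParams(E_act_max=5.0, V0=10.0, A_pas=0.40, B_pas=0.035,
                       t_onset=0.0, t_sys=0.60 * T, peak_frac=0.95,
                       rise_power=0.5, label="LV")
    la = ChamberParams(E_act_max=0.45, V0=10.0, A_pas=0.45, B_pas=0.05,
                       t_onset=0.86 * T, t_sys=0.13 * T, label="LA")
    return lv, la


class Trajectory:
    """Uniformly sampled time histories of all states and derived quantities."""

    def __init__(self, data, dt, T, rec_stride, terminal_order=OUTLET_NAMES, meta=None):
        self.data = data
        self.dt = dt
        self.T = T
        self.rec_stride = rec_stride
        self.terminal_order = tuple(terminal_order)
        self.meta = meta or {}
        nt = len(self.terminal_order)
        self.columns = (
            ["time_s", "V_LA", "V_LV", "P_LA", "P_LV", "s_MV", "s_AV",
             "Q_MV", "Q_AV", "p_root", "p_device_node", "q_device", "x_dev",
             "p_sr", "p_ven", "Q_ven"]
            + [f"p_cap_{n}" for n in self.terminal_order]
            + [f"q_{n}" for n in self.terminal_order]
            + [f"p_{n}" for n in self.terminal_order]
        )
        assert data.shape[1] == 16 + 3 * nt

    def column(self, name):
        return self.data[:, self.columns.index(name)]

    @property
    def time(self):
        return self.data[:, 0]

    @property
    def samples_per_cycle(self):
        spc = self.T / (self.dt * self.rec_stride)
        return int(round(spc))

    @property
    def n_cycles(self):
        return int(round(self.time[-1] / self.T))

    def cycle_start_indices(self):
        """Row indices of the cycle boundaries (including the final boundary)."""
        spc = self.samples_per_cycle
        return list(range(0, self.data.shape[0], spc))

    def cycle(self, k):
        """Rows of cycle k (0-based), inclusive of both boundary samples."""
        spc = self.samples_per_cycle
        lo = k * spc
        hi = (k + 1) * spc
        if hi >= self.data.shape[0]:
            hi = self.data.shape[0] - 1
        if hi <= lo:
            raise IndexError(f"cycle {k} not contained in trajectory")
        return self.data[lo:hi + 1]

    def cycle_view(self, k):
        sub = Trajectory(self.cycle(k), self.dt, self.T, self.rec_stride,
                         self.terminal_order, self.meta)
        return sub

    def end_state(self):
        nt = len(self.terminal_order)
        row = self.data[-1]
        y = np.concatenate([[row[1], row[2], row[5], row[6], row[7], row[8]],
                            row[16:16 + nt], [row[12]]])
        return SystemState.from_vector(y, self.terminal_order, t=float(row[0]))

    def to_frame(self):
        return pd.DataFrame(self.data, columns=self.columns)

    def to_csv(self, path, meta_path=None):
        self.to_frame().to_csv(path, index=False)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump({"dt_s": self.dt, "cycle_s": self.T,
                           "rec_stride": self.rec_stride, **self.meta}, fh, indent=1)


class CardiovascularModel:
    """Assembled closed-loop model ready for integration.

    Parameters
    ----------
    network : NetworkTopology
        The arterial tree with tuned (or placeholder) terminals.
    lv, la : ChamberParams
    mv, av : ValveParams
    device : DeviceParams or None
        The counterpulsation element; ``None`` (or ``p_act == 0``) leaves the
        baseline circulation untouched.
    hr : float, bpm
    R_ven : float
        Venous return resistance from the common venous node into the LA.
    pa_mean_init : float
        Initial loop-pressure estimate feeding the device gain, refreshed
        every completed cycle from the running aortic-root mean.
    """

    def __init__(self, network: NetworkTopology, lv=None, la=None, mv=None, av=None,
                 device=None, hr=60.0, R_ven=0.03, pa_mean_init=95.0):
        network.validate()
        self.network = network
        if lv is None or la is None:
            d_lv, d_la = default_heart(hr)
            lv = lv or d_lv
            la = la or d_la
        self.lv = lv.validate(60.0 / hr)
        self.la = la.validate(60.0 / hr)
        self.mv = mv or ValveParams(A_eff_max=4.0, label="MV")
        self.av = av or ValveParams(A_eff_max=1.0,
                                    inertance_coeff=blood_inertance(1.0, 10.0),
                                    label="AV")
        self.device = device
        self.hr = hr
        self.R_ven = R_ven
        self.pa_mean_init = pa_mean_init
        self.terminal_order = tuple(OUTLET_NAMES)
        self._build_linear_maps()

    @property
    def T(self):
        return 60.0 / self.hr

    # ------------------------------------------------------------------ setup
    def _build_linear_maps(self):
        """Nodal analysis of the rigid resistive tree.

        Produces the affine maps [p_root, p_dev_node, p_outlets] =
        A8 @ p_cap + b_av Q_AV + b_dev q_dev used by the kernel.
        """
        net = self.network
        names = [s.name for s in net.segments]
        idx = {"root": 0}
        for i, name in enumerate(names):
            idx[name] = i + 1
        nn = len(idx)
        nt = len(self.terminal_order)

        G = np.zeros((nn, nn))
        for seg in net.segments:
            a = idx[net.parents[seg.name]]
            b = idx[seg.name]
            g = 1.0 / max(seg.resistance, 1e-9)
            G[a, a] += g
            G[b, b] += g
            G[a, b] -= g
            G[b, a] -= g

        B = np.zeros((nn, nt))
        for i, tname in enumerate(self.terminal_order):
            term = net.terminals[tname]
            node = idx[net.outlet_segments[tname]]
            g = 1.0 / term.R_proximal
            G[node, node] += g
            B[node, i] = g

        e_av = np.zeros(nn)
        e_av[idx["root"]] = 1.0
        e_dev = np.zeros(nn)
        e_dev[idx[net.device_insertion_site]] = 1.0

        rhs = np.column_stack([B, e_av, e_dev])
        sol = np.linalg.solve(G, rhs)

        rows = [idx["root"], idx[net.device_insertion_site]] + \
               [idx[net.outlet_segments[t]] for t in self.terminal_order]
        sel = sol[rows]
        self._A8 = np.ascontiguousarray(sel[:, :nt])
        self._b_av = np.ascontiguousarray(sel[:, nt])
        self._b_dev = np.ascontiguousarray(sel[:, nt + 1])
        self._Rp = np.array([net.terminals[t].R_proximal for t in self.terminal_order])
        self._Rd = np.array([net.terminals[t].R_distal for t in self.terminal_order])
        self._Cc = np.array([net.terminals[t].C for t in self.terminal_order])

    def _packed(self):
        lv = np.array([self.lv.A_pas, self.lv.B_pas, self.lv.V0, self.lv.E_act_max,
                       self.lv.t_onset, self.lv.t_sys, self.lv.peak_frac,
                       self.lv.rise_power])
        la = np.array([self.la.A_pas, self.la.B_pas, self.la.V0, self.la.E_act_max,
                       self.la.t_onset, self.la.t_sys, self.la.peak_frac,
                       self.la.rise_power])
        mv = np.array([self.mv.K_open, self.mv.K_close, self.mv.bernoulli_coeff,
                       self.mv.inertance_coeff or _physio_L(self.mv),
                       S_GATE, TAU_GATE])
        av = np.array([self.av.K_open, self.av.K_close, self.av.bernoulli_coeff,
                       self.av.inertance_coeff or _physio_L(self.av),
                       S_GATE, TAU_GATE])
        d = self.device
        if d is not None and d.active and any(c != 0 for c in d.gain_coeffs):
            # the pocket capacitance references pressure deviation from the
            # baseline mean: an unpressurized device exchanges no net volume
            dev = np.array([1.0, d.correction, d.C_sr, d.R_sr, d.p_act, d.dt_act,
                            d.t_on, d.t_off, d.k1, d.k2, self.pa_mean_init])
            gc = np.asarray(d.gain_coeffs, float)
        else:
            dev = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.3, 0.5, 1.0, 1.0, 0.0])
            gc = np.zeros(5)
        return lv, la, mv, av, dev, gc

    # ------------------------------------------------------------- evaluation
    def derivative(self, state: SystemState, t=None):
        """Time derivative of the state vector (for inspection and testing)."""
        y = state.to_vector(self.terminal_order)
        dy = np.empty_like(y)
        aux = np.empty(_kernel.N_AUX_HEAD + 2 * len(self.terminal_order))
        lv, la, mv, av, dev, gc = self._packed()
        _kernel._rhs(state.t if t is None else t, y, dy, aux, self.T, lv, la, mv, av,
                     self._A8, self._b_av, self._b_dev, self._Rp, self._Rd, self._Cc,
                     self.R_ven, dev, gc, self.pa_mean_init)
        names = _aux_names(self.terminal_order)
        info = dict(zip(names, aux))
        info["Q_MV"] = float(y[4])
        info["Q_AV"] = float(y[5])
        return dy, info

    def total_volume(self, state: SystemState):
        """Total stored blood volume: chambers + terminal capacitors + device pocket."""
        pc = np.array([state.terminal_pressures[t] for t in self.terminal_order])
        return state.V_LA + state.V_LV + float(self._Cc @ pc) + state.device_volume

    # ------------------------------------------------------------ integration
    def integrate(self, state0=None, dt=1e-4, n_cycles=10, rec_stride=1):
        """Fixed-step RK4 over n_cycles cardiac cycles; returns a Trajectory."""
        if dt <= 0 or n_cycles < 1:
            raise ValueError("need dt > 0 and n_cycles >= 1")
        if state0 is None:
            state0 = literature_initial_state()
        y0 = state0.to_vector(self.terminal_order)
        n_steps = int(round(n_cycles * self.T / dt))
        n_rec = n_steps // rec_stride + 1 + (1 if n_steps % rec_stride else 0)
        nt = len(self.terminal_order)
        out = np.empty((n_rec, 16 + 3 * nt))
        lv, la, mv, av, dev, gc = self._packed()
        fail = _kernel.run_fixed_step(
            y0, n_steps, dt, self.T, lv, la, mv, av,
            self._A8, self._b_av, self._b_dev, self._Rp, self._Rd, self._Cc,
            self.R_ven, dev, gc, self.pa_mean_init, rec_stride, out)
        if fail >= 0:
            raise SimulationError(f"state became non-finite at t = {fail * dt:.4f} s")
        meta = {"n_cycles": n_cycles, "hr_bpm": self.hr,
                "device_active": bool(dev[0] > 0.5)}
        return Trajectory(out, dt, self.T, rec_stride, self.terminal_order, meta)

    def estimate_initial_conditions(self, guess=None, dt=1e-4, tol=1e-4, max_iter=20):
        """Fixed-point refinement of the initial conditions.

        Simulates single cycles, taking each cycle-end state as the next
        guess, until the normalized squared cycle-start/cycle-end mismatch
        drops below ``tol``; warns and returns the best state found if not
        converged within ``max_iter`` iterations.
        """
        state = guess or literature_initial_state()
        spc = int(round(self.T / dt))
        best, best_m = state, np.inf
        for _ in range(max_iter):
            traj = self.integrate(state, dt=dt, n_cycles=1, rec_stride=spc)
            end = traj.end_state()
            a = state.to_vector(self.terminal_order)
            b = end.to_vector(self.terminal_order)
            scale = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1.0)
            m = float(np.mean(((b - a) / scale) ** 2))
            end.t = 0.0
            if m < best_m:
                best, best_m = end, m
            state = end
            if m < tol:
                return end
        warnings.warn(f"initial-condition iteration did not converge "
                      f"(mismatch {best_m:.2e} after {max_iter} cycles)")
        return best

    def with_device(self, device):
        """A copy of this model with a different device block (or None)."""
        m = CardiovascularModel.__new__(CardiovascularModel)
        m.__dict__.update(self.__dict__)
        m.device = device
        return m


def _aux_names(terminal_order):
    return (["P_LA", "P_LV", "p_root", "p_device_node",
             "q_device", "p_sr", "p_ven", "Q_ven"]
            + [f"p_{n}" for n in terminal_order]
            + [f"q_{n}" for n in terminal_order])


_STATE_COLUMNS = ("V_LA", "V_LV", "s_MV", "s_AV", "Q_MV", "Q_AV", "x_dev")


def detect_periodicity(traj: Trajectory, tol=0.01):
    """Smallest cycle index k (1-based) running identically to cycle k+1.

    Every state variable's cycle-start value must change by less than ``tol``
    relative between consecutive cycles.  Raises :class:`NotPeriodicError`
    when no such cycle exists in the trajectory.
    """
    starts = traj.cycle_start_indices()
    if len(starts) < 3:
        raise ValueError("need at least 2 complete cycles")
    cols = [traj.columns.index(c) for c in _STATE_COLUMNS]
    cols += [traj.columns.index(f"p_cap_{n}") for n in traj.terminal_order]
    vals = traj.data[np.asarray(starts)][:, cols]
    for k in range(len(starts) - 2):
        a, b = vals[k], vals[k + 1]
        denom = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-9)
        if np.all(np.abs(b - a) / denom < tol):
            return k + 1
    raise NotPeriodicError(f"no periodic cycle within {len(starts) - 1} cycles at tol={tol}")
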