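"""YAML run configuration: chambers, valves, device and integration blocks.

A config file mirrors the model structure::

    hr_bpm: 60
    geometry: null          # null -> packaged fixture, else a JSON path
    chambers:
      LV: {E_act_max: 5.0, V0: 10.0, A_pas: 0.4, B_pas: 0.035,
           t_onset: 0.0, t_sys: 0.45}
      LA: {E_act_max: 0.45, V0: 10.0, A_pas: 0.45, B_pas: 0.05,
           t_onset: 0.86, t_sys: 0.13}
    valves:
      MV: {K_open: 2.0, K_close: 2.0, A_eff_max: 4.0}
      AV: {K_open: 2.0, K_close: 2.0, A_eff_max: 3.5}
    device:
      p_act_psi: 12.0
      delay_ms: 650
      t_act_ms: 300
      C_sr: 0.05
      correction: 1.0
      gain_coeffs: null     # null -> fit from bench_csv or packaged surface
      bench_csv: null
    run: {cycles: 10, dt_ms: 0.1}

Unspecified blocks fall back to the defaults used throughout the package.
"""

from __future__ import annotations

import yaml

from .chambers import ChamberParams
from .device import DEFAULT_GAIN_COEFFS, BenchGrid, DeviceParams, fit_gain_surface, timing_lookup
from .network import build_network, load_geometry
from .simulator import CardiovascularModel, default_heart
from .valves import ValveParams

__all__ = ["load_config", "model_from_config", "device_from_config", "default_config"]


def default_config():
    return {
        "hr_bpm": 60.0,
        "geometry": None,
        "chambers": {},
        "valves": {},
        "device": None,
        "run": {"cycles": 10, "dt_ms": 0.1},
    }


def load_config(path):
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = default_config()
    merged.update(cfg)
    return merged


def _chamber(block, base):
    if not block:
        return base
    fields = {k: block[k] for k in
              ("E_act_max", "V0", "A_pas", "B_pas", "t_onset", "t_sys") if k in block}
    from dataclasses import replace
    return replace(base, **fields)


def _valve(block, base):
    if not block:
        return base
    kwargs = {k: block[k] for k in ("K_open", "K_close", "A_eff_max", "bernoulli_coeff")
              if k in block}
    return ValveParams(label=base.label, **kwargs)


def device_from_config(block):
    """Build a DeviceParams from a config device block (None stays None)."""
    if not block:
        return None
    coeffs = block.get("gain_coeffs")
    t_on, t_off = 0.3, 0.5
    if block.get("bench_csv"):
        grid = BenchGrid.from_csv(block["bench_csv"])
        if coeffs is None:
            coeffs, _ = fit_gain_surface(grid)
        t_on, t_off = timing_lookup(block.get("p_act_psi", 12.0), 100.0, grid)
    if coeffs is None:
        coeffs = DEFAULT_GAIN_COEFFS
    return DeviceParams(
        p_act=block.get("p_act_psi", 12.0),
        dt_act=block.get("delay_ms", 650.0) / 1000.0,
        t_act=block.get("t_act_ms", 300.0) / 1000.0,
        t_on=block.get("t_on_s", t_on),
        t_off=block.get("t_off_s", t_off),
        C_sr=block.get("C_sr", 0.05),
        correction=block.get("correction", 1.0),
        gain_coeffs=tuple(coeffs),
    )


def model_from_config(cfg):
    """Assemble a CardiovascularModel from a (loaded) configuration dict."""
    hr = cfg.get("hr_bpm", 60.0)
    geometry = load_geometry(cfg["geometry"]) if cfg.get("geometry") else None
    net = build_network(geometry)
    lv0, la0 = default_heart(hr)
    chambers = cfg.get("chambers") or {}
    valves = cfg.get("valves") or {}
    return CardiovascularModel(
        net,
        lv=_chamber(chambers.get("LV"), lv0),
        la=_chamber(chambers.get("LA"), la0),
        mv=_valve(valves.get("MV"), ValveParams(A_eff_max=4.0, label="MV")),
        av=_valve(valves.get("AV"), ValveParams(A_eff_max=3.5, label="AV")),
        device=device_from_config(cfg.get("device")),
        hr=hr,
    )
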