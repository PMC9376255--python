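"""Arterial network construction: Poiseuille segments and RCR Windkessel terminals.

The aortic arch and its branches are represented as a tree of purely resistive
vessel segments (rigid walls: segments store no volume).  Each segment's
resistance follows from Poiseuille flow through its mean lumen area and is
split into three equal sub-resistors placed in series.  Each outlet is closed
by a three-element Windkessel (proximal resistance, capacitance, distal
resistance) standing in for the distal vascular bed; the Windkessel values are
placeholders until calibration tunes them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VesselSegment",
    "TerminalRCR",
    "NetworkTopology",
    "GeometryError",
    "poiseuille_resistance",
    "split_into_series",
    "build_network",
    "load_geometry",
    "default_geometry",
    "OUTLET_NAMES",
]

#: The six outlets of the left-heart systemic tree (coronaries branch at the
#: aortic root; the descending aorta carries the lower-body/systemic bed).
OUTLET_NAMES = (
    "right_subclavian",
    "right_carotid",
    "left_carotid",
    "left_subclavian",
    "coronaries",
    "descending_aorta",
)

#: dyn·s/cm^5 per mmHg·s/mL
_DYN_PER_MMHG = 1333.22

#: Blood (and blood-analog) dynamic viscosity, poise.
DEFAULT_VISCOSITY = 0.04


class GeometryError(ValueError):
    """Invalid vessel geometry or network description."""


def poiseuille_resistance(lumen_areas, length, viscosity=DEFAULT_VISCOSITY):
    """Poiseuille resistance of a vessel segment, in mmHg·s/mL.

    The segment is reduced to a single resistor based on the arithmetic mean
    of its sampled cross-sectional areas:  R = 8·pi·mu·L / A_mean^2
    (equivalent to the familiar 8·mu·L/(pi·r^4) with A = pi·r^2), converted
    from dyn·s/cm^5 to mmHg·s/mL.

    Parameters
    ----------
    lumen_areas : sequence of float
        Sampled cross-sectional areas along the centerline, cm^2.
    length : float
        Segment length, cm.
    viscosity : float
        Dynamic viscosity, poise (g/(cm·s)).
    """
    areas = np.asarray(lumen_areas, dtype=float)
    if areas.size == 0 or np.any(areas <= 0):
        raise GeometryError("lumen areas must be positive and non-empty")
    if viscosity <= 0:
        raise GeometryError("viscosity must be positive")
    if length < 0:
        raise GeometryError("length must be non-negative")
    mean_area = float(areas.mean())
    r_cgs = 8.0 * np.pi * viscosity * length / mean_area**2
    return r_cgs / _DYN_PER_MMHG


def split_into_series(resistance):
    """Split a segment resistance into three equal series sub-resistors."""
    if resistance < 0:
        raise GeometryError("resistance must be non-negative")
    third = resistance / 3.0
    return (third, third, third)


@dataclass
class VesselSegment:
    """A resistive aortic segment (rigid wall, no stored volume)."""

    name: str
    length: float  # cm
    lumen_areas: tuple  # cm^2 samples along the centerline
    resistance: float = None  # mmHg·s/mL
    sub_resistances: tuple = None
    inertance: float = 0.0  # mmHg·s^2/mL, optional

    def __post_init__(self):
        if self.resistance is None:
            self.resistance = poiseuille_resistance(self.lumen_areas, self.length)
        if self.sub_resistances is None:
            self.sub_resistances = split_into_series(self.resistance)
        if self.length > 0 and self.resistance <= 0:
            raise GeometryError(f"segment {self.name!r}: non-positive resistance")
        if abs(sum(self.sub_resistances) - self.resistance) > 1e-12 * max(self.resistance, 1e-30):
            raise GeometryError(f"segment {self.name!r}: sub-resistances do not sum to total")


@dataclass
class TerminalRCR:
    """Three-element Windkessel bed closing one outlet."""

    name: str
    R_proximal: float  # mmHg·s/mL
    C: float  # mL/mmHg
    R_distal: float  # mmHg·s/mL
    stored_pressure: float = 0.0  # mmHg, capacitor state

    def __post_init__(self):
        if min(self.R_proximal, self.C, self.R_distal) <= 0:
            raise GeometryError(f"terminal {self.name!r}: R and C must be positive")


@dataclass
class NetworkTopology:
    """Validated arterial tree rooted at the aortic valve.

    ``junctions`` maps each parent name ("root" for the aortic valve outlet)
    to the names of its child segments.  ``device_insertion_site`` names the
    edge (the distal node of that segment) between the first two ascending
    aorta segments where the counterpulsation element couples in.
    """

    segments: list = field(default_factory=list)
    junctions: dict = field(default_factory=dict)
    terminals: dict = field(default_factory=dict)
    device_insertion_site: str = ""
    parents: dict = field(default_factory=dict)
    outlet_segments: dict = field(default_factory=dict)  # terminal name -> feeding segment

    def segment(self, name):
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def path_resistance(self, outlet):
        """Summed segment resistance from the root to (and including) an outlet segment."""
        r = 0.0
        name = outlet
        while name != "root":
            seg = self.segment(name)
            r += seg.resistance
            name = self.parents[name]
        return r

    def validate(self):
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise GeometryError("duplicate segment names")
        for t in OUTLET_NAMES:
            if t not in self.terminals:
                raise GeometryError(f"missing terminal for outlet {t!r}")
        # tree check: every segment reaches root through parents, no cycles
        for name in names:
            seen = set()
            cur = name
            while cur != "root":
                if cur in seen:
                    raise GeometryError(f"cyclic topology at {cur!r}")
                seen.add(cur)
                if cur not in self.parents:
                    raise GeometryError(f"segment {cur!r} detached from root")
                cur = self.parents[cur]
        if self.device_insertion_site not in names:
            raise GeometryError("device_insertion_site does not refer to an existing edge")
        return self

    def summary_frame(self):
        """Per-segment resistances and per-terminal RCR values as a DataFrame."""
        rows = []
        for s in self.segments:
            rows.append({
                "element": s.name, "kind": "segment", "length_cm": s.length,
                "R_mmHg_s_per_mL": s.resistance,
                "R1": s.sub_resistances[0], "R2": s.sub_resistances[1],
                "R3": s.sub_resistances[2],
                "C_mL_per_mmHg": np.nan, "R_distal": np.nan,
            })
        for t in self.terminals.values():
            rows.append({
                "element": t.name, "kind": "terminal", "length_cm": np.nan,
                "R_mmHg_s_per_mL": t.R_proximal,
                "R1": np.nan, "R2": np.nan, "R3": np.nan,
                "C_mL_per_mmHg": t.C, "R_distal": t.R_distal,
            })
        return pd.DataFrame(rows)

    def write_summary(self, path):
        self.summary_frame().to_csv(path, index=False)


_REQUIRED_FIELDS = {"name", "parent", "length_cm", "areas_cm2"}
_ALLOWED_FIELDS = _REQUIRED_FIELDS | {"terminal", "inertance"}


def default_geometry():
    """Load the packaged adult aortic geometry description."""
    with resources.files("counterpulse.data").joinpath("geometry.json").open() as fh:
        return json.load(fh)


def load_geometry(path):
    """Load a geometry description from a JSON file."""
    with open(path) as fh:
        return json.load(fh)


def build_network(geometry=None, viscosity=DEFAULT_VISCOSITY):
    """Build a validated :class:`NetworkTopology` from a geometry description.

    The geometry is a list of segment records (``name``, ``parent``,
    ``length_cm``, ``areas_cm2``; outlet segments carry a ``terminal`` flag
    naming one of the six outlets).  Terminal RCR values are initialised to
    placeholder values and later tuned by calibration.
    """
    if geometry is None:
        geometry = default_geometry()
    if isinstance(geometry, dict):
        geometry = geometry["segments"]

    net = NetworkTopology()
    terminal_for = {}
    for rec in geometry:
        unknown = set(rec) - _ALLOWED_FIELDS
        if unknown:
            raise GeometryError(f"unknown field(s) {sorted(unknown)} in segment {rec.get('name')!r}")
        missing = _REQUIRED_FIELDS - set(rec)
        if missing:
            raise GeometryError(f"missing field(s) {sorted(missing)} in segment {rec.get('name')!r}")
        seg = VesselSegment(
            name=rec["name"],
            length=float(rec["length_cm"]),
            lumen_areas=tuple(float(a) for a in rec["areas_cm2"]),
            resistance=poiseuille_resistance(rec["areas_cm2"], rec["length_cm"], viscosity),
            inertance=float(rec.get("inertance", 0.0)),
        )
        net.segments.append(seg)
        net.parents[seg.name] = rec["parent"]
        net.junctions.setdefault(rec["parent"], []).append(seg.name)
        if "terminal" in rec:
            tname = rec["terminal"]
            if tname not in OUTLET_NAMES:
                raise GeometryError(f"unknown terminal name {tname!r} on segment {seg.name!r}")
            terminal_for[tname] = seg.name

    for tname in OUTLET_NAMES:
        if tname not in terminal_for:
            raise GeometryError(f"geometry omits outlet {tname!r}")

    # placeholder Windkessels; calibration overwrites these
    for tname, seg_name in terminal_for.items():
        net.outlet_segments[tname] = seg_name
        net.terminals[tname] = TerminalRCR(name=tname, R_proximal=0.1, C=0.2, R_distal=1.0)

    # device couples between the first two ascending-aorta elements
    asc = [s.name for s in net.segments if s.name.startswith("asc_aorta")]
    if len(asc) < 2:
        raise GeometryError("geometry needs at least two ascending-aorta segments for the device edge")
    net.device_insertion_site = asc[0]
    return net.validate()
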