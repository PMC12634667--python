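"""Parametric geometry of the pillar-array barrier and the MPS device.

The barrier is a line of cylindrical pillars separating a cell chamber from a
media channel.  The gap between adjacent pillar surfaces is the *pore size*;
the plan-view void fraction of the rectangular barrier region is the
*porosity*; pore size together with the pillar (fenestration) height sets the
hydraulic diameter D_h = 2hw/(h+w) that makes a shallow rectangular opening
comparable to a membrane pore.

Lengths are stored in micrometres throughout; solvers convert to SI
internally.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GapConvention",
    "PillarLayout",
    "FenestraKind",
    "FenestraGeometry",
    "DeviceGeometry",
    "FluidProperties",
    "hydraulic_diameter",
    "build_pillar_layout",
    "porosity",
    "porous_volume",
    "load_device_config",
]

#: relative tolerance for "layout fits region" checks
_FIT_RTOL = 1e-9


class GapConvention(str, enum.Enum):
    """How pore gaps tile the barrier line.

    ``end_gaps``: n pillars separated from each other *and from the region
    ends* by the pore size (n+1 gaps).  ``internal_only``: gaps only between
    pillars (n-1 gaps), pillars flush with the region ends.
    """

    end_gaps = "end_gaps"
    internal_only = "internal_only"


class FenestraKind(str, enum.Enum):
    straight_channel = "straight_channel"
    pillar_array = "pillar_array"


@dataclass(frozen=True)
class PillarLayout:
    """A row of equal cylindrical pillars in a rectangular barrier region.

    Parameters are in micrometres.  ``region_length`` runs along the barrier
    line (the direction of the pillar row); ``region_width`` runs across it
    (the flow direction through the barrier).
    """

    region_length: float
    region_width: float
    n_pillars: int
    pillar_diameter: float
    pore_size: float
    height: float
    gap_convention: GapConvention = GapConvention.end_gaps

    def __post_init__(self) -> None:
        for name in ("region_length", "region_width", "height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_pillars < 0:
            raise ValueError("n_pillars must be non-negative")
        if self.pore_size < 0:
            raise ValueError("pore_size must be non-negative")
        if self.n_pillars > 0:
            if self.pillar_diameter <= 0:
                raise ValueError("pillar_diameter must be positive")
            n, d, g = self.n_pillars, self.pillar_diameter, self.pore_size
            n_gaps = n + 1 if self.gap_convention is GapConvention.end_gaps else n - 1
            occupied = n * d + n_gaps * g
            if not math.isclose(occupied, self.region_length,
                                rel_tol=1e-6, abs_tol=1e-6):
                raise ValueError(
                    f"layout does not fit region: {n} pillars of {d} um with "
                    f"{n_gaps} gaps of {g} um occupy {occupied} um, region is "
                    f"{self.region_length} um"
                )

    @property
    def pitch(self) -> float:
        """Center-to-center pillar spacing (um)."""
        return self.pillar_diameter + self.pore_size

    def pillar_centers(self) -> np.ndarray:
        """Pillar center coordinates along the barrier line (um)."""
        n, d, g = self.n_pillars, self.pillar_diameter, self.pore_size
        if n == 0:
            return np.empty(0)
        if self.gap_convention is GapConvention.end_gaps:
            first = g + d / 2.0
        else:
            first = d / 2.0
        return first + self.pitch * np.arange(n)

    def to_frame(self) -> pd.DataFrame:
        """Pillar centers/diameters as a DataFrame (CSV-exportable)."""
        c = self.pillar_centers()
        return pd.DataFrame(
            {"center_um": c, "diameter_um": np.full(c.size, self.pillar_diameter)}
        )


@dataclass(frozen=True)
class FenestraGeometry:
    """A single opening through the barrier: straight slot or pillar array."""

    kind: FenestraKind
    height: float                       # um, out-of-plane depth of the opening
    width_or_layout: Union[float, PillarLayout]
    length: float                       # um, extent in the flow direction

    def __post_init__(self) -> None:
        if self.height <= 0 or self.length <= 0:
            raise ValueError("height and length must be positive")
        if self.kind is FenestraKind.straight_channel:
            if not isinstance(self.width_or_layout, (int, float)):
                raise TypeError("straight_channel needs a numeric width")
            if self.width_or_layout <= 0:
                raise ValueError("channel width must be positive")
        else:
            if not isinstance(self.width_or_layout, PillarLayout):
                raise TypeError("pillar_array needs a PillarLayout")

    @property
    def pore_width(self) -> float:
        """In-plane width of the narrowest opening (um)."""
        if self.kind is FenestraKind.straight_channel:
            return float(self.width_or_layout)
        return self.width_or_layout.pore_size

    @property
    def hydraulic_diameter(self) -> float:
        """D_h of the (narrowest) rectangular opening cross-section (um)."""
        return hydraulic_diameter(self.height, self.pore_width)


@dataclass(frozen=True)
class DeviceGeometry:
    """Plan-view layout of the MPS: central cell chamber flanked by media
    channels, separated by barrier strips.

    Defaults are the cardiac device: 300 um chamber, 100 um media channels,
    150 um chamber/channel heights, with three 75 um force-measuring pillars
    spaced 225 um inside the chamber.
    """

    chamber_width: float = 300.0
    chamber_height: float = 150.0
    channel_width: float = 100.0
    channel_height: float = 150.0
    barrier: Optional[FenestraGeometry] = None
    chamber_pillars: bool = True
    chamber_pillar_diameter: float = 75.0
    chamber_pillar_spacing: float = 225.0
    chamber_pillar_count: int = 3

    def __post_init__(self) -> None:
        for name in ("chamber_width", "chamber_height",
                     "channel_width", "channel_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FluidProperties:
    """Interfacial and bulk properties of the working liquid (water/medium)."""

    surface_tension: float = 0.072      # N/m, liquid-vapour
    contact_angle_deg: float = 66.0     # advancing angle on the channel walls
    viscosity: float = 1.0e-3           # Pa s
    density: float = 1000.0             # kg/m3

    def __post_init__(self) -> None:
        if self.surface_tension < 0:
            raise ValueError("surface_tension must be non-negative")
        if not 0.0 < self.contact_angle_deg < 180.0:
            raise ValueError("contact_angle_deg must lie in (0, 180)")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")

    @property
    def contact_angle(self) -> float:
        """Contact angle in radians."""
        return math.radians(self.contact_angle_deg)


def hydraulic_diameter(height: float, width: float) -> float:
    """Hydraulic diameter 2hw/(h+w) of a rectangular duct (um in, um out)."""
    if height <= 0 or width <= 0:
        raise ValueError("height and width must be positive")
    return 2.0 * height * width / (height + width)


def build_pillar_layout(
    n_pillars: int,
    pore_size: float,
    region_length: float,
    gap_convention: GapConvention = GapConvention.end_gaps,
    *,
    region_width: float = 125.0,
    height: float = 2.0,
) -> PillarLayout:
    """Solve for the pillar diameter that tiles ``region_length`` exactly.

    Under ``end_gaps`` (default) there are n+1 gaps of ``pore_size``, so
    d = (L - (n+1) g)/n; under ``internal_only`` d = (L - (n-1) g)/n.
    """
    if n_pillars < 1:
        raise ValueError("n_pillars must be >= 1")
    gap_convention = GapConvention(gap_convention)
    n_gaps = n_pillars + 1 if gap_convention is GapConvention.end_gaps else n_pillars - 1
    d = (region_length - n_gaps * pore_size) / n_pillars
    if d <= 0:
        raise ValueError(
            f"infeasible layout: {n_pillars} pillars with {n_gaps} gaps of "
            f"{pore_size} um leave diameter {d:.3g} um in {region_length} um"
        )
    return PillarLayout(
        region_length=region_length,
        region_width=region_width,
        n_pillars=n_pillars,
        pillar_diameter=d,
        pore_size=pore_size,
        height=height,
        gap_convention=gap_convention,
    )


def porosity(layout: PillarLayout) -> float:
    """Plan-view void fraction of the barrier region.

    1 - (total pillar plan area)/(region plan area); independent of pillar
    height.  Pillars are assumed fully inside the region.
    """
    area = layout.region_length * layout.region_width
    solid = layout.n_pillars * math.pi * (layout.pillar_diameter / 2.0) ** 2
    phi = 1.0 - solid / area
    if phi < 0:
        raise ValueError("pillars overlap or exceed the region area")
    return phi


def porous_volume(layout: PillarLayout) -> float:
    """Void volume of the barrier region (um^3); exactly linear in height."""
    return porosity(layout) * layout.region_length * layout.region_width * layout.height


# ---------------------------------------------------------------------------
# config I/O


def _fenestra_from_dict(d: dict) -> FenestraGeometry:
    kind = FenestraKind(d["kind"])
    if kind is FenestraKind.straight_channel:
        wl: Union[float, PillarLayout] = float(d["width"])
    else:
        lay = d["layout"]
        wl = build_pillar_layout(
            n_pillars=int(lay["n_pillars"]),
            pore_size=float(lay["pore_size"]),
            region_length=float(lay["region_length"]),
            gap_convention=GapConvention(lay.get("gap_convention", "end_gaps")),
            region_width=float(lay.get("region_width", d.get("length", 125.0))),
            height=float(d["height"]),
        )
    return FenestraGeometry(
        kind=kind,
        height=float(d["height"]),
        width_or_layout=wl,
        length=float(d.get("length", 125.0)),
    )


def load_device_config(path: Union[str, Path]) -> DeviceGeometry:
    """Read a device geometry from a YAML or JSON config with explicit units.

    The file must declare ``units: um``; all lengths are micrometres.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data.get("units", "um") != "um":
        raise ValueError(f"unsupported units {data.get('units')!r}; use 'um'")
    barrier = _fenestra_from_dict(data["barrier"]) if "barrier" in data else None
    dev = data.get("device", {})
    return DeviceGeometry(
        chamber_width=float(dev.get("chamber_width", 300.0)),
        chamber_height=float(dev.get("chamber_height", 150.0)),
        channel_width=float(dev.get("channel_width", 100.0)),
        channel_height=float(dev.get("channel_height", 150.0)),
        barrier=barrier,
        chamber_pillars=bool(dev.get("chamber_pillars", True)),
    )
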