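"""Site tidal levels by inverse-distance interpolation from admiralty ports.

A site's six mean tidal levels — Highest Astronomical Tide (HAT), Mean High
Water Spring/Neap (MHWS/MHWN), Mean Water Spring (MWS) and Mean Low Water
Neap/Spring (MLWN/MLWS) — are interpolated from the weighted mean of
surrounding ports' predicted levels, using ports up to 30 km away, after
converting each port from Chart Datum (CD) to Ordnance Datum Newlyn (ODN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LEVEL_NAMES",
    "PortRecord",
    "TidalLevels",
    "TideDataError",
    "to_odn",
    "interpolate_tidal_levels",
    "read_ports_csv",
]

LEVEL_NAMES = ("hat", "mhws", "mhwn", "mws", "mlwn", "mlws")

DEFAULT_RADIUS_M = 30_000.0


class TideDataError(ValueError):
    """Port or level data violate the tidal-level ordering or coverage."""


def _check_ordering(levels: tuple[float, ...], context: str) -> None:
    for hi, lo in zip(LEVEL_NAMES[:-1], LEVEL_NAMES[1:]):
        i, j = LEVEL_NAMES.index(hi), LEVEL_NAMES.index(lo)
        if levels[i] < levels[j]:
            raise TideDataError(
                f"{context}: {hi.upper()}={levels[i]} < {lo.upper()}={levels[j]} "
                "violates the tidal-level ordering"
            )


@dataclass(frozen=True)
class TidalLevels:
    """The six mean tidal levels for one site, in metres ODN."""

    hat: float
    mhws: float
    mhwn: float
    mws: float
    mlwn: float
    mlws: float

    def __post_init__(self) -> None:
        _check_ordering(self.as_tuple(), "tidal levels")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.hat, self.mhws, self.mhwn, self.mws, self.mlwn, self.mlws)


@dataclass(frozen=True)
class PortRecord:
    """One port's six predicted tidal levels relative to Chart Datum.

    ``cd_to_odn`` is the additive offset converting CD levels to ODN
    (typically negative: Chart Datum sits below ODN's zero).
    """

    name: str
    x: float
    y: float
    levels_cd: tuple[float, ...]
    cd_to_odn: float

    def __post_init__(self) -> None:
        if len(self.levels_cd) != len(LEVEL_NAMES):
            raise TideDataError(
                f"port '{self.name}': expected {len(LEVEL_NAMES)} levels"
            )
        if not math.isfinite(self.cd_to_odn):
            raise TideDataError(f"port '{self.name}': non-finite datum offset")
        _check_ordering(self.levels_cd, f"port '{self.name}'")


def to_odn(port: PortRecord) -> PortRecord:
    """Shift a port's levels from Chart Datum to ODN by its datum offset."""
    shifted = tuple(v + port.cd_to_odn for v in port.levels_cd)
    _check_ordering(shifted, f"port '{port.name}' after datum conversion")
    return PortRecord(name=port.name, x=port.x, y=port.y, levels_cd=shifted,
                      cd_to_odn=0.0)


def interpolate_tidal_levels(site_xy: tuple[float, float],
                             ports: list[PortRecord],
                             radius: float = DEFAULT_RADIUS_M,
                             power: float = 1.0) -> TidalLevels:
    """Inverse-distance weighted mean of the surrounding ports' ODN levels.

    Only ports within ``radius`` (default 30 km, planar Euclidean distance in
    the projected CRS) contribute, with weights 1/d**power. A port exactly at
    the site returns its levels verbatim.
    """
    sx, sy = site_xy
    odn_ports = [to_odn(p) for p in ports]
    within: list[tuple[float, PortRecord]] = []
    nearest = math.inf
    for p in odn_ports:
        d = math.hypot(p.x - sx, p.y - sy)
        nearest = min(nearest, d)
        if d <= radius:
            within.append((d, p))
    if not within:
        raise TideDataError(
            f"no port within {radius / 1000:.0f} km of site "
            f"(nearest port is {nearest / 1000:.1f} km away)"
        )
    for d, p in within:
        if d == 0.0:
            return TidalLevels(*p.levels_cd)
    w = np.array([1.0 / d**power for d, _ in within])
    levels = np.array([p.levels_cd for _, p in within])
    mean = (w[:, None] * levels).sum(axis=0) / w.sum()
    return TidalLevels(*mean)


def read_ports_csv(path) -> list[PortRecord]:
    """Read a port table: name,x,y,hat,mhws,mhwn,mws,mlwn,mlws,cd_to_odn."""
    import pandas as pd

    df = pd.read_csv(path)
    required = ["name", "x", "y", *LEVEL_NAMES, "cd_to_odn"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TideDataError(f"port table missing columns: {missing}")
    return [
        PortRecord(
            name=str(row["name"]), x=float(row["x"]), y=float(row["y"]),
            levels_cd=tuple(float(row[k]) for k in LEVEL_NAMES),
            cd_to_odn=float(row["cd_to_odn"]),
        )
        for _, row in df.iterrows()
    ]
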