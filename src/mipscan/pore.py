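"""Pore-diameter profiles: gap filling and substrate size feasibility.

Channel-profiling tools report the pore diameter only at positions where a
pore center was detected, leaving gaps along the channel axis.  A continuous
profile is reconstructed on the integer grid spanning the observed range by
piecewise-linear interpolation (no extrapolation beyond the range); observed
points are preserved exactly.  The size check at the ar/R constriction is a
*necessary-size heuristic* only — pore diameter alone does not determine
selectivity — and is never merged into the signature-based predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PoreDiameterProfile:
    """Ordered (axis position, diameter in angstrom) pairs; gaps permitted."""

    positions: tuple
    diameters: tuple

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.diameters):
            raise ValueError("positions and diameters differ in length")
        pos = list(self.positions)
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("positions must be strictly increasing")
        if any(d <= 0 for d in self.diameters):
            raise ValueError("diameters must be positive")

    def __len__(self) -> int:
        return len(self.positions)

    def as_dict(self) -> dict:
        return dict(zip(self.positions, self.diameters))


def read_pore_table(path) -> PoreDiameterProfile:
    """Two-column (position, diameter) TSV, tolerant of header/comment lines."""
    points = []
    for line in open(path):
        parts = line.replace(",", "\t").split()
        if len(parts) < 2:
            continue
        try:
            pos, diam = float(parts[0]), float(parts[1])
        except ValueError:
            continue  # header or annotation line
        points.append((pos, diam))
    points.sort()
    if len(points) < 2:
        raise ValueError(f"{path}: fewer than 2 data points")
    positions = tuple(p for p, _ in points)
    if len(set(positions)) != len(positions):
        raise ValueError(f"{path}: duplicate positions")
    return PoreDiameterProfile(positions, tuple(d for _, d in points))


def interpolate_profile(profile: PoreDiameterProfile) -> PoreDiameterProfile:
    """Complete profile on the integer grid spanning the observed range.

    Observed points are preserved bit-for-bit (they are carried through, also
    at non-integer positions); missing integer positions are filled by linear
    interpolation between the nearest flanking observations.  Values outside
    the observed range are never produced.
    """
    if len(profile) < 2:
        raise ValueError("need at least 2 points to interpolate")
    lo, hi = profile.positions[0], profile.positions[-1]
    grid = set(range(math.ceil(lo), math.floor(hi) + 1))
    out_positions = sorted(grid | set(profile.positions))
    observed = profile.as_dict()
    xs = np.asarray(profile.positions, dtype=float)
    ys = np.asarray(profile.diameters, dtype=float)
    diameters = [
        observed[p] if p in observed else float(np.interp(p, xs, ys))
        for p in out_positions
    ]
    return PoreDiameterProfile(tuple(out_positions), tuple(diameters))


def diameter_at(profile: PoreDiameterProfile, position: float) -> float:
    """Interpolated diameter at one axis position (must be within range)."""
    if not profile.positions[0] <= position <= profile.positions[-1]:
        raise ValueError("position outside the observed range")
    observed = profile.as_dict()
    if position in observed:
        return observed[position]
    xs = np.asarray(profile.positions, dtype=float)
    ys = np.asarray(profile.diameters, dtype=float)
    return float(np.interp(position, xs, ys))


def feasibility_at_filter(diameter_at_filter: float, substrate: str, table) -> bool:
    """Necessary-size heuristic: pore at the ar/R filter admits the substrate.

    True iff the pore diameter is >= the substrate diameter (boundary counts
    as feasible).  ``table`` is a :class:`~mipscan.io.SubstrateSignatureTable`.
    """
    if diameter_at_filter <= 0:
        raise ValueError("pore diameter must be positive")
    try:
        substrate_diameter = table.diameter_of(substrate)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    return diameter_at_filter >= substrate_diameter
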