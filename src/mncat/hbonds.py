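"""Geometric hydrogen-bond detection and occupancy statistics.

A donor–hydrogen–acceptor triple forms a hydrogen bond in a frame iff the
donor–acceptor distance is at most 3.5 Å AND the D-H…A angle (measured at
the hydrogen; 180° = linear) is at least 150°.  Both boundaries are
inclusive.  Occupancy of a triple over a trajectory is the fraction of
frames in which the criterion holds — the standard stability measure for a
proton-transfer network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DegenerateGeometryError, bond_angle, distance

__all__ = ["HBondCriterion", "HBondEvent", "hbond_filter", "hbond_occupancy"]


@dataclass
class HBondCriterion:
    max_distance: float = 3.5   # Å, donor-acceptor
    min_angle: float = 150.0    # degrees, D-H...A at the hydrogen

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0.0 < self.min_angle <= 180.0):
            raise ValueError("angle cutoff must lie in (0, 180]")


@dataclass
class HBondEvent:
    frame: int
    donor: int
    hydrogen: int
    acceptor: int
    distance: float   # Å
    angle: float      # degrees


def hbond_filter(
    positions: np.ndarray,
    triples: list[tuple[int, int, int]],
    criterion: HBondCriterion | None = None,
    frame: int = 0,
) -> list[HBondEvent]:
    """Hydrogen bonds present in one frame, as events; boundaries are inclusive."""
    criterion = criterion or HBondCriterion()
    positions = np.asarray(positions, dtype=float)
    events: list[HBondEvent] = []
    for d, h, a in triples:
        if np.allclose(positions[h], positions[d]) or np.allclose(positions[h], positions[a]):
            raise DegenerateGeometryError(
                f"hydrogen {h} coincides with donor/acceptor in triple ({d}, {h}, {a})"
            )
        r_da = distance(positions[d], positions[a])
        theta = bond_angle(positions[d], positions[h], positions[a])
        if r_da <= criterion.max_distance and theta >= criterion.min_angle:
            events.append(HBondEvent(frame, d, h, a, r_da, theta))
    return events


def hbond_occupancy(
    trajectory,
    triples: list[tuple[int, int, int]],
    criterion: HBondCriterion | None = None,
) -> np.ndarray:
    """Per-triple fraction of frames (in [0, 1]) satisfying the criterion.

    ``trajectory`` is a :class:`~mncat.dynamics.Trajectory` or any iterable
    of (N, 3) coordinate frames.
    """
    criterion = criterion or HBondCriterion()
    frames = getattr(trajectory, "frames", trajectory)
    counts = np.zeros(len(triples))
    n_frames = 0
    for k, frame in enumerate(frames):
        n_frames += 1
        for j, (d, h, a) in enumerate(triples):
            events = hbond_filter(frame, [(d, h, a)], criterion, frame=k)
            if events:
                counts[j] += 1
    if n_frames == 0:
        raise ValueError("occupancy needs at least one frame")
    return counts / n_frames
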