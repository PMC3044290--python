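"""Geometric hydrogen-bond detection and per-bond presence time series."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import Conformation, Topology, Trajectory

__all__ = [
    "DetectionCriteria",
    "HBondID",
    "OccurrenceSeries",
    "detect_hbonds",
    "build_presence_matrix",
    "donor_hydrogen_pairs",
    "acceptor_serials",
    "occurrences_to_csv",
]

#: Heavy-atom chemistry allowed for donors and acceptors.
DONOR_ACCEPTOR_ELEMENTS = frozenset({"N", "O", "S"})


@dataclass(frozen=True)
class DetectionCriteria:
    """Geometric H-bond criteria: dist(H,A) <= ``max_ha``, dist(D,A) <=
    ``max_da`` (Angstrom) and angle(D,H,A) >= ``min_angle_dha`` (degrees)."""

    max_ha: float = 2.5
    max_da: float = 3.5
    min_angle_dha: float = 90.0


@dataclass(frozen=True, order=True)
class HBondID:
    """Identity of one hydrogen bond: the (donor, hydrogen, acceptor)
    atom-serial triple, persistent across conformations."""

    donor_serial: int
    hydrogen_serial: int
    acceptor_serial: int


@dataclass
class OccurrenceSeries:
    """Boolean presence vector of one bond, indexed by tick."""

    bond: HBondID
    presence: np.ndarray

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)

    def __len__(self) -> int:
        return len(self.presence)


def donor_hydrogen_pairs(topology: Topology) -> list[tuple[int, int]]:
    """All covalent (donor, hydrogen) pairs with an N/O/S donor."""
    pairs = []
    for h_serial, d_serial in sorted(topology.hydrogen_donor.items()):
        if topology.atoms[d_serial].element.upper() in DONOR_ACCEPTOR_ELEMENTS:
            pairs.append((d_serial, h_serial))
    return pairs


def acceptor_serials(topology: Topology) -> list[int]:
    """Serials of all N/O/S heavy atoms (candidate acceptors)."""
    return sorted(
        s for s, a in topology.atoms.items()
        if a.element.upper() in DONOR_ACCEPTOR_ELEMENTS
    )


def detect_hbonds(
    conformation: Conformation,
    topology: Topology | None = None,
    criteria: DetectionCriteria = DetectionCriteria(),
) -> set[HBondID]:
    """Detect all H-bonds present in one conformation.

    A triple (D, H, A) qualifies iff D is an N/O/S atom covalently bonded to
    hydrogen H, A is an N/O/S atom not covalently bonded to H, and the
    geometric criteria hold.
    """
    if topology is None:
        topology = conformation.trajectory.topology
    pairs = donor_hydrogen_pairs(topology)
    if not pairs:
        warnings.warn(
            "conformation has no donor-hydrogen pairs; no H-bonds detectable",
            stacklevel=2,
        )
        return set()
    acceptors = acceptor_serials(topology)
    if not acceptors:
        return set()

    traj = conformation.trajectory
    coords = traj.coords[conformation.tick_index]
    idx = traj.serial_index
    acc_xyz = coords[[idx[s] for s in acceptors]]
    tree = cKDTree(acc_xyz)

    found: set[HBondID] = set()
    for d_serial, h_serial in pairs:
        h_xyz = coords[idx[h_serial]]
        d_xyz = coords[idx[d_serial]]
        for k in tree.query_ball_point(h_xyz, criteria.max_ha):
            a_serial = acceptors[k]
            if a_serial == d_serial or topology.bonded(a_serial, h_serial):
                continue
            a_xyz = acc_xyz[k]
            if np.linalg.norm(d_xyz - a_xyz) > criteria.max_da:
                continue
            v1 = d_xyz - h_xyz
            v2 = a_xyz - h_xyz
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            cos_angle = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
            angle = np.degrees(np.arccos(cos_angle))
            if angle >= criteria.min_angle_dha:
                found.add(HBondID(d_serial, h_serial, a_serial))
    return found


def build_presence_matrix(
    trajectory: Trajectory,
    criteria: DetectionCriteria = DetectionCriteria(),
) -> dict[HBondID, OccurrenceSeries]:
    """Detect H-bonds at every tick and assemble per-bond presence series.

    The key set is the union over ticks of detected bonds; a bond's identity
    persists across ticks where it is absent.
    """
    n = trajectory.n_ticks
    per_tick: list[set[HBondID]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for conf in trajectory.conformations:
            per_tick.append(detect_hbonds(conf, trajectory.topology, criteria))
    bonds = sorted(set().union(*per_tick)) if per_tick else []
    result: dict[HBondID, OccurrenceSeries] = {}
    for bond in bonds:
        presence = np.fromiter(
            (bond in tick_set for tick_set in per_tick), dtype=bool, count=n
        )
        result[bond] = OccurrenceSeries(bond, presence)
    return result


def occurrences_to_csv(series_map: dict[HBondID, OccurrenceSeries], path: str) -> None:
    """Export detected occurrences: one row per (tick, bond) where present."""
    import pandas as pd

    records = []
    for bond, series in sorted(series_map.items()):
        for tick in np.flatnonzero(series.presence):
            records.append(
                (int(tick), bond.donor_serial, bond.hydrogen_serial,
                 bond.acceptor_serial)
            )
    pd.DataFrame(
        records,
        columns=["tick", "donor_serial", "hydrogen_serial", "acceptor_serial"],
    ).to_csv(path, index=False)
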