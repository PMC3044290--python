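"""Multi-model PDB trajectory I/O and covalent topology inference.

A trajectory is an ordered sequence of conformations (one PDB ``MODEL``
per tick, fixed atom set) sampled every ``delta_ps`` picoseconds.
Covalent topology is inferred from interatomic distances on the first
conformation and held fixed for the whole trajectory.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Conformation",
    "Topology",
    "Trajectory",
    "TrajectoryError",
    "infer_topology",
    "read_trajectory",
    "write_trajectory",
    "COVALENT_RADII",
    "MAIN_CHAIN_ATOM_NAMES",
]


class TrajectoryError(ValueError):
    """Raised for malformed trajectory input."""


#: Single-bond covalent radii in Angstrom (Cordero et al. 2008), used for
#: distance-based bond perception.
COVALENT_RADII = {
    "H": 0.31, "D": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
    "P": 1.07, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
    "NA": 1.66, "MG": 1.41, "K": 2.03, "CA": 1.76, "ZN": 1.22, "FE": 1.32,
    "CU": 1.32, "MN": 1.39,
}
_DEFAULT_RADIUS = 0.77
#: Extra slack added to the sum of covalent radii when perceiving bonds.
BOND_TOLERANCE = 0.4

#: Protein backbone atoms (amide hydrogen variants included).
MAIN_CHAIN_ATOM_NAMES = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HN", "HA", "HA2", "HA3"}
)


@dataclass(frozen=True)
class Atom:
    """One atom of the (fixed) atom set of a trajectory."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str

    @property
    def is_main_chain(self) -> bool:
        return self.name in MAIN_CHAIN_ATOM_NAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


class Conformation:
    """View of one tick of a trajectory: a map atom serial -> (x, y, z)."""

    def __init__(self, trajectory: "Trajectory", tick_index: int):
        self.trajectory = trajectory
        self.tick_index = int(tick_index)

    @property
    def coordinates(self) -> dict[int, np.ndarray]:
        coords = self.trajectory.coords[self.tick_index]
        return {a.serial: coords[i] for i, a in enumerate(self.trajectory.atoms)}

    def coord(self, serial: int) -> np.ndarray:
        return self.trajectory.coords[self.tick_index,
                                      self.trajectory.serial_index[serial]]

    @property
    def atoms(self) -> list[Atom]:
        return self.trajectory.atoms

    def __len__(self) -> int:
        return len(self.trajectory.atoms)


class Topology:
    """Covalent-bond adjacency over atom serials.

    Hydrogens bonded to exactly one heavy atom are paired with that atom as
    their donor; ambiguous or isolated hydrogens are excluded from donor
    pairing (with a warning at construction time).
    """

    def __init__(self, atoms: list[Atom], adjacency: dict[int, set[int]]):
        self.atoms = {a.serial: a for a in atoms}
        self.adjacency = {s: frozenset(nb) for s, nb in adjacency.items()}
        self.hydrogen_donor: dict[int, int] = {}
        for atom in atoms:
            if not atom.is_hydrogen:
                continue
            heavy = [s for s in self.adjacency.get(atom.serial, ())
                     if not self.atoms[s].is_hydrogen]
            if len(heavy) == 1:
                self.hydrogen_donor[atom.serial] = heavy[0]
            else:
                warnings.warn(
                    f"hydrogen serial {atom.serial} has {len(heavy)} heavy-atom "
                    "neighbors; excluded from donor pairing",
                    stacklevel=3,
                )

    def neighbors(self, serial: int) -> frozenset[int]:
        return self.adjacency.get(serial, frozenset())

    def bonded(self, a: int, b: int) -> bool:
        return b in self.adjacency.get(a, frozenset())

    def donor_of(self, hydrogen_serial: int) -> int | None:
        return self.hydrogen_donor.get(hydrogen_serial)


@dataclass
class Trajectory:
    """Ordered conformations over a fixed atom set.

    ``coords`` has shape ``(n_ticks, n_atoms, 3)`` in Angstrom; row ``i`` of
    the atom axis corresponds to ``atoms[i]``.
    """

    protein_label: str
    delta_ps: float
    atoms: list[Atom]
    coords: np.ndarray
    topology: Topology | None = None
    serial_index: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (n_ticks, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise TrajectoryError("trajectory must contain at least one conformation")
        if self.coords.shape[1] != len(self.atoms):
            raise TrajectoryError("coords second axis must match atom count")
        if self.delta_ps <= 0:
            raise TrajectoryError("delta_ps must be positive")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise TrajectoryError("atom serials must be unique")
        if not self.serial_index:
            self.serial_index = {s: i for i, s in enumerate(serials)}
        if self.topology is None:
            self.topology = infer_topology(self.conformations[0])

    @property
    def n_ticks(self) -> int:
        return self.coords.shape[0]

    @property
    def conformations(self) -> list[Conformation]:
        return [Conformation(self, i) for i in range(self.n_ticks)]

    def conformation(self, tick_index: int) -> Conformation:
        if not 0 <= tick_index < self.n_ticks:
            raise IndexError(f"tick_index {tick_index} out of range")
        return Conformation(self, tick_index)


def _covalent_radius(element: str) -> float:
    return COVALENT_RADII.get(element.upper(), _DEFAULT_RADIUS)


def infer_topology(conformation: Conformation) -> Topology:
    """Perceive covalent bonds from interatomic distances.

    Two atoms are bonded iff their distance is at most the sum of their
    covalent radii plus a 0.4 A tolerance.
    """
    atoms = conformation.atoms
    coords = conformation.trajectory.coords[conformation.tick_index]
    radii = np.array([_covalent_radius(a.element) for a in atoms])
    adjacency: dict[int, set[int]] = {a.serial: set() for a in atoms}
    if len(atoms) >= 2:
        tree = cKDTree(coords)
        max_cut = 2.0 * radii.max() + BOND_TOLERANCE
        for i, j in tree.query_pairs(max_cut):
            cutoff = radii[i] + radii[j] + BOND_TOLERANCE
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                adjacency[atoms[i].serial].add(atoms[j].serial)
                adjacency[atoms[j].serial].add(atoms[i].serial)
    return Topology(atoms, adjacency)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _structure_to_trajectory(stack, label: str, delta_ps: float) -> Trajectory:
    import biotite.structure as struc

    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    n = stack.array_length()
    if "atom_id" in stack.get_annotation_categories():
        serials = np.asarray(stack.atom_id, dtype=int)
        if len(set(serials.tolist())) != n:
            serials = np.arange(1, n + 1)
    else:
        serials = np.arange(1, n + 1)
    atoms = [
        Atom(
            serial=int(serials[i]),
            name=str(stack.atom_name[i]),
            element=str(stack.element[i]) or str(stack.atom_name[i])[0],
            residue_name=str(stack.res_name[i]),
            residue_number=int(stack.res_id[i]),
            chain_id=str(stack.chain_id[i]),
        )
        for i in range(n)
    ]
    return Trajectory(
        protein_label=label,
        delta_ps=delta_ps,
        atoms=atoms,
        coords=np.asarray(stack.coord, dtype=float),
    )


def _read_multimodel_pdb(path: str, label: str, delta_ps: float) -> Trajectory:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(path)
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise TrajectoryError(f"{path}: no models found")
    try:
        stack = pdb.get_structure(model=None, extra_fields=["atom_id"])
    except Exception:
        _raise_mismatched_model(path)
        raise
    return _structure_to_trajectory(stack, label, delta_ps)


def _raise_mismatched_model(path: str) -> None:
    """Scan raw PDB lines to name the first model with a deviating atom set."""
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                counts.append(0)
                current = len(counts) - 1
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    counts.append(0)
                    current = 0
                counts[current] += 1
    if counts:
        ref = counts[0]
        for k, c in enumerate(counts):
            if c != ref:
                raise TrajectoryError(
                    f"{path}: model {k + 1} has {c} atoms, expected {ref}"
                )
    raise TrajectoryError(f"{path}: models have mismatched atom sets")


_SUFFIX_RE = re.compile(r"(\d+)\.pdb$", re.IGNORECASE)


def read_trajectory(path: str, delta_ps: float, label: str | None = None) -> Trajectory:
    """Read a trajectory from a multi-model PDB file or a directory of
    per-tick single-model PDB files ordered by numeric suffix."""
    if label is None:
        label = os.path.splitext(os.path.basename(os.path.normpath(path)))[0]
    if os.path.isdir(path):
        entries = []
        for fname in os.listdir(path):
            m = _SUFFIX_RE.search(fname)
            if m:
                entries.append((int(m.group(1)), fname))
        if not entries:
            raise TrajectoryError(f"{path}: no numbered .pdb files found")
        entries.sort()
        trajs = [
            _read_multimodel_pdb(os.path.join(path, fname), label, delta_ps)
            for _, fname in entries
        ]
        ref = trajs[0]
        ref_key = [(a.serial, a.name) for a in ref.atoms]
        coords = [ref.coords[0]]
        for k, t in enumerate(trajs[1:], start=2):
            if [(a.serial, a.name) for a in t.atoms] != ref_key:
                raise TrajectoryError(
                    f"{path}: model {k} has a different atom set than model 1"
                )
            coords.append(t.coords[0])
        return Trajectory(
            protein_label=label,
            delta_ps=delta_ps,
            atoms=ref.atoms,
            coords=np.stack(coords),
        )
    return _read_multimodel_pdb(path, label, delta_ps)


def write_trajectory(trajectory: Trajectory, path: str) -> None:
    """Write a trajectory as a multi-model PDB file (one MODEL per tick)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(trajectory.atoms)
    stack = struc.AtomArrayStack(trajectory.n_ticks, n)
    stack.coord = np.asarray(trajectory.coords, dtype=np.float32)
    stack.set_annotation(
        "atom_id", np.array([a.serial for a in trajectory.atoms], dtype=int)
    )
    stack.set_annotation("atom_name", np.array([a.name for a in trajectory.atoms]))
    stack.set_annotation("element", np.array([a.element for a in trajectory.atoms]))
    stack.set_annotation(
        "res_name", np.array([a.residue_name for a in trajectory.atoms])
    )
    stack.set_annotation(
        "res_id", np.array([a.residue_number for a in trajectory.atoms], dtype=int)
    )
    stack.set_annotation(
        "chain_id", np.array([a.chain_id for a in trajectory.atoms])
    )
    stack.set_annotation("hetero", np.zeros(n, dtype=bool))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)
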