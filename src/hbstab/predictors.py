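"""Per-occurrence predictor computation.

Predictors fall into four groups:

* geometric   — distances/angles of the D-H...A(-AA) unit,
* energetic   — a Mayo-form hydrogen-bond potential (``FIRST_energy``),
* environment — counts of nearby bonds around the H-A midpoint,
* static      — chain type, residue identities and sequence separation.

Time-varying numerical predictors are averaged over a trailing window of
``l_prime`` ticks to suppress thermal noise; the window is truncated at the
trajectory start so no future information enters a row's predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hbonds import HBondID
from .trajectory import Conformation, Topology, Trajectory

__all__ = [
    "PredictorSpec",
    "PredictorRegistry",
    "default_registry",
    "MISSING",
    "MISSING_CATEGORY",
    "MayoParameters",
    "mayo_energy",
    "hybridization",
    "compute_geometric",
    "compute_first_energy",
    "compute_environment",
    "compute_static",
    "average_time_varying",
    "trailing_mean",
    "featurize_trajectory",
]

#: Sentinel for a missing numerical value. Splits send it to the left child.
MISSING = float("nan")
#: Token used for a missing categorical value.
MISSING_CATEGORY = "NA"


@dataclass(frozen=True)
class PredictorSpec:
    name: str
    kind: str  # "numerical" | "categorical"
    time_varying: bool

    def __post_init__(self):
        if self.kind not in ("numerical", "categorical"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")


class PredictorRegistry:
    """Ordered collection of predictor specs; order breaks split-score ties."""

    def __init__(self, specs: list[PredictorSpec]):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate predictor names in registry")
        self.specs = list(specs)
        self._by_name = {s.name: s for s in specs}

    def __iter__(self):
        return iter(self.specs)

    def __len__(self):
        return len(self.specs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def spec(self, name: str) -> PredictorSpec:
        return self._by_name[name]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, names: list[str]) -> "PredictorRegistry":
        return PredictorRegistry([self._by_name[n] for n in names])

    def compatible(self, other: "PredictorRegistry") -> bool:
        return [(s.name, s.kind) for s in self.specs] == \
            [(s.name, s.kind) for s in other.specs]

    def to_config(self) -> list[dict]:
        return [
            {"name": s.name, "kind": s.kind, "time_varying": s.time_varying}
            for s in self.specs
        ]

    @classmethod
    def from_config(cls, config: list[dict]) -> "PredictorRegistry":
        return cls([PredictorSpec(d["name"], d["kind"], bool(d["time_varying"]))
                    for d in config])


def default_registry() -> PredictorRegistry:
    """The implemented named predictor set."""
    return PredictorRegistry([
        PredictorSpec("Dist_H_A", "numerical", True),
        PredictorSpec("Dist_D_A", "numerical", True),
        PredictorSpec("Dist_H_D", "numerical", True),
        PredictorSpec("Dist_D_AA", "numerical", True),
        PredictorSpec("Angle_D_H_A", "numerical", True),
        PredictorSpec("Angle_H_A_AA", "numerical", True),
        PredictorSpec("FIRST_energy", "numerical", True),
        PredictorSpec("Num_hb_spaceNbr", "numerical", True),
        PredictorSpec("Num_hb_spaceRgdNbr", "numerical", True),
        PredictorSpec("Ch_type", "categorical", False),
        PredictorSpec("Resi_name_H", "categorical", False),
        PredictorSpec("Resi_name_A", "categorical", False),
        PredictorSpec("Range", "numerical", False),
    ])


# ---------------------------------------------------------------------------
# Hybridization lookup
# ---------------------------------------------------------------------------

# (residue, atom name) -> hybridization; residue "*" matches any residue.
_HYBRIDIZATION_TABLE = {
    ("*", "N"): "sp2",      # backbone amide
    ("*", "O"): "sp2",      # backbone carbonyl
    ("*", "OXT"): "sp2",
    ("SER", "OG"): "sp3",
    ("THR", "OG1"): "sp3",
    ("TYR", "OH"): "sp2",
    ("ASP", "OD1"): "sp2", ("ASP", "OD2"): "sp2",
    ("GLU", "OE1"): "sp2", ("GLU", "OE2"): "sp2",
    ("ASN", "OD1"): "sp2", ("ASN", "ND2"): "sp2",
    ("GLN", "OE1"): "sp2", ("GLN", "NE2"): "sp2",
    ("HIS", "ND1"): "sp2", ("HIS", "NE2"): "sp2",
    ("LYS", "NZ"): "sp3",
    ("ARG", "NE"): "sp2", ("ARG", "NH1"): "sp2", ("ARG", "NH2"): "sp2",
    ("TRP", "NE1"): "sp2",
    ("CYS", "SG"): "sp3",
    ("MET", "SD"): "sp3",
    ("HOH", "O"): "sp3",
}


def hybridization(atom) -> str:
    """sp2/sp3 assignment by residue and atom name; unknown atoms default to
    sp3 with a warning."""
    key = (atom.residue_name.upper(), atom.name.upper())
    if key in _HYBRIDIZATION_TABLE:
        return _HYBRIDIZATION_TABLE[key]
    generic = ("*", atom.name.upper())
    if generic in _HYBRIDIZATION_TABLE:
        return _HYBRIDIZATION_TABLE[generic]
    warnings.warn(
        f"unknown hybridization for {atom.residue_name}:{atom.name}; "
        "defaulting to sp3",
        stacklevel=2,
    )
    return "sp3"


# ---------------------------------------------------------------------------
# Mayo-form hydrogen-bond potential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MayoParameters:
    """Constants of the Mayo-form potential.

    ``phi_lower_deg`` is the in-plane floor applied to phi in the sp2-sp2
    angular factor.
    """

    well_depth: float = 8.0      # kcal/mol
    r0: float = 2.8              # Angstrom
    sp3_phi0_deg: float = 109.5
    phi_lower_deg: float = 150.0


def mayo_energy(
    r_da,
    theta_deg,
    phi_deg,
    donor_hyb="sp3",
    acceptor_hyb="sp3",
    params: MayoParameters = MayoParameters(),
):
    """Mayo-form H-bond energy in kcal/mol (vectorized, clamped to <= 0).

    ``E = V0 * (5 (R0/R)^12 - 6 (R0/R)^10) * F(theta, phi)`` with R the
    donor-acceptor distance, theta the D-H-A angle and phi the H-A-AA angle.
    The angular factor F follows the four donor/acceptor hybridization cases;
    F = 0 for theta < 90 degrees. A missing phi (NaN) leaves the phi-factor
    at its maximum.
    """
    r = np.asarray(r_da, dtype=float)
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    donor_sp3 = np.asarray(donor_hyb) == "sp3"
    acceptor_sp3 = np.asarray(acceptor_hyb) == "sp3"

    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ratio2 = (params.r0 / r) ** 2
        radial = params.well_depth * (5.0 * ratio2**6 - 6.0 * ratio2**5)

        cos_t = np.cos(theta)
        decay = np.exp(-((np.pi - theta) ** 6))
        phi_factor_sp3 = np.where(
            np.isnan(phi), 1.0,
            np.cos(phi - np.radians(params.sp3_phi0_deg)) ** 2,
        )
        phi_factor_sp2 = np.where(np.isnan(phi), 1.0, np.cos(phi) ** 2)
        phi_clamped = np.where(
            np.isnan(phi), np.pi,
            np.maximum(phi, np.radians(params.phi_lower_deg)),
        )
        phi_factor_sp2sp2 = np.cos(phi_clamped) ** 2

        f_sp3_sp3 = cos_t**2 * decay * phi_factor_sp3
        f_sp3_sp2 = cos_t**2 * decay * phi_factor_sp2
        f_sp2_sp3 = cos_t**4 * np.exp(-2.0 * (np.pi - theta) ** 6)
        f_sp2_sp2 = cos_t**2 * decay * phi_factor_sp2sp2

        angular = np.where(
            donor_sp3,
            np.where(acceptor_sp3, f_sp3_sp3, f_sp3_sp2),
            np.where(acceptor_sp3, f_sp2_sp3, f_sp2_sp2),
        )
        angular = np.where(theta < np.pi / 2.0, 0.0, angular)
        energy = np.minimum(radial * angular, 0.0)
        energy = np.where(np.isnan(r) | np.isnan(theta), np.nan, energy)
    if np.isscalar(r_da) or np.ndim(r_da) == 0:
        return float(energy)
    return energy


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        warnings.warn("degenerate zero-length vector in angle computation",
                      stacklevel=3)
        return MISSING
    cos = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def acceptor_antecedent(
    bond: HBondID, conformation: Conformation, topology: Topology
) -> int | None:
    """Covalent neighbor of the acceptor (excluding the bond's hydrogen);
    if several, the one nearest the hydrogen in this conformation."""
    neighbors = [s for s in topology.neighbors(bond.acceptor_serial)
                 if s != bond.hydrogen_serial]
    if not neighbors:
        return None
    if len(neighbors) == 1:
        return neighbors[0]
    h = conformation.coord(bond.hydrogen_serial)
    return min(neighbors,
               key=lambda s: float(np.linalg.norm(conformation.coord(s) - h)))


def compute_geometric(
    bond: HBondID, conformation: Conformation, topology: Topology | None = None
) -> dict[str, float]:
    """Distances and angles of the bonded unit for one occurrence."""
    if topology is None:
        topology = conformation.trajectory.topology
    d = conformation.coord(bond.donor_serial)
    h = conformation.coord(bond.hydrogen_serial)
    a = conformation.coord(bond.acceptor_serial)
    out = {
        "Dist_H_A": float(np.linalg.norm(a - h)),
        "Dist_D_A": float(np.linalg.norm(a - d)),
        "Dist_H_D": float(np.linalg.norm(h - d)),
        "Angle_D_H_A": _angle_deg(d - h, a - h),
    }
    aa_serial = acceptor_antecedent(bond, conformation, topology)
    if aa_serial is None:
        out["Dist_D_AA"] = MISSING
        out["Angle_H_A_AA"] = MISSING
    else:
        aa = conformation.coord(aa_serial)
        out["Dist_D_AA"] = float(np.linalg.norm(aa - d))
        out["Angle_H_A_AA"] = _angle_deg(h - a, aa - a)
    return out


def compute_first_energy(
    bond: HBondID,
    conformation: Conformation,
    topology: Topology | None = None,
    params: MayoParameters = MayoParameters(),
) -> float:
    """Mayo-form energy of one occurrence, using table hybridizations."""
    if topology is None:
        topology = conformation.trajectory.topology
    geom = compute_geometric(bond, conformation, topology)
    donor = topology.atoms[bond.donor_serial]
    acceptor = topology.atoms[bond.acceptor_serial]
    return mayo_energy(
        geom["Dist_D_A"], geom["Angle_D_H_A"], geom["Angle_H_A_AA"],
        hybridization(donor), hybridization(acceptor), params,
    )


#: Energy threshold (kcal/mol) below which a neighbor bond counts as rigid.
RIGID_ENERGY_CUTOFF = -1.0


def compute_environment(
    bond: HBondID,
    bonds_at_tick: list[HBondID],
    conformation: Conformation,
    topology: Topology | None = None,
    radius: float = 5.0,
    params: MayoParameters = MayoParameters(),
) -> dict[str, float]:
    """Neighbor-bond counts around this bond's H-A midpoint.

    ``Num_hb_spaceRgdNbr`` approximates rigid-cluster membership by an
    energy filter (bonds with energy <= -1 kcal/mol).
    """
    if topology is None:
        topology = conformation.trajectory.topology

    def midpoint(b: HBondID) -> np.ndarray:
        return 0.5 * (conformation.coord(b.hydrogen_serial)
                      + conformation.coord(b.acceptor_serial))

    center = midpoint(bond)
    n_all = 0
    n_rigid = 0
    for other in bonds_at_tick:
        if other == bond:
            continue
        if np.linalg.norm(midpoint(other) - center) <= radius:
            n_all += 1
            if compute_first_energy(other, conformation, topology,
                                    params) <= RIGID_ENERGY_CUTOFF:
                n_rigid += 1
    return {"Num_hb_spaceNbr": float(n_all), "Num_hb_spaceRgdNbr": float(n_rigid)}


def compute_static(bond: HBondID, topology: Topology) -> dict[str, object]:
    """Chain type, residue identities and sequence separation of a bond."""
    donor = topology.atoms[bond.donor_serial]
    acceptor = topology.atoms[bond.acceptor_serial]
    ch_type = ("M" if donor.is_main_chain else "S") + \
        ("M" if acceptor.is_main_chain else "S")
    rng = abs(acceptor.residue_number - donor.residue_number)
    if donor.chain_id != acceptor.chain_id:
        rng += 1000  # separate inter-chain bonds while staying numeric
    return {
        "Ch_type": ch_type,
        "Resi_name_H": donor.residue_name,
        "Resi_name_A": acceptor.residue_name,
        "Range": float(rng),
    }


# ---------------------------------------------------------------------------
# Trailing-window averaging
# ---------------------------------------------------------------------------

def trailing_mean(values: np.ndarray, window: int) -> np.ndarray:
    """NaN-aware trailing mean along axis 0: the value at tick ``i`` is the
    mean over the last ``min(i + 1, window)`` ticks ending at ``i``."""
    a = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return a.copy()
    finite = np.isfinite(a)
    filled = np.where(finite, a, 0.0)
    csum = np.cumsum(filled, axis=0)
    ccount = np.cumsum(finite.astype(float), axis=0)
    sums = csum.copy()
    counts = ccount.copy()
    if a.shape[0] > window:
        sums[window:] = csum[window:] - csum[:-window]
        counts[window:] = ccount[window:] - ccount[:-window]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def average_time_varying(
    series: dict[str, np.ndarray],
    i: int,
    l_prime: int,
    registry: PredictorRegistry,
) -> dict[str, float]:
    """Averaged predictor values at tick ``i`` from per-tick value streams.

    Time-varying numerical predictors are averaged over the trailing window;
    categorical and time-invariant predictors pass through unchanged.
    """
    out: dict[str, float] = {}
    for name, values in series.items():
        spec = registry.spec(name) if name in registry else None
        if spec is not None and spec.time_varying and spec.kind == "numerical":
            arr = np.asarray(values, dtype=float)
            start = max(0, i - l_prime + 1)
            window = arr[start:i + 1]
            finite = window[np.isfinite(window)]
            out[name] = float(finite.mean()) if finite.size else MISSING
        elif np.ndim(values) == 0:
            out[name] = values
        else:
            out[name] = values[i]
    return out


# ---------------------------------------------------------------------------
# Vectorized trajectory featurization
# ---------------------------------------------------------------------------

def _norm(v: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("...k,...k->...", v, v))


def _angles_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    n1 = _norm(v1)
    n2 = _norm(v2)
    denom = n1 * n2
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.einsum("...k,...k->...", v1, v2) / denom
    cos = np.clip(cos, -1.0, 1.0)
    out = np.degrees(np.arccos(cos))
    out[denom == 0] = np.nan
    return out


def featurize_trajectory(
    trajectory: Trajectory,
    bonds: list[HBondID],
    presence: np.ndarray,
    registry: PredictorRegistry | None = None,
    env_radius: float = 5.0,
    mayo_params: MayoParameters = MayoParameters(),
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Compute raw (unaveraged) predictor values for every (tick, bond).

    Geometric/energetic values are computed at every tick regardless of bond
    presence (so averaging windows are complete); environment counts at a
    tick count only bonds *present* at that tick (``presence`` has shape
    ``(n_ticks, n_bonds)``).

    Returns ``(time_varying, static)`` where time-varying entries have shape
    ``(n_ticks, n_bonds)`` and static entries shape ``(n_bonds,)``.
    """
    if registry is None:
        registry = default_registry()
    topology = trajectory.topology
    coords = trajectory.coords
    idx = trajectory.serial_index
    T = trajectory.n_ticks
    B = len(bonds)
    presence = np.asarray(presence, dtype=bool)
    if presence.shape != (T, B):
        raise ValueError("presence must have shape (n_ticks, n_bonds)")

    d_idx = np.array([idx[b.donor_serial] for b in bonds], dtype=int)
    h_idx = np.array([idx[b.hydrogen_serial] for b in bonds], dtype=int)
    a_idx = np.array([idx[b.acceptor_serial] for b in bonds], dtype=int)

    D = coords[:, d_idx]  # (T, B, 3)
    H = coords[:, h_idx]
    A = coords[:, a_idx]

    tv: dict[str, np.ndarray] = {}
    tv["Dist_H_A"] = _norm(A - H)
    tv["Dist_D_A"] = _norm(A - D)
    tv["Dist_H_D"] = _norm(H - D)
    tv["Angle_D_H_A"] = _angles_deg(D - H, A - H)

    # Acceptor antecedent: unique neighbor resolved statically, ambiguous
    # ones per tick by distance to the hydrogen.
    aa_neighbors = [
        [s for s in topology.neighbors(b.acceptor_serial)
         if s != b.hydrogen_serial]
        for b in bonds
    ]
    AA = np.full((T, B, 3), np.nan)
    has_aa = np.zeros(B, dtype=bool)
    for k, nbrs in enumerate(aa_neighbors):
        if not nbrs:
            continue
        has_aa[k] = True
        if len(nbrs) == 1:
            AA[:, k] = coords[:, idx[nbrs[0]]]
        else:
            cand = coords[:, [idx[s] for s in nbrs]]        # (T, m, 3)
            dist_h = _norm(cand - H[:, k][:, None, :])       # (T, m)
            choice = np.argmin(dist_h, axis=1)
            AA[:, k] = cand[np.arange(T), choice]
    tv["Dist_D_AA"] = _norm(AA - D)
    tv["Angle_H_A_AA"] = _angles_deg(H - A, AA - A)

    donor_hyb = np.array(
        [hybridization(topology.atoms[b.donor_serial]) for b in bonds]
    )
    acc_hyb = np.array(
        [hybridization(topology.atoms[b.acceptor_serial]) for b in bonds]
    )
    tv["FIRST_energy"] = mayo_energy(
        tv["Dist_D_A"], tv["Angle_D_H_A"], tv["Angle_H_A_AA"],
        donor_hyb[None, :], acc_hyb[None, :], mayo_params,
    )

    if "Num_hb_spaceNbr" in registry or "Num_hb_spaceRgdNbr" in registry:
        mid = 0.5 * (H + A)                                   # (T, B, 3)
        rigid = tv["FIRST_energy"] <= RIGID_ENERGY_CUTOFF
        n_nbr = np.zeros((T, B))
        n_rgd = np.zeros((T, B))
        # All-pairs per tick; B is small in practice (per-protein bonds).
        chunk = max(1, int(2e6 // max(B * B, 1)))
        for t0 in range(0, T, chunk):
            t1 = min(T, t0 + chunk)
            diff = mid[t0:t1, :, None, :] - mid[t0:t1, None, :, :]
            within = _norm(diff) <= env_radius
            within &= ~np.eye(B, dtype=bool)[None]
            pres = presence[t0:t1]
            n_nbr[t0:t1] = (within & pres[:, None, :]).sum(axis=2)
            n_rgd[t0:t1] = (
                within & (pres & rigid[t0:t1])[:, None, :]
            ).sum(axis=2)
        tv["Num_hb_spaceNbr"] = n_nbr
        tv["Num_hb_spaceRgdNbr"] = n_rgd

    static: dict[str, np.ndarray] = {
        "Ch_type": np.empty(B, dtype=object),
        "Resi_name_H": np.empty(B, dtype=object),
        "Resi_name_A": np.empty(B, dtype=object),
        "Range": np.zeros(B),
    }
    for k, b in enumerate(bonds):
        vals = compute_static(b, topology)
        for name in ("Ch_type", "Resi_name_H", "Resi_name_A", "Range"):
            static[name][k] = vals[name]

    tv = {name: arr for name, arr in tv.items() if name in registry}
    static = {name: arr for name, arr in static.items() if name in registry}
    return tv, static
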