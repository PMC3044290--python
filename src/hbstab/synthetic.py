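"""Synthetic trajectories and data tables with known ground truth.

``generate_trajectory`` builds isolated donor-hydrogen-acceptor-antecedent
clusters whose H...A distance follows a first-order autoregressive process
around a per-bond equilibrium, so per-bond presence/absence series with a
known stability structure emerge from the geometric detection criteria.
``generate_table`` draws tabular rows from an explicit threshold rule for
tree-recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import KEY_COLUMNS, DataTable
from .hbonds import DetectionCriteria, HBondID
from .predictors import PredictorRegistry, PredictorSpec
from .trajectory import Atom, Trajectory

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticTrajectory",
    "generate_trajectory",
    "randomized_config",
    "ThresholdRule",
    "CategoryRule",
    "SyntheticTableConfig",
    "generate_table",
]

_DH_BOND_LENGTH = 1.0      # donor-hydrogen distance, Angstrom
_AA_BOND_LENGTH = 1.23     # acceptor-antecedent distance
_MIN_HA_DISTANCE = 1.45    # floor keeping H and A non-covalent


@dataclass
class SyntheticConfig:
    """Generator settings; per-bond parameters accept scalars or arrays."""

    n_bonds: int = 10
    n_ticks: int = 400
    seed: int = 0
    mu: np.ndarray | float | None = None       # equilibrium H..A distance
    s: np.ndarray | float = 0.12               # stationary fluctuation sd
    rho: float = 0.8                           # AR(1) autocorrelation
    angle_noise_deg: np.ndarray | float = 8.0  # theta jitter sd, per bond
    theta0_deg: np.ndarray | float = 180.0     # D-H-A equilibrium angle
    dh_length: np.ndarray | float = _DH_BOND_LENGTH  # donor-hydrogen length
    phi_deg: np.ndarray | float = 120.0        # H-A-AA equilibrium angle
    mu_off: float = 3.2                        # equilibrium while gate is off
    secondary_driver: bool = False
    weak_fraction: float = 0.5
    gate_on_prob: float = 0.6
    gate_dwell_ticks: float = 150.0
    #: with the secondary driver, redraw weak-class equilibria from this
    #: range so the gate (not current geometry) dominates their stability
    weak_mu_range: tuple[float, float] | None = None
    cluster_spacing: float = 35.0
    crowded: bool = False
    delta_ps: float = 1.0
    label: str = "synthetic"
    l: int | None = None
    l_prime: int | None = None
    cutoff_ref: float = 2.5

    def resolved_mu(self) -> np.ndarray:
        if self.mu is None:
            return np.linspace(1.8, 3.2, self.n_bonds)
        return np.broadcast_to(np.asarray(self.mu, dtype=float),
                               (self.n_bonds,)).copy()

    def validate(self) -> None:
        if self.n_bonds < 1 or self.n_ticks < 1:
            raise ValueError("need n_bonds >= 1 and n_ticks >= 1")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.l is not None and self.l_prime is not None and \
                self.n_ticks <= self.l + self.l_prime:
            raise ValueError("n_ticks must exceed l + l_prime")
        mu = self.resolved_mu()
        if self.n_bonds >= 2 and not (mu.min() < self.cutoff_ref < mu.max()):
            warnings.warn(
                "per-bond equilibria do not span the detection cutoff; "
                "tables will lack stability contrast",
                stacklevel=3,
            )


@dataclass
class GroundTruth:
    """Exact per-tick geometry and presence emitted by the generator."""

    bonds: list[HBondID]
    presence: np.ndarray       # (n_ticks, n_bonds) bool
    dist_ha: np.ndarray        # (n_ticks, n_bonds)
    dist_da: np.ndarray
    theta_deg: np.ndarray
    phi_deg: np.ndarray
    weak_class: np.ndarray     # (n_bonds,) bool

    def true_y(self, l: int) -> np.ndarray:
        """Exact labels y[i, k] for ticks i <= n_ticks - 1 - l (NaN beyond)."""
        T, B = self.presence.shape
        csum = np.cumsum(self.presence.astype(np.int64), axis=0)
        out = np.full((T, B), np.nan)
        max_i = T - 1 - l
        if max_i >= 0:
            i = np.arange(max_i + 1)
            out[:max_i + 1] = (csum[i + l] - csum[i]) / float(l)
        return out

    def to_csv(self, path: str) -> None:
        T, B = self.presence.shape
        frames = []
        for k, b in enumerate(self.bonds):
            frames.append(pd.DataFrame({
                "tick": np.arange(T),
                "donor_serial": b.donor_serial,
                "hydrogen_serial": b.hydrogen_serial,
                "acceptor_serial": b.acceptor_serial,
                "presence": self.presence[:, k].astype(int),
                "dist_ha": self.dist_ha[:, k],
                "dist_da": self.dist_da[:, k],
                "theta_deg": self.theta_deg[:, k],
                "phi_deg": self.phi_deg[:, k],
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


@dataclass
class SyntheticTrajectory:
    trajectory: Trajectory
    ground_truth: GroundTruth
    config: SyntheticConfig


_RESNAME_CYCLE = ["ALA", "SER", "VAL", "LEU"]
_STRONG_RESNAME = "ALA"
_WEAK_RESNAME = "GLY"


def generate_trajectory(
    config: SyntheticConfig,
    criteria: DetectionCriteria = DetectionCriteria(),
) -> SyntheticTrajectory:
    """Generate a trajectory of isolated H-bond clusters with exact ground
    truth.

    Per bond k the H..A distance is AR(1) around ``mu[k]`` with stationary
    sd ``s[k]``; the D-H-A angle jitters around linearity. With
    ``secondary_driver`` half the bonds form a "weak" class (distinct
    residue name and H-A-AA angle regime) whose equilibrium is displaced to
    ``mu_off`` whenever a slow two-state gate is off, so stability depends
    on more than current geometry.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    B = config.n_bonds
    T = config.n_ticks
    mu = config.resolved_mu()
    s = np.broadcast_to(np.asarray(config.s, dtype=float), (B,)).copy()
    noise = np.broadcast_to(
        np.asarray(config.angle_noise_deg, dtype=float), (B,)).copy()
    phi0 = np.broadcast_to(
        np.asarray(config.phi_deg, dtype=float), (B,)).copy()

    weak = np.zeros(B, dtype=bool)
    if config.secondary_driver:
        n_weak = int(round(config.weak_fraction * B))
        weak[rng.permutation(B)[:n_weak]] = True
        phi0 = np.where(weak, 100.0, 130.0)
        if config.weak_mu_range is not None:
            lo, hi = config.weak_mu_range
            mu = np.where(weak, rng.uniform(lo, hi, B), mu)

    # slow on/off gate (weak bonds only; strong bonds always on)
    gate = np.ones((T, B), dtype=bool)
    if config.secondary_driver and weak.any():
        p_on = config.gate_on_prob
        dwell_on = max(config.gate_dwell_ticks * p_on, 1.0)
        dwell_off = max(config.gate_dwell_ticks * (1.0 - p_on), 1.0)
        for k in np.flatnonzero(weak):
            state = rng.random() < p_on
            u = rng.random(T)
            g = np.empty(T, dtype=bool)
            for t in range(T):
                g[t] = state
                flip = u[t] < (1.0 / dwell_on if state else 1.0 / dwell_off)
                if flip:
                    state = not state
            gate[:, k] = g

    # AR(1) deviation around the (gate-dependent) equilibrium
    innov = rng.standard_normal((T, B))
    dev = np.empty((T, B))
    dev[0] = s * innov[0]
    scale = np.sqrt(1.0 - config.rho**2) * s
    for t in range(1, T):
        dev[t] = config.rho * dev[t - 1] + scale * innov[t]
    mu_eff = np.where(gate, mu[None, :], config.mu_off)
    dist_ha = np.maximum(mu_eff + dev, _MIN_HA_DISTANCE)

    theta0 = np.broadcast_to(
        np.asarray(config.theta0_deg, dtype=float), (B,)).copy()
    theta = np.clip(theta0 - np.abs(rng.standard_normal((T, B)) * noise),
                    91.0, 180.0)
    phi = np.clip(phi0 + rng.standard_normal((T, B)) * noise, 95.0, 175.0)

    # assemble coordinates: D at the cluster origin, H along +x, A in the
    # xy-plane at angle (180 - theta) from +x, AA at angle phi from A->H
    beta = np.radians(180.0 - theta)
    ux, uy = np.cos(beta), np.sin(beta)
    hx = np.broadcast_to(
        np.asarray(config.dh_length, dtype=float), (B,)).copy()
    ax = hx + dist_ha * ux
    ay = dist_ha * uy
    dist_da = np.sqrt(ax**2 + ay**2)

    # A->H unit vector, rotated by phi to place the antecedent
    vx, vy = (hx - ax) / dist_ha, -ay / dist_ha
    cphi = np.cos(np.radians(phi))
    sphi = np.sin(np.radians(phi))
    wx = cphi * vx - sphi * vy
    wy = sphi * vx + cphi * vy
    aax = ax + _AA_BOND_LENGTH * wx
    aay = ay + _AA_BOND_LENGTH * wy

    spacing = 6.0 if config.crowded else config.cluster_spacing
    atoms: list[Atom] = []
    bonds: list[HBondID] = []
    coords = np.zeros((T, 4 * B, 3))
    for k in range(B):
        base = 4 * k
        serial = base + 1
        if config.secondary_driver:
            resname_d = _WEAK_RESNAME if weak[k] else _STRONG_RESNAME
        else:
            resname_d = _RESNAME_CYCLE[k % len(_RESNAME_CYCLE)]
        resname_a = _RESNAME_CYCLE[(k + 2) % len(_RESNAME_CYCLE)]
        res_d = 2 * k + 1
        res_a = res_d + 1 + (3 * k) % 7   # varying sequence separation
        atoms.extend([
            Atom(serial, "N", "N", resname_d, res_d, "A"),
            Atom(serial + 1, "H", "H", resname_d, res_d, "A"),
            Atom(serial + 2, "O", "O", resname_a, res_a, "A"),
            Atom(serial + 3, "C", "C", resname_a, res_a, "A"),
        ])
        bonds.append(HBondID(serial, serial + 1, serial + 2))
        offset = k * spacing
        coords[:, base, 0] = offset
        coords[:, base + 1, 0] = offset + hx[k]
        coords[:, base + 2, 0] = offset + ax[:, k]
        coords[:, base + 2, 1] = ay[:, k]
        coords[:, base + 3, 0] = offset + aax[:, k]
        coords[:, base + 3, 1] = aay[:, k]

    trajectory = Trajectory(
        protein_label=config.label,
        delta_ps=config.delta_ps,
        atoms=atoms,
        coords=coords,
    )
    presence = (
        (dist_ha <= criteria.max_ha)
        & (dist_da <= criteria.max_da)
        & (theta >= criteria.min_angle_dha)
    )
    truth = GroundTruth(
        bonds=bonds, presence=presence, dist_ha=dist_ha, dist_da=dist_da,
        theta_deg=theta, phi_deg=phi, weak_class=weak,
    )
    return SyntheticTrajectory(trajectory, truth, config)


def randomized_config(
    seed: int,
    n_bonds: int = 24,
    n_ticks: int = 800,
    secondary_driver: bool = False,
    label: str = "synthetic",
    mu_range: tuple[float, float] = (2.2, 2.8),
    l: int = 50,
    l_prime: int = 50,
) -> SyntheticConfig:
    """A config with per-bond parameter diversity (equilibria near the
    detection cutoff, varied donor-hydrogen lengths and angle regimes) so
    that the hydrogen-acceptor distance is the identifiable stability
    driver rather than any of its correlated transforms."""
    rng = np.random.default_rng(seed)
    return SyntheticConfig(
        n_bonds=n_bonds,
        n_ticks=n_ticks,
        seed=seed,
        mu=rng.uniform(*mu_range, n_bonds),
        dh_length=rng.uniform(0.7, 1.1, n_bonds),
        s=0.12,
        rho=0.8,
        theta0_deg=rng.uniform(150.0, 178.0, n_bonds),
        phi_deg=rng.uniform(95.0, 145.0, n_bonds),
        angle_noise_deg=rng.uniform(4.0, 12.0, n_bonds),
        secondary_driver=secondary_driver,
        weak_mu_range=(1.9, 2.4) if secondary_driver else None,
        gate_on_prob=0.55,
        gate_dwell_ticks=120.0,
        label=label,
        l=l,
        l_prime=l_prime,
    )


# ---------------------------------------------------------------------------
# Tabular generator with an explicit ground-truth rule
# ---------------------------------------------------------------------------

@dataclass
class ThresholdRule:
    """value < threshold -> ``low`` branch, else ``high``; branches are
    nested rules or leaf means."""

    predictor: str
    threshold: float
    low: "ThresholdRule | CategoryRule | float"
    high: "ThresholdRule | CategoryRule | float"

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        mask = df[self.predictor].to_numpy(dtype=float) < self.threshold
        return _eval_branches(self, df, mask)


@dataclass
class CategoryRule:
    """value in subset -> ``low`` branch, else ``high``."""

    predictor: str
    subset: frozenset
    low: "ThresholdRule | CategoryRule | float"
    high: "ThresholdRule | CategoryRule | float"

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        mask = df[self.predictor].isin(self.subset).to_numpy()
        return _eval_branches(self, df, mask)


def _eval_branches(rule, df, mask: np.ndarray) -> np.ndarray:
    out = np.empty(len(df))
    for branch, sel in ((rule.low, mask), (rule.high, ~mask)):
        if isinstance(branch, (int, float)):
            out[sel] = float(branch)
        elif sel.any():
            out[sel] = branch.evaluate(df.loc[sel])
    return out


def rule_predictors(rule) -> set[str]:
    names = set()
    stack = [rule]
    while stack:
        node = stack.pop()
        if isinstance(node, (ThresholdRule, CategoryRule)):
            names.add(node.predictor)
            stack.extend([node.low, node.high])
    return names


@dataclass
class SyntheticTableConfig:
    """Distributions for i.i.d. tabular rows.

    ``predictors`` maps a name to ``("uniform", low, high)`` or
    ``("choice", [tokens...])``.
    """

    n_rows: int = 1000
    seed: int = 0
    predictors: dict = field(default_factory=lambda: {
        "Dist_H_A": ("uniform", 1.5, 3.5),
        "Angle_H_A_AA": ("uniform", 90.0, 180.0),
    })
    noise_sd: float = 0.0
    l: int = 50
    n_bonds: int = 20
    label: str = "synthetic_table"


def generate_table(
    config: SyntheticTableConfig,
    tree_truth: "ThresholdRule | CategoryRule | float",
) -> DataTable:
    """Draw i.i.d. rows from the configured predictor distributions and
    label them by the ground-truth rule plus clipped, 1/l-quantized noise."""
    rng = np.random.default_rng(config.seed)
    n = config.n_rows
    data: dict[str, np.ndarray] = {}
    specs: list[PredictorSpec] = []
    for name, dist in config.predictors.items():
        if dist[0] == "uniform":
            data[name] = rng.uniform(dist[1], dist[2], size=n)
            specs.append(PredictorSpec(name, "numerical", True))
        elif dist[0] == "choice":
            data[name] = rng.choice(np.asarray(dist[1], dtype=object), size=n)
            specs.append(PredictorSpec(name, "categorical", False))
        else:
            raise ValueError(f"unknown distribution {dist[0]!r}")
    registry = PredictorRegistry(specs)
    df = pd.DataFrame(data)
    if isinstance(tree_truth, (int, float)):
        y = np.full(n, float(tree_truth))
    else:
        missing = rule_predictors(tree_truth) - set(df.columns)
        if missing:
            raise ValueError(f"rule uses unconfigured predictors: {missing}")
        y = tree_truth.evaluate(df)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=n)
    y = np.clip(y, 0.0, 1.0)
    y = np.round(y * config.l) / config.l
    df["y"] = y
    df["protein_label"] = config.label
    df["tick"] = np.arange(n)
    bond_ids = np.arange(n) % config.n_bonds
    df["donor_serial"] = 3 * bond_ids + 1
    df["hydrogen_serial"] = 3 * bond_ids + 2
    df["acceptor_serial"] = 3 * bond_ids + 3
    table = DataTable(df[KEY_COLUMNS + registry.names + ["y"]], registry,
                      config.l, 1, 1.0)
    table.metadata["ground_truth_rule"] = repr(tree_truth)
    return table
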