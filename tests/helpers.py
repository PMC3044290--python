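"""Independent oracles and small builders shared across the test suite.

Oracles here deliberately use naive enumeration / direct formulas so they
stay independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from hbstab.dataset import KEY_COLUMNS, DataTable
from hbstab.predictors import PredictorRegistry, PredictorSpec
from hbstab.trajectory import Atom, Trajectory


def oracle_split_score(y, mask) -> float:
    """Direct SSE-reduction formula: (SSE_total - SSE_L - SSE_R) / n."""
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask, dtype=bool)

    def sse(v):
        return float(((v - v.mean()) ** 2).sum()) if v.size else 0.0

    return (sse(y) - sse(y[mask]) - sse(y[~mask])) / y.size


def oracle_best_score(df: pd.DataFrame, y, registry: PredictorRegistry) -> float:
    """Exhaustive enumeration over all thresholds and all categorical
    bipartitions; returns the maximal achievable score (0 if none)."""
    y = np.asarray(y, dtype=float)
    best = 0.0
    for spec in registry:
        col = df[spec.name].to_numpy()
        if spec.kind == "numerical":
            vals = np.asarray(col, dtype=float)
            nan = np.isnan(vals)
            # candidate thresholds: midpoints between consecutive distinct
            # values (missing entries lie left of every threshold)
            finite = np.unique(vals[~nan])
            for lo, hi in zip(finite[:-1], finite[1:]):
                t = 0.5 * (lo + hi)
                mask = nan | (vals < t)
                if mask.any() and not mask.all():
                    best = max(best, oracle_split_score(y, mask))
        else:
            cats = sorted(set(map(str, col)))
            tokens = np.asarray(col, dtype=str)
            for r in range(1, len(cats)):
                for subset in itertools.combinations(cats, r):
                    mask = np.isin(tokens, subset)
                    if mask.any() and not mask.all():
                        best = max(best, oracle_split_score(y, mask))
    return best


def oracle_neighbor_counts(midpoints: np.ndarray, radius: float) -> np.ndarray:
    """O(n^2) all-pairs neighbor count."""
    n = len(midpoints)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and np.linalg.norm(midpoints[i] - midpoints[j]) <= radius:
                counts[i] += 1
    return counts


def oracle_angle_deg(a, b, c) -> float:
    """Angle at vertex b, by normalized dot product."""
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cos, -1, 1))))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def table_from_arrays(
    predictors: dict[str, np.ndarray],
    y,
    kinds: dict[str, str] | None = None,
    l: int = 50,
    n_bonds: int | None = None,
) -> DataTable:
    """Assemble a DataTable from raw predictor columns and labels."""
    y = np.asarray(y, dtype=float)
    n = y.size
    kinds = kinds or {}
    specs = []
    data = {}
    for name, col in predictors.items():
        col = np.asarray(col)
        kind = kinds.get(
            name, "categorical" if col.dtype.kind in "OSU" else "numerical"
        )
        specs.append(PredictorSpec(name, kind, kind == "numerical"))
        data[name] = col
    registry = PredictorRegistry(specs)
    if n_bonds is None:
        n_bonds = max(2, n // 10)
    bond = np.arange(n) % n_bonds
    df = pd.DataFrame({
        "protein_label": "test",
        "tick": np.arange(n),
        "donor_serial": 3 * bond + 1,
        "hydrogen_serial": 3 * bond + 2,
        "acceptor_serial": 3 * bond + 3,
        **data,
        "y": y,
    })
    return DataTable(df[KEY_COLUMNS + registry.names + ["y"]], registry, l, 1, 1.0)


def random_table(rng: np.random.Generator, n_rows: int = 120,
                 n_numeric: int = 2, n_categorical: int = 2) -> DataTable:
    """A random mixed-type table for split-search oracle checks."""
    predictors = {}
    for j in range(n_numeric):
        vals = rng.normal(size=n_rows)
        if j == 0 and n_rows > 4:
            # duplicated values and a few missing entries
            vals = np.round(vals, 1)
            vals[rng.choice(n_rows, size=max(1, n_rows // 20), replace=False)] = np.nan
        predictors[f"x{j}"] = vals
    for j in range(n_categorical):
        k = int(rng.integers(2, 6))
        tokens = np.array([f"c{i}" for i in range(k)], dtype=object)
        predictors[f"g{j}"] = rng.choice(tokens, size=n_rows)
    y = np.round(rng.random(n_rows) * 50) / 50
    return table_from_arrays(predictors, y)


def linear_triple_trajectory(
    dist_ha: float = 1.9,
    dist_dh: float = 1.0,
    angle_dha_deg: float = 175.0,
    n_ticks: int = 1,
    acceptor_element: str = "O",
) -> Trajectory:
    """One D-H...A(-AA) unit with exact geometry, replicated over ticks."""
    atoms = [
        Atom(1, "N", "N", "ALA", 1, "A"),
        Atom(2, "H", "H", "ALA", 1, "A"),
        Atom(3, "O", acceptor_element, "GLY", 2, "A"),
        Atom(4, "C", "C", "GLY", 2, "A"),
    ]
    d = np.array([0.0, 0.0, 0.0])
    h = np.array([dist_dh, 0.0, 0.0])
    beta = np.radians(180.0 - angle_dha_deg)
    a = h + dist_ha * np.array([np.cos(beta), np.sin(beta), 0.0])
    aa = a + 1.23 * np.array([0.0, 1.0, 0.0])
    frame = np.stack([d, h, a, aa])
    coords = np.repeat(frame[None], n_ticks, axis=0)
    return Trajectory("triple", 1.0, atoms, coords)
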