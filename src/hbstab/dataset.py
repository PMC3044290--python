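"""Stability labeling and data-table assembly.

A data table has one row per H-bond *occurrence*: a (bond, tick) pair where
the bond is present and a full ``l``-tick future window exists. The label is
the measured stability ``y = m / l`` — the fraction of the next ``l`` ticks
at which the bond is present.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hbonds import DetectionCriteria, HBondID, OccurrenceSeries, build_presence_matrix
from .predictors import (
    MISSING_CATEGORY,
    MayoParameters,
    PredictorRegistry,
    default_registry,
    featurize_trajectory,
    trailing_mean,
)
from .trajectory import Trajectory

__all__ = [
    "KEY_COLUMNS",
    "DataTable",
    "measured_stability",
    "build_table",
    "mix_tables",
    "split_validation",
]

#: Row-identity columns, before predictor columns and the label column "y".
KEY_COLUMNS = [
    "protein_label", "tick", "donor_serial", "hydrogen_serial", "acceptor_serial",
]
BOND_COLUMNS = KEY_COLUMNS[0:1] + KEY_COLUMNS[2:]


@dataclass
class DataTable:
    """Rows = H-bond occurrences, columns = predictors + measured stability.

    ``df`` columns are ``KEY_COLUMNS + registry.names + ["y"]``.
    """

    df: pd.DataFrame
    registry: PredictorRegistry
    l: int
    l_prime: int
    delta_ps: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = KEY_COLUMNS + self.registry.names + ["y"]
        missing = [c for c in expected if c not in self.df.columns]
        if missing:
            raise ValueError(f"data table missing columns: {missing}")
        self.df = self.df[expected].reset_index(drop=True)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy(dtype=float)

    def predictor_column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy()

    def bond_keys(self) -> pd.Series:
        return self.df[BOND_COLUMNS].apply(tuple, axis=1)

    def with_rows(self, df: pd.DataFrame) -> "DataTable":
        return DataTable(df.reset_index(drop=True), self.registry, self.l,
                         self.l_prime, self.delta_ps, dict(self.metadata))

    # -- serialization ------------------------------------------------------

    def to_csv(self, path: str, sidecar_path: str | None = None) -> None:
        """Write rows as CSV plus a JSON sidecar with registry and settings."""
        self.df.to_csv(path, index=False)
        if sidecar_path is None:
            sidecar_path = str(path) + ".meta.json"
        meta = {
            "registry": self.registry.to_config(),
            "l": self.l,
            "l_prime": self.l_prime,
            "delta_ps": self.delta_ps,
            "metadata": self.metadata,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_csv(cls, path: str, sidecar_path: str | None = None) -> "DataTable":
        if sidecar_path is None:
            sidecar_path = str(path) + ".meta.json"
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        registry = PredictorRegistry.from_config(meta["registry"])
        df = pd.read_csv(path)
        for spec in registry:
            if spec.kind == "categorical":
                df[spec.name] = df[spec.name].fillna(MISSING_CATEGORY).astype(str)
        return cls(df, registry, int(meta["l"]), int(meta["l_prime"]),
                   float(meta["delta_ps"]), meta.get("metadata", {}))


def measured_stability(series: OccurrenceSeries | np.ndarray, i: int, l: int):
    """Measured stability ``y = m / l`` of an occurrence at tick ``i``:
    the fraction of ticks ``i+1 .. i+l`` at which the bond is present.

    Returns ``None`` (row-skip signal) when fewer than ``l`` future ticks
    exist.
    """
    presence = series.presence if isinstance(series, OccurrenceSeries) \
        else np.asarray(series, dtype=bool)
    if l < 1:
        raise ValueError("l must be >= 1")
    if i < 0:
        raise ValueError("tick index must be >= 0")
    if i + l > len(presence) - 1:
        return None
    return float(presence[i + 1:i + l + 1].sum()) / l


def build_table(
    trajectory: Trajectory,
    criteria: DetectionCriteria = DetectionCriteria(),
    registry: PredictorRegistry | None = None,
    l: int = 50,
    l_prime: int = 50,
    env_radius: float = 5.0,
    mayo_params: MayoParameters = MayoParameters(),
) -> DataTable:
    """Detect bonds, featurize, average, and label a whole trajectory.

    Rows are emitted for every (bond, tick i) with the bond present at tick
    i and a full l-tick future window (i <= n_ticks - 1 - l); rows lacking a
    full window are dropped. Time-varying predictors at tick i are trailing
    means over the last min(i+1, l') ticks.
    """
    if registry is None:
        registry = default_registry()
    series_map = build_presence_matrix(trajectory, criteria)
    bonds = sorted(series_map)
    T = trajectory.n_ticks
    columns = {c: [] for c in KEY_COLUMNS + registry.names + ["y"]}
    if not bonds or T <= l + 1:
        if T <= l + 1:
            warnings.warn(
                f"trajectory {trajectory.protein_label!r} has {T} ticks, "
                f"needs more than l + 1 = {l + 1}; table is empty",
                stacklevel=2,
            )
        df = pd.DataFrame({c: pd.Series(columns[c]) for c in columns})
        return DataTable(df, registry, l, l_prime, trajectory.delta_ps)

    presence = np.stack([series_map[b].presence for b in bonds], axis=1)
    tv, static = featurize_trajectory(
        trajectory, bonds, presence, registry, env_radius, mayo_params
    )
    averaged = {
        name: trailing_mean(arr, l_prime)
        if registry.spec(name).time_varying else arr
        for name, arr in tv.items()
    }

    max_i = T - 1 - l
    csum = np.cumsum(presence.astype(np.int64), axis=0)

    rows_bond: list[int] = []
    rows_tick: list[int] = []
    ys: list[float] = []
    for k in range(len(bonds)):
        ticks = np.flatnonzero(presence[:max_i + 1, k])
        if ticks.size == 0:
            continue
        m = csum[ticks + l, k] - csum[ticks, k]
        rows_bond.extend([k] * ticks.size)
        rows_tick.extend(ticks.tolist())
        ys.extend((m / float(l)).tolist())

    rows_bond_arr = np.array(rows_bond, dtype=int)
    rows_tick_arr = np.array(rows_tick, dtype=int)
    data: dict[str, object] = {
        "protein_label": [trajectory.protein_label] * len(rows_bond),
        "tick": rows_tick_arr,
        "donor_serial": [bonds[k].donor_serial for k in rows_bond],
        "hydrogen_serial": [bonds[k].hydrogen_serial for k in rows_bond],
        "acceptor_serial": [bonds[k].acceptor_serial for k in rows_bond],
    }
    for name in registry.names:
        if name in averaged:
            data[name] = averaged[name][rows_tick_arr, rows_bond_arr]
        elif name in static:
            data[name] = static[name][rows_bond_arr]
        else:
            raise ValueError(f"predictor {name!r} not computed by featurizer")
    data["y"] = np.array(ys)
    df = pd.DataFrame(data)
    for spec in registry:
        if spec.kind == "categorical":
            df[spec.name] = df[spec.name].fillna(MISSING_CATEGORY).astype(str)
    return DataTable(df, registry, l, l_prime, trajectory.delta_ps)


def mix_tables(tables: list[DataTable], fraction: float, seed: int) -> DataTable:
    """Stratified random sample: ``ceil(fraction * n_j)`` rows drawn without
    replacement from each table ``j``, concatenated. Deterministic per seed."""
    if not tables:
        raise ValueError("need at least one table")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ref = tables[0]
    for t in tables[1:]:
        if not ref.registry.compatible(t.registry):
            raise ValueError("tables have incompatible predictor registries")
    rng = np.random.default_rng(seed)
    parts = []
    for t in tables:
        n = t.n_rows
        k = math.ceil(fraction * n)
        chosen = np.sort(rng.choice(n, size=k, replace=False))
        parts.append(t.df.iloc[chosen])
    return ref.with_rows(pd.concat(parts, ignore_index=True))


def split_validation(
    table: DataTable, validation_fraction: float, seed: int
) -> tuple[DataTable, DataTable]:
    """Partition a table into (train, validation) grouped by bond identity:
    all rows of one bond land on the same side. The validation side is sized
    as close to the requested fraction as bond granularity allows."""
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must be in (0, 1)")
    keys = table.bond_keys()
    unique_bonds = sorted(keys.unique())
    if len(unique_bonds) < 2:
        raise ValueError("cannot partition a table with a single bond")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique_bonds))
    counts = keys.value_counts()
    sizes = np.array([counts[unique_bonds[i]] for i in order], dtype=float)
    cum = np.cumsum(sizes)
    target = validation_fraction * table.n_rows
    # best prefix of the shuffled bond list, keeping both sides nonempty
    k = int(np.argmin(np.abs(cum - target))) + 1
    k = min(k, len(unique_bonds) - 1)
    val_bonds = {unique_bonds[i] for i in order[:k]}
    mask = keys.isin(val_bonds).to_numpy()
    return table.with_rows(table.df[~mask]), table.with_rows(table.df[mask])
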