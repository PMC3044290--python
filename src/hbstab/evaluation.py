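"""Model evaluation: RMSE, relative base error decrease (RBED),
identification curves for the least stable bonds, predictor importance,
and the leave-one-protein-out protocol."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cart import RegressionTree, grow_tree, prune_tree
from .dataset import DataTable, mix_tables, split_validation

__all__ = [
    "GlobalMeanModel",
    "train_single_predictor_tree",
    "train_model",
    "rmse",
    "rbed",
    "IdentificationCurve",
    "identification_curve",
    "predictor_importance",
    "leave_one_protein_out",
]


@dataclass
class GlobalMeanModel:
    """Base model: predicts the average measured stability of its training
    table for every occurrence."""

    mean: float

    @classmethod
    def fit(cls, table: DataTable) -> "GlobalMeanModel":
        if table.n_rows == 0:
            raise ValueError("cannot fit on an empty table")
        return cls(mean=float(table.y.mean()))

    def predict_frame(self, df) -> np.ndarray:
        return np.full(len(df), self.mean)


def train_model(
    train: DataTable,
    validation: DataTable | None = None,
    max_depth: int = 5,
    min_node_size: int = 10,
    predictors: list[str] | None = None,
) -> RegressionTree:
    """Grow (and optionally prune) a tree, possibly on a predictor subset."""
    registry = train.registry if predictors is None \
        else train.registry.subset(predictors)
    tree = grow_tree(train, max_depth=max_depth, min_node_size=min_node_size,
                     registry=registry)
    if validation is not None and validation.n_rows > 0:
        tree = prune_tree(tree, validation)
    return tree


def train_single_predictor_tree(
    train: DataTable,
    validation: DataTable | None,
    predictor: str = "FIRST_energy",
    max_depth: int = 5,
    min_node_size: int = 10,
) -> RegressionTree:
    """Base model: a tree grown/pruned with the same settings but a
    one-predictor registry."""
    return train_model(train, validation, max_depth, min_node_size,
                       predictors=[predictor])


def _predictions(model, table: DataTable) -> np.ndarray:
    return np.asarray(model.predict_frame(table.df), dtype=float)


def rmse(model, table: DataTable) -> float:
    """Root mean square prediction error on a table."""
    if table.n_rows == 0:
        raise ValueError("cannot evaluate on an empty table")
    pred = _predictions(model, table)
    return float(np.sqrt(np.mean((pred - table.y) ** 2)))


def rbed(model, base, table: DataTable) -> float:
    """Relative base error decrease, percent:
    ``100 * (RMSE(base, T) - RMSE(model, T)) / RMSE(base, T)``."""
    base_rmse = rmse(base, table)
    if base_rmse <= 0:
        raise ZeroDivisionError("base model has zero RMSE; RBED undefined")
    return 100.0 * (base_rmse - rmse(model, table)) / base_rmse


# ---------------------------------------------------------------------------
# Identification curves
# ---------------------------------------------------------------------------

@dataclass
class IdentificationCurve:
    """w(u): fraction of the truly least-stable set S captured within the
    lowest-ranked 100*u % occurrences of a predicted ranking."""

    u: np.ndarray
    w: np.ndarray
    fraction: float = 0.10
    w_ideal: np.ndarray | None = None
    w_base: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"u": self.u, "w_model": self.w}
        if self.w_ideal is not None:
            data["w_ideal"] = self.w_ideal
        if self.w_base is not None:
            data["w_base"] = self.w_base
        return pd.DataFrame(data)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def _curve_from_ranking(order: np.ndarray, in_s: np.ndarray,
                        u_grid: np.ndarray, s_size: int) -> np.ndarray:
    hits = np.cumsum(in_s[order])
    n = order.size
    w = np.empty(u_grid.size)
    for g, u in enumerate(u_grid):
        k = int(math.floor(u * n + 1e-9))
        w[g] = hits[k - 1] / s_size if k > 0 else 0.0
    return w


def identification_curve(
    model,
    table: DataTable,
    fraction: float = 0.10,
    grid: np.ndarray | None = None,
    base_scores: np.ndarray | None = None,
) -> IdentificationCurve:
    """Identification curve of the least stable occurrences.

    S is the ``ceil(fraction * n)`` occurrences with the smallest measured
    stability (stable ties on row order); the model ranking sorts by
    ascending predicted stability. The ideal curve (ranking by true y) is
    always attached; ``base_scores`` (lower = ranked earlier) adds a base
    curve, e.g. decreasing FIRST_energy.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if table.n_rows == 0:
        raise ValueError("cannot evaluate on an empty table")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    n = table.n_rows
    y = table.y
    s_size = math.ceil(fraction * n)
    ideal_order = np.argsort(y, kind="stable")
    in_s = np.zeros(n, dtype=bool)
    in_s[ideal_order[:s_size]] = True

    pred = _predictions(model, table)
    model_order = np.argsort(pred, kind="stable")
    w_model = _curve_from_ranking(model_order, in_s, grid, s_size)
    w_ideal = _curve_from_ranking(ideal_order, in_s, grid, s_size)
    w_base = None
    if base_scores is not None:
        base_order = np.argsort(np.asarray(base_scores, dtype=float),
                                kind="stable")
        w_base = _curve_from_ranking(base_order, in_s, grid, s_size)
    return IdentificationCurve(u=grid, w=w_model, fraction=fraction,
                               w_ideal=w_ideal, w_base=w_base)


# ---------------------------------------------------------------------------
# Predictor importance
# ---------------------------------------------------------------------------

def predictor_importance(
    trees: list[RegressionTree], scale: bool = True
) -> dict[str, float]:
    """Importance of predictor p: sum over p's split nodes of
    ``score * n_fall``, averaged across trees; if ``scale``, divided by the
    minimum non-zero average so the least important used predictor maps to 1.
    """
    if not trees:
        return {}
    reg = trees[0].registry
    for t in trees[1:]:
        if not reg.compatible(t.registry):
            raise ValueError("trees have incompatible registries")
    totals = {name: 0.0 for name in reg.names}
    any_split = False
    for tree in trees:
        for node in tree.internal_nodes():
            any_split = True
            totals[node.split.predictor] += node.split.score * node.n_fall
    if not any_split:
        return {}
    averaged = {name: v / len(trees) for name, v in totals.items()}
    if scale:
        nonzero = [v for v in averaged.values() if v > 0]
        floor = min(nonzero)
        averaged = {name: v / floor for name, v in averaged.items()}
    return averaged


# ---------------------------------------------------------------------------
# Leave-one-protein-out protocol
# ---------------------------------------------------------------------------

@dataclass
class HeldOutReport:
    held_out: str
    rbed_values: list[float]
    rmse_values: list[float] = field(default_factory=list)

    @property
    def mean_rbed(self) -> float:
        return float(np.mean(self.rbed_values))

    @property
    def var_rbed(self) -> float:
        return float(np.var(self.rbed_values))


def leave_one_protein_out(
    tables: list[DataTable],
    fraction: float = 0.1,
    max_depth: int = 5,
    n_models: int = 10,
    seed: int = 0,
    min_node_size: int = 10,
    validation_fraction: float = 0.25,
    predictors: list[str] | None = None,
    labels: list[str] | None = None,
) -> list[HeldOutReport]:
    """For each table: train ``n_models`` models on a stratified mix of the
    remaining tables, prune on a bond-grouped validation split, and report
    RBED on the held-out table against a training-mean base model."""
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    if labels is None:
        labels = []
        for j, t in enumerate(tables):
            vals = t.df["protein_label"].unique()
            labels.append(str(vals[0]) if len(vals) else f"table_{j}")
    seeds = np.random.SeedSequence(seed).generate_state(len(tables) * n_models * 2)
    reports = []
    s = 0
    for j, held_out in enumerate(tables):
        others = [t for k, t in enumerate(tables) if k != j]
        rbeds, rmses = [], []
        for _ in range(n_models):
            mix_seed = int(seeds[s]); val_seed = int(seeds[s + 1]); s += 2
            mixed = mix_tables(others, fraction, mix_seed)
            train, validation = split_validation(mixed, validation_fraction,
                                                 val_seed)
            model = train_model(train, validation, max_depth, min_node_size,
                                predictors=predictors)
            base = GlobalMeanModel.fit(train)
            rbeds.append(rbed(model, base, held_out))
            rmses.append(rmse(model, held_out))
        reports.append(HeldOutReport(labels[j], rbeds, rmses))
    return reports


def loo_report_frame(reports: list[HeldOutReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "held_out": [r.held_out for r in reports],
            "mean_RBED": [r.mean_rbed for r in reports],
            "var_RBED": [r.var_rbed for r in reports],
        }
    )
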