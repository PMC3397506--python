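"""Kohonen self-organizing map and representative train/test splitting.

A rectangular lattice of weight vectors is trained by online competitive
learning: per input, the winning node (minimum Euclidean distance) and its
lattice neighbours move toward the input under a decaying learning rate
and a shrinking Gaussian neighbourhood.  Compounds mapping to the same
node are structural neighbours, so a split that (a) keeps the compound
nearest each occupied node's weight in the training set and (b) draws the
test set from multi-occupant nodes covers the descriptor space with both
halves — the premise behind SOM-based "rational" train/test design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SOMGrid",
    "TrainTestSplit",
    "default_grid_shape",
    "train_som",
    "assign_cells",
    "split_train_test",
]


@dataclass
class SOMGrid:
    shape: tuple[int, int]
    weights: np.ndarray  # (rows*cols, dim), row-major node order
    training_meta: dict = field(default_factory=dict)

    def node_coords(self) -> np.ndarray:
        rows, cols = self.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])


@dataclass
class TrainTestSplit:
    train_ids: list[str]
    test_ids: list[str]
    cell_of: dict[str, tuple[int, int]]


def default_grid_shape(n_compounds: int, cells_per_compound: float = 0.25) -> tuple[int, int]:
    """Smallest square lattice offering at least ``cells_per_compound * n`` nodes.

    Reproduces an 8x8 grid for a 224-compound subset.
    """
    needed = max(1, int(np.ceil(cells_per_compound * n_compounds)))
    side = int(np.ceil(np.sqrt(needed)))
    return (side, side)


def train_som(
    features: np.ndarray,
    shape: tuple[int, int],
    *,
    epochs: int = 100,
    lr_start: float = 0.5,
    lr_end: float = 0.01,
    radius_start: float | None = None,
    radius_end: float = 0.25,
    seed: int = 0,
) -> SOMGrid:
    """Online Kohonen training, deterministic for a given seed.

    Weights are initialised uniformly within the per-dimension data range.
    The learning rate decays linearly and the neighbourhood radius
    exponentially over ``epochs`` passes through a reshuffled sample order.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("features must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    rows, cols = shape
    if rows < 1 or cols < 1:
        raise ValueError("grid must contain at least one node")
    n, dim = X.shape
    n_nodes = rows * cols
    rng = np.random.default_rng(seed)

    lo, hi = X.min(axis=0), X.max(axis=0)
    W = rng.uniform(lo, hi, size=(n_nodes, dim))
    coords = SOMGrid((rows, cols), W).node_coords().astype(float)

    if radius_start is None:
        radius_start = max(rows, cols) / 2.0
    radius_start = max(radius_start, radius_end, 1e-9)
    total = epochs * n
    step = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            frac = step / max(total - 1, 1)
            lr = lr_start + (lr_end - lr_start) * frac
            sigma = radius_start * (radius_end / radius_start) ** frac
            x = X[i]
            d2 = ((W - x) ** 2).sum(axis=1)
            win = int(np.argmin(d2))  # first index = row-major tie-break
            g2 = ((coords - coords[win]) ** 2).sum(axis=1)
            h = np.exp(-g2 / (2.0 * sigma**2))
            W += lr * h[:, None] * (x - W)
            step += 1
    return SOMGrid(
        shape=(rows, cols),
        weights=W,
        training_meta={
            "epochs": epochs,
            "lr": (lr_start, lr_end),
            "radius": (radius_start, radius_end),
            "seed": seed,
        },
    )


def assign_cells(som: SOMGrid, features: np.ndarray) -> np.ndarray:
    """Winning (row, col) per compound; ties go to the row-major-first node."""
    X = np.asarray(features, dtype=float)
    if X.shape[1] != som.weights.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != SOM dimension {som.weights.shape[1]}"
        )
    d2 = ((X[:, None, :] - som.weights[None, :, :]) ** 2).sum(axis=2)
    winners = np.argmin(d2, axis=1)
    rows, cols = som.shape
    return np.column_stack([winners // cols, winners % cols])


def split_train_test(
    som: SOMGrid,
    features: np.ndarray,
    ids: Sequence[str],
    *,
    ratio: float = 4.0,
    seed: int = 0,
) -> TrainTestSplit:
    """Representative ~``ratio``:1 train/test split from the SOM assignment.

    The compound nearest each occupied node's weight vector is pinned to
    the training set, so training covers every occupied region of the map.
    The test quota ``floor(n / (ratio + 1))`` is then drawn (seeded,
    without replacement) from the remaining compounds with probability
    proportional to their node's occupancy, so densely populated regions
    contribute proportionally more test compounds.  If the representatives
    exhaust the data the quota is relaxed with a warning.
    """
    X = np.asarray(features, dtype=float)
    ids = list(ids)
    n = len(ids)
    if X.shape[0] != n:
        raise ValueError("ids and features disagree in length")
    cells = assign_cells(som, X)
    rows, cols = som.shape
    node_idx = cells[:, 0] * cols + cells[:, 1]
    d2 = ((X - som.weights[node_idx]) ** 2).sum(axis=1)

    representatives: set[int] = set()
    for node in np.unique(node_idx):
        members = np.flatnonzero(node_idx == node)
        representatives.add(int(members[np.argmin(d2[members])]))

    occupancy = np.bincount(node_idx, minlength=rows * cols)
    pool = np.array([i for i in range(n) if i not in representatives], dtype=int)
    quota = int(np.floor(n / (ratio + 1.0)))
    if quota > len(pool):
        warnings.warn(
            f"test quota {quota} exceeds the {len(pool)} non-representative "
            "compounds; relaxing the quota",
            stacklevel=2,
        )
        quota = len(pool)

    rng = np.random.default_rng(seed)
    if quota > 0:
        weights = occupancy[node_idx[pool]].astype(float)
        weights /= weights.sum()
        test_idx = rng.choice(pool, size=quota, replace=False, p=weights, shuffle=False)
    else:
        test_idx = np.array([], dtype=int)
    test_set = set(int(i) for i in test_idx)
    train_ids = [ids[i] for i in range(n) if i not in test_set]
    test_ids = [ids[i] for i in sorted(test_set)]
    cell_of = {ids[i]: (int(cells[i, 0]), int(cells[i, 1])) for i in range(n)}
    return TrainTestSplit(train_ids=train_ids, test_ids=test_ids, cell_of=cell_of)
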