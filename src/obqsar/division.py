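"""Self-consistent division of a compound set into binding-affinity subsets.

Compounds are ranked by an aggregate protein-binding score and cut into
contiguous subsets.  The cut positions minimise the mean within-subset
pairwise dispersion in (z-scored) descriptor space,

    J = (1/n) * sum_i [ sum_{j != k in subset i} ||x_j - x_k||^2 / (r_i (r_i - 1)) ],

so each subset groups compounds that are mutually similar, while the
ranking constraint keeps the subsets interpretable as affinity bands.
Because the ordered-pair sum telescopes to ``2 * S_i / (r_i - 1)`` with
``S_i`` the within-subset sum of squared deviations from the subset mean,
segment costs are cheap and the optimal cut positions for a fixed number
of subsets can be found exactly by dynamic programming over the ranked
order.  The quality of each candidate subset count is judged by the
per-subset coefficient of determination between logB and the aggregate
binding score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .datamodel import CompoundDataset, CompoundRecord

__all__ = [
    "InfeasiblePartitionError",
    "SubsetPartition",
    "aggregate_binding_score",
    "aggregate_scores",
    "standardize_features",
    "dispersion_criterion",
    "self_consistent_division",
]


class InfeasiblePartitionError(ValueError):
    """No contiguous partition satisfies the minimum-size constraint."""


@dataclass
class SubsetPartition:
    """A contiguous-in-rank partition of a dataset into affinity subsets.

    Subset labels are 0-based and ascend with the aggregate binding score
    (subset 0 holds the weakest binders).  ``boundaries`` are the n-1 score
    cut points (midpoints between the adjacent ranked compounds), ascending.
    """

    n_subsets: int
    boundaries: list[float]
    labels: np.ndarray  # per-compound subset index, in dataset order
    criterion_value: float
    per_subset_r2: list[float]

    def sizes(self) -> list[int]:
        return [int(np.sum(self.labels == s)) for s in range(self.n_subsets)]


AggregationMode = Literal["max", "mean"]


def aggregate_binding_score(record: CompoundRecord, mode: str = "max") -> float:
    """Collapse a compound's per-protein binding scores to one ranking scalar.

    ``max`` (default) takes the strongest interaction — the protein a
    compound binds best is the one most likely to dominate its disposition.
    ``mean`` averages; any other value is read as a protein name.
    """
    if not record.binding_scores:
        raise ValueError(f"record {record.compound_id!r} has no binding scores")
    vals = record.binding_scores
    if mode == "max":
        return float(max(vals.values()))
    if mode == "mean":
        return float(np.mean(list(vals.values())))
    if mode in vals:
        return float(vals[mode])
    raise KeyError(f"protein {mode!r} absent from {sorted(vals)}")


def aggregate_scores(dataset: CompoundDataset, mode: str = "max") -> np.ndarray:
    return np.array([aggregate_binding_score(r, mode) for r in dataset.records])


def standardize_features(X: np.ndarray) -> np.ndarray:
    """Column-wise z-scoring; zero-variance columns are left centred."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _segment_stats(features: np.ndarray):
    """Prefix machinery: cost(a, b) of the ranked slice [a, b) in O(1)."""
    n = features.shape[0]
    P = np.vstack([np.zeros(features.shape[1]), np.cumsum(features, axis=0)])
    Q = np.concatenate([[0.0], np.cumsum((features**2).sum(axis=1))])
    G = P @ P.T  # Gram of prefix sums: ||P_b - P_a||^2 via 3 lookups
    diag = np.diag(G)

    def cost(a: np.ndarray | int, b: np.ndarray | int) -> np.ndarray | float:
        r = np.asarray(b) - np.asarray(a)
        ss2 = diag[b] + diag[a] - 2.0 * G[a, b]
        S = (Q[b] - Q[a]) - ss2 / r
        return 2.0 * np.maximum(S, 0.0) / (r - 1)

    return cost, n


def dispersion_criterion(labels: Sequence[int], features: np.ndarray) -> float:
    """Mean within-subset pairwise squared-distance dispersion.

    ``features`` should be z-scored over the whole dataset.  Every subset
    must contain at least two compounds (the ordered-pair normaliser
    ``r(r-1)`` vanishes otherwise).
    """
    labels = np.asarray(labels)
    features = np.asarray(features, dtype=float)
    total = 0.0
    subsets = np.unique(labels)
    for s in subsets:
        xs = features[labels == s]
        r = xs.shape[0]
        if r < 2:
            raise ValueError(f"subset {s} has size {r} < 2")
        S = float(((xs - xs.mean(axis=0)) ** 2).sum())
        total += 2.0 * S / (r - 1)
    return total / len(subsets)


def _optimal_cuts(features_ranked: np.ndarray, n_subsets: int, min_size: int):
    """Exact DP over contiguous cut positions; returns (cut indices, J)."""
    cost, n = _segment_stats(features_ranked)
    m = max(2, min_size)
    if n < n_subsets * m:
        raise InfeasiblePartitionError(
            f"{n} compounds cannot form {n_subsets} subsets of size >= {m}"
        )
    INF = np.inf
    # D[k][b] = min total cost of splitting ranked[0:b] into k subsets
    D = np.full((n_subsets + 1, n + 1), INF)
    back = np.zeros((n_subsets + 1, n + 1), dtype=int)
    bs = np.arange(m, n + 1)
    D[1, bs] = cost(np.zeros(len(bs), dtype=int), bs)
    for k in range(2, n_subsets + 1):
        for b in range(k * m, n + 1):
            a = np.arange((k - 1) * m, b - m + 1)
            cand = D[k - 1, a] + cost(a, np.full(len(a), b))
            j = int(np.argmin(cand))
            D[k, b] = cand[j]
            back[k, b] = a[j]
    if not np.isfinite(D[n_subsets, n]):
        raise InfeasiblePartitionError("no feasible partition found")
    cuts = []
    b = n
    for k in range(n_subsets, 1, -1):
        b = int(back[k, b])
        cuts.append(b)
    cuts.reverse()
    return cuts, float(D[n_subsets, n] / n_subsets)


def _safe_r2(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def self_consistent_division(
    dataset: CompoundDataset,
    candidate_n: Iterable[int] = (2, 3, 4, 5),
    *,
    mode: str = "max",
    min_size: int = 20,
    feature_names: Sequence[str] | None = None,
) -> SubsetPartition:
    """Divide a dataset into affinity-ordered subsets.

    For every candidate subset count the globally optimal contiguous cut
    positions (under the dispersion criterion) are found by dynamic
    programming on the affinity-ranked order.  Each candidate partition is
    then judged by the per-subset R² between logB and the aggregate binding
    score; the candidate with the highest mean per-subset R² is returned
    (ties to the smaller count).  Record order never matters: ranking is by
    (score descending, compound_id) and the result is reported in dataset
    order.

    Parameters
    ----------
    candidate_n
        Subset counts to evaluate.
    mode
        Binding-score aggregation (see :func:`aggregate_binding_score`).
    min_size
        Smallest admissible subset (>= 2 enforced).
    feature_names
        Restrict the dispersion criterion to these descriptors; default all.
    """
    scores = aggregate_scores(dataset, mode)
    X = dataset.descriptor_matrix()
    if feature_names is not None:
        cols = [dataset.descriptor_names.index(nm) for nm in feature_names]
        X = X[:, cols]
    Z = standardize_features(X)
    logb = dataset.logb_vector()

    # descending affinity, ties broken by compound_id for order-invariance
    ids = dataset.compound_ids
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    order = np.array(order, dtype=int)
    Zr = Z[order]
    scores_r = scores[order]
    logb_r = logb[order]

    best: SubsetPartition | None = None
    best_key: tuple[float, int] | None = None
    for n_sub in sorted(set(int(k) for k in candidate_n)):
        if n_sub < 1:
            raise ValueError("candidate subset counts must be >= 1")
        if n_sub == 1:
            cost, n = _segment_stats(Zr)
            cuts, J = [], float(cost(0, n))
        else:
            cuts, J = _optimal_cuts(Zr, n_sub, min_size)

        # ranked position -> subset label; subset 0 = weakest binders
        seg_edges = [0, *cuts, len(order)]
        labels_ranked = np.empty(len(order), dtype=int)
        for k in range(n_sub):
            labels_ranked[seg_edges[k] : seg_edges[k + 1]] = n_sub - 1 - k
        labels = np.empty(len(order), dtype=int)
        labels[order] = labels_ranked

        boundaries = sorted(
            float((scores_r[c - 1] + scores_r[c]) / 2.0) for c in cuts
        )
        r2s = [
            _safe_r2(scores_r[labels_ranked == s], logb_r[labels_ranked == s])
            for s in range(n_sub)
        ]
        part = SubsetPartition(
            n_subsets=n_sub,
            boundaries=boundaries,
            labels=labels,
            criterion_value=J,
            per_subset_r2=r2s,
        )
        key = (-float(np.mean(r2s)), n_sub)
        if best_key is None or key < best_key:
            best, best_key = part, key
    assert best is not None
    return best
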