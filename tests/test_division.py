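"""Dispersion criterion, exact cut search, and affinity-boundary recovery."""

import itertools

import numpy as np
import pytest

from obqsar.datamodel import CompoundDataset, CompoundRecord
from obqsar.division import (
    InfeasiblePartitionError,
    aggregate_binding_score,
    aggregate_scores,
    dispersion_criterion,
    self_consistent_division,
    standardize_features,
)
from obqsar.synthetic import SyntheticConfig, generate_dataset

from conftest import make_record


class TestAggregateScore:
    def test_modes(self):
        rec = make_record("A", 50.0, {"cyp3a4": 6.0, "cyp2d6": 4.0, "pgp": 7.0})
        assert aggregate_binding_score(rec, "max") == 7.0
        assert aggregate_binding_score(rec, "mean") == pytest.approx(17.0 / 3.0)
        assert aggregate_binding_score(rec, "cyp2d6") == 4.0

    def test_singleton_any_mode(self):
        rec = make_record("A", 50.0, {"cyp3a4": 5.2})
        assert aggregate_binding_score(rec, "max") == 5.2
        assert aggregate_binding_score(rec, "mean") == 5.2

    def test_absent_protein_raises(self):
        rec = make_record("A", 50.0, {"cyp3a4": 5.2})
        with pytest.raises(KeyError):
            aggregate_binding_score(rec, "pgp")


class TestDispersionCriterion:
    def test_identical_points_zero(self):
        X = np.ones((6, 3))
        assert dispersion_criterion([0, 0, 0, 1, 1, 1], X) == 0.0

    def test_pair_at_distance_d(self):
        d = 1.7
        X = np.array([[0.0, 0.0], [d, 0.0]])
        # ordered-pair sum 2d^2 over r(r-1)=2 -> d^2
        assert dispersion_criterion([0, 0], X) == pytest.approx(d**2)

    def test_two_pairs_average(self):
        d1, d2 = 1.0, 3.0
        X = np.array([[0, 0], [d1, 0], [10, 0], [10 + d2, 0]], dtype=float)
        expected = (d1**2 + d2**2) / 2.0
        assert dispersion_criterion([0, 0, 1, 1], X) == pytest.approx(expected)

    def test_undersized_subset_raises(self):
        with pytest.raises(ValueError):
            dispersion_criterion([0, 1, 1], np.zeros((3, 2)))


def _brute_force_best(Z, n_subsets, min_size):
    """Enumerate every contiguous partition; return the minimal criterion."""
    n = len(Z)
    best = np.inf
    positions = range(min_size, n - min_size + 1)
    for cuts in itertools.combinations(positions, n_subsets - 1):
        edges = [0, *cuts, n]
        sizes = np.diff(edges)
        if np.any(sizes < min_size):
            continue
        labels = np.repeat(np.arange(n_subsets), sizes)
        best = min(best, dispersion_criterion(labels, Z))
    return best


def _toy_dataset(rng, n, d=3):
    scores = rng.uniform(3, 9, size=n)
    records = [
        CompoundRecord(
            compound_id=f"c{i:03d}",
            ob_percent=float(rng.uniform(1, 99)),
            binding_scores={"cyp3a4": float(scores[i])},
            descriptors={f"x{j}": float(v) for j, v in enumerate(rng.normal(size=d))},
        )
        for i in range(n)
    ]
    return CompoundDataset(records, [f"x{j}" for j in range(d)])


@pytest.mark.parametrize("n,n_subsets", [(12, 2), (20, 2), (20, 3), (40, 3)])
def test_search_matches_exhaustive_enumeration(rng, n, n_subsets):
    ds = _toy_dataset(rng, n)
    part = self_consistent_division(ds, candidate_n=[n_subsets], min_size=2)
    scores = aggregate_scores(ds, "max")
    order = sorted(range(n), key=lambda i: (-scores[i], ds.compound_ids[i]))
    Z = standardize_features(ds.descriptor_matrix())[order]
    assert part.criterion_value == pytest.approx(
        _brute_force_best(Z, n_subsets, 2), abs=1e-10
    )


def test_single_subset_degenerate(rng):
    ds = _toy_dataset(rng, 10)
    part = self_consistent_division(ds, candidate_n=[1], min_size=2)
    assert part.n_subsets == 1
    assert part.boundaries == []
    Z = standardize_features(ds.descriptor_matrix())
    assert part.criterion_value == pytest.approx(
        dispersion_criterion(np.zeros(10, dtype=int), Z)
    )


def test_two_separated_clouds_boundary_in_gap(rng):
    n = 30
    scores = np.concatenate([rng.uniform(3, 4, 15), rng.uniform(7, 8, 15)])
    records = [
        CompoundRecord(
            compound_id=f"c{i:02d}",
            ob_percent=50.0,
            binding_scores={"cyp3a4": float(scores[i])},
            # descriptor means track the clouds so the criterion sees them
            descriptors={"x0": float(rng.normal(0 if i < 15 else 5, 0.3))},
        )
        for i in range(n)
    ]
    ds = CompoundDataset(records, ["x0"])
    part = self_consistent_division(ds, candidate_n=[2], min_size=2)
    assert 4.0 < part.boundaries[0] < 7.0
    assert sorted(part.sizes()) == [15, 15]


def test_permutation_invariance(rng):
    ds = _toy_dataset(rng, 25)
    part1 = self_consistent_division(ds, candidate_n=[3], min_size=2)
    perm = rng.permutation(25)
    shuffled = CompoundDataset(
        [ds.records[i] for i in perm], list(ds.descriptor_names)
    )
    part2 = self_consistent_division(shuffled, candidate_n=[3], min_size=2)
    assert part1.boundaries == pytest.approx(part2.boundaries)
    assert part1.criterion_value == pytest.approx(part2.criterion_value)


def test_beats_random_contiguous_partitions(rng):
    cfg = SyntheticConfig(n_compounds=120, n_descriptors=10, seed=9)
    ds, _ = generate_dataset(cfg)
    part = self_consistent_division(ds, candidate_n=[4], min_size=5)
    scores = aggregate_scores(ds, "max")
    order = sorted(range(len(ds)), key=lambda i: (-scores[i], ds.compound_ids[i]))
    Z = standardize_features(ds.descriptor_matrix())[order]
    n = len(ds)
    for _ in range(1000):
        cuts = np.sort(rng.choice(np.arange(5, n - 4), size=3, replace=False))
        if np.any(np.diff([0, *cuts, n]) < 5):
            continue
        labels = np.repeat(np.arange(4), np.diff([0, *cuts, n]))
        assert part.criterion_value <= dispersion_criterion(labels, Z) + 1e-10


def test_boundary_recovery_on_synthetic_strata():
    """Cut points land within 0.25 score units of the generating boundaries."""
    for seed in range(1, 6):
        cfg = SyntheticConfig(
            n_compounds=805, n_descriptors=50, noise_sd=0.2, seed=seed
        )
        ds, truth = generate_dataset(cfg)
        part = self_consistent_division(ds, candidate_n=[4], min_size=20)
        for found, true in zip(part.boundaries, truth.boundaries):
            assert abs(found - true) < 0.25, f"seed {seed}: {found} vs {true}"


def test_infeasible_min_size(rng):
    ds = _toy_dataset(rng, 10)
    with pytest.raises(InfeasiblePartitionError):
        self_consistent_division(ds, candidate_n=[3], min_size=4)


def test_partition_covers_and_is_contiguous_in_rank(rng):
    ds = _toy_dataset(rng, 30)
    part = self_consistent_division(ds, candidate_n=[3], min_size=2)
    assert sorted(np.unique(part.labels)) == [0, 1, 2]
    assert sum(part.sizes()) == 30
    scores = aggregate_scores(ds, "max")
    # labels ascend with score band: every subset-1 score above every subset-0 score
    for lo, hi in [(0, 1), (1, 2)]:
        assert scores[part.labels == lo].max() <= scores[part.labels == hi].min()
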