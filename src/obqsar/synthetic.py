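"""Synthetic compound datasets with the structure the pipeline assumes.

Real oral-bioavailability modelling data couple three ingredients that are
hard to come by together: measured %F, docking scores against the
disposition proteins (CYP3A4, CYP2D6, P-gp), and a wide molecular
descriptor block.  The generator emulates exactly that shape:

* binding scores populate four affinity strata (boundaries 5 / 6 / 7.5 by
  default) with realistic imbalance, as a shared latent affinity plus small
  per-protein jitter;
* descriptors follow a block-correlated Gaussian (equicorrelation ``rho``
  within blocks) with a distinct mean vector per stratum, reflecting that
  strong CYP/P-gp binders differ systematically in descriptor space;
* logB is a *stratum-specific* linear model on a few informative
  descriptors (optionally with quadratic or interaction terms) plus
  Gaussian noise, calibrated so %F mostly lies in [1, 100].

The true coefficients and informative descriptor sets are returned as a
:class:`GroundTruth`, so recovery of the generating model is testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .datamodel import CompoundDataset, CompoundRecord

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset"]

#: Stratum proportions mirroring the 192/149/224/240 split of an 805-compound set.
DEFAULT_STRATUM_PROPORTIONS = (192 / 805, 149 / 805, 224 / 805, 240 / 805)


class ConfigError(ValueError):
    """The synthetic configuration is internally inconsistent."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    ``noise_sd`` is the residual standard deviation on the logB scale;
    0.2 corresponds to roughly a 1.6-fold spread in %F, a plausible
    inter-study reproducibility for bioavailability measurements.
    ``stratum_shift`` is the standard deviation of the per-descriptor mean
    offset each affinity stratum receives, i.e. how chemically distinct the
    strata are relative to within-stratum variation.
    """

    n_compounds: int = 805
    n_descriptors: int = 100
    n_informative: int = 5
    subset_boundaries: tuple[float, ...] = (5.0, 6.0, 7.5)
    stratum_proportions: tuple[float, ...] | None = None
    noise_sd: float = 0.2
    nonlinearity: Literal["none", "quadratic", "interaction"] = "none"
    collinearity_rho: float = 0.5
    block_size: int = 5
    stratum_shift: float = 1.0
    score_jitter_sd: float = 0.1
    logb_center: float = 1.0
    logb_signal_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_descriptors:
            raise ConfigError(
                f"n_informative ({self.n_informative}) exceeds n_descriptors "
                f"({self.n_descriptors})"
            )
        b = self.subset_boundaries
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ConfigError("subset boundaries must be strictly increasing")
        if not 0 <= self.collinearity_rho < 1:
            raise ConfigError("collinearity_rho must lie in [0, 1)")
        if self.stratum_proportions is not None and len(self.stratum_proportions) != len(b) + 1:
            raise ConfigError("need one proportion per stratum (len(boundaries) + 1)")


@dataclass
class GroundTruth:
    """What the generator actually used, for recovery tests and audits."""

    boundaries: tuple[float, ...]
    stratum_of: list[int]
    informative: dict[int, list[str]]
    coefficients: dict[int, dict[str, float]]
    intercepts: dict[int, float]
    nonlinearity: str
    nonlinear_terms: dict[int, list[tuple[str, str, float]]] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "boundaries": list(self.boundaries),
            "stratum_of": self.stratum_of,
            "informative": {str(k): v for k, v in self.informative.items()},
            "coefficients": {str(k): v for k, v in self.coefficients.items()},
            "intercepts": {str(k): v for k, v in self.intercepts.items()},
            "nonlinearity": self.nonlinearity,
            "nonlinear_terms": {
                str(k): [list(t) for t in v] for k, v in self.nonlinear_terms.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _stratum_counts(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment; every stratum gets at least one."""
    raw = [p * n for p in proportions]
    counts = [int(np.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = np.argsort([c - f for c, f in zip(counts, raw)])  # largest remainder first
    for i in range(rem):
        counts[order[i]] += 1
    for i, c in enumerate(counts):
        if c == 0 and n >= len(proportions):
            counts[i] = 1
            counts[int(np.argmax(counts))] -= 1
    return counts


def _score_ranges(boundaries: tuple[float, ...]) -> list[tuple[float, float]]:
    b = list(boundaries)
    lo_width = b[1] - b[0] if len(b) > 1 else 1.0
    hi_width = b[-1] - b[-2] if len(b) > 1 else 1.0
    edges = [b[0] - lo_width, *b, b[-1] + hi_width]
    return list(zip(edges[:-1], edges[1:]))


def generate_dataset(config: SyntheticConfig) -> tuple[CompoundDataset, GroundTruth]:
    """Draw one synthetic dataset; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n, d = config.n_compounds, config.n_descriptors
    props = config.stratum_proportions or DEFAULT_STRATUM_PROPORTIONS
    n_strata = len(config.subset_boundaries) + 1
    if config.stratum_proportions is None and n_strata != len(props):
        props = tuple(1.0 / n_strata for _ in range(n_strata))
    counts = _stratum_counts(n, props)
    ranges = _score_ranges(config.subset_boundaries)

    stratum_of = np.repeat(np.arange(n_strata), counts)

    # latent binding affinity per compound, uniform within its stratum range
    latent = np.empty(n)
    for s, (lo, hi) in enumerate(ranges):
        mask = stratum_of == s
        latent[mask] = rng.uniform(lo, hi, size=mask.sum())
    # three protein scores share the latent affinity plus independent jitter
    proteins = ("cyp3a4", "cyp2d6", "pgp")
    scores = {
        p: latent + rng.normal(0.0, config.score_jitter_sd, size=n) for p in proteins
    }

    # block-equicorrelated descriptors: x = sqrt(rho)*z_block + sqrt(1-rho)*e
    rho = config.collinearity_rho
    n_blocks = int(np.ceil(d / config.block_size))
    block_of = np.repeat(np.arange(n_blocks), config.block_size)[:d]
    z = rng.normal(size=(n, n_blocks))
    e = rng.normal(size=(n, d))
    X = np.sqrt(rho) * z[:, block_of] + np.sqrt(1.0 - rho) * e

    # distinct per-stratum descriptor means: each stratum is offset by an
    # independent N(0, stratum_shift^2) amount per descriptor, reflecting
    # systematic chemical differences between the affinity classes
    for s in range(n_strata):
        offset = rng.normal(0.0, config.stratum_shift, size=d)
        X[stratum_of == s] += offset

    names = [f"D{j:04d}" for j in range(d)]
    informative: dict[int, list[str]] = {}
    coefficients: dict[int, dict[str, float]] = {}
    intercepts: dict[int, float] = {}
    nonlinear_terms: dict[int, list[tuple[str, str, float]]] = {}
    logb = np.empty(n)
    for s in range(n_strata):
        mask = stratum_of == s
        idx = rng.choice(d, size=config.n_informative, replace=False)
        idx = np.sort(idx)
        coefs = rng.uniform(-1.0, 1.0, size=config.n_informative)
        signal = X[mask][:, idx] @ coefs
        terms: list[tuple[str, str, float]] = []
        # nonlinear terms act on within-stratum centred descriptors, so the
        # curvature carries no linear component a linear fit could absorb
        Xc = X[mask][:, idx] - X[mask][:, idx].mean(axis=0)
        if config.nonlinearity == "quadratic":
            qcoefs = rng.uniform(0.5, 1.0, size=config.n_informative) * rng.choice(
                [-1.0, 1.0], size=config.n_informative
            )
            signal = signal + (Xc**2) @ qcoefs
            terms = [(names[j], names[j], float(c)) for j, c in zip(idx, qcoefs)]
        elif config.nonlinearity == "interaction":
            pairs = [(idx[k], idx[(k + 1) % len(idx)]) for k in range(len(idx) - 1)]
            icoefs = rng.uniform(-1.0, 1.0, size=len(pairs))
            for k, ((a, b), c) in enumerate(zip(pairs, icoefs)):
                signal = signal + c * Xc[:, k] * Xc[:, (k + 1) % len(idx)]
                terms.append((names[a], names[b], float(c)))
        # calibrate the signal to the target logB location/spread
        sd = float(np.std(signal))
        scale = config.logb_signal_sd / sd if sd > 0 else 1.0
        coefs = coefs * scale
        signal = signal * scale
        terms = [(a, b, c * scale) for a, b, c in terms]
        intercept = config.logb_center - float(np.mean(signal))
        logb[mask] = intercept + signal + rng.normal(0.0, config.noise_sd, size=mask.sum())

        informative[s] = [names[j] for j in idx]
        coefficients[s] = {names[j]: float(c) for j, c in zip(idx, coefs)}
        intercepts[s] = intercept
        if terms:
            nonlinear_terms[s] = terms

    # %F = 10^logB, clipped into the physical (0, 100] range
    ob = np.minimum(10.0 ** logb, 100.0)

    records = [
        CompoundRecord(
            compound_id=f"C{i:04d}",
            ob_percent=float(ob[i]),
            binding_scores={p: float(scores[p][i]) for p in proteins},
            descriptors={names[j]: float(X[i, j]) for j in range(d)},
        )
        for i in range(n)
    ]
    dataset = CompoundDataset(
        records=records,
        descriptor_names=names,
        provenance=f"synthetic(seed={config.seed})",
    )
    truth = GroundTruth(
        boundaries=tuple(config.subset_boundaries),
        stratum_of=[int(s) for s in stratum_of],
        informative=informative,
        coefficients=coefficients,
        intercepts=intercepts,
        nonlinearity=config.nonlinearity,
        nonlinear_terms=nonlinear_terms,
    )
    return dataset, truth
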