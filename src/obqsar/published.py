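"""Fixed, ready-to-use published bioavailability regression equations.

Two stepwise-MLR equations for logB = log10(%F), one for the weakest-
binding affinity subset ("set1") and one for the next band ("set2"), each
with eleven Dragon-style descriptor terms.  The coefficients are carried
verbatim on their original (raw descriptor) scales, so users supply the
named descriptor values and get logB (and %F) back — no refitting
involved.

Descriptor names follow Dragon conventions (GETAWAY autocorrelations such
as ``R3v+``, WHIM symmetry ``G2e``, 3D-MoRSE ``Mor27v``, functional-group
counts such as ``nROCON``, atom-centred fragments like ``O-056``).  A
punctuation-insensitive alias map makes lookup robust to the formatting
variants these names appear under (e.g. ``T(O..P)`` vs ``T (O.P)``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "PublishedModel",
    "MissingDescriptorError",
    "PUBLISHED_MODELS",
    "get_published_model",
    "predict_published",
    "predict_ob_percent",
]


class MissingDescriptorError(KeyError):
    """One or more required descriptors are absent from the input."""

    def __init__(self, missing: list[str]):
        super().__init__(", ".join(missing))
        self.missing = missing


def _norm(name: str) -> str:
    return re.sub(r"[^0-9a-z+]+", "", name.lower())


@dataclass(frozen=True)
class PublishedModel:
    name: str
    terms: tuple[tuple[str, float], ...]  # ordered (descriptor, coefficient)
    intercept: float

    @property
    def required_descriptors(self) -> list[str]:
        return [t for t, _ in self.terms]

    def to_dict(self) -> dict:
        return {
            "kind": "published_mlr",
            "name": self.name,
            "terms": [[t, c] for t, c in self.terms],
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PublishedModel":
        return cls(
            name=payload["name"],
            terms=tuple((t, float(c)) for t, c in payload["terms"]),
            intercept=float(payload["intercept"]),
        )


_SET1_TERMS = (
    ("R3v+", -16.8),
    ("R2p+", 8.5),
    ("nC=O(O)2", -2.7),
    ("nNq", -1.5),
    ("nROCON", -1.1),
    ("nSH", -0.7),
    ("MATS7p", -0.2),
    ("T(O..P)", -0.1),
    ("O-056", -0.1),
    ("G(N..Br)", -0.04),
    ("RDF130m", -0.02),
)

_SET2_TERMS = (
    ("G2e", -2.3),
    ("R1e", -1.4),
    ("Mor27v", 0.8),
    ("nCONN", -0.8),
    ("Mor25e", 0.5),
    ("nRCOOR", -0.3),
    ("Mor30u", -0.4),
    ("C-039", 0.3),
    ("MAXDN", 0.2),
    ("Mor06e", 0.1),
    ("Mor04e", -0.1),
)

PUBLISHED_MODELS: dict[str, PublishedModel] = {
    "set1_eq6": PublishedModel("set1_eq6", _SET1_TERMS, 1.9),
    "set2_eq7": PublishedModel("set2_eq7", _SET2_TERMS, 4.6),
}


def get_published_model(name: str) -> PublishedModel:
    try:
        return PUBLISHED_MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown published model {name!r}; choose from {sorted(PUBLISHED_MODELS)}"
        ) from None


def predict_published(model: PublishedModel, descriptors: Mapping[str, float]) -> float:
    """Evaluate a published equation: intercept + sum(coef * descriptor).

    Descriptor lookup is punctuation- and case-insensitive; all missing
    names are reported together; extra descriptors are ignored with a
    notice.
    """
    supplied = {_norm(k): float(v) for k, v in descriptors.items()}
    missing = [t for t, _ in model.terms if _norm(t) not in supplied]
    if missing:
        raise MissingDescriptorError(missing)
    needed = {_norm(t) for t, _ in model.terms}
    extra = [k for k in descriptors if _norm(k) not in needed]
    if extra:
        warnings.warn(f"ignoring {len(extra)} extra descriptor(s): {extra}", stacklevel=2)
    return model.intercept + sum(c * supplied[_norm(t)] for t, c in model.terms)


def predict_ob_percent(
    model: PublishedModel, descriptors: Mapping[str, float]
) -> tuple[float, bool]:
    """Predicted %F = 10**logB, clipped into (0, 100].

    Returns ``(percent, clipped)`` where ``clipped`` flags a prediction
    above 100 % that was truncated to the physical range.
    """
    logb = predict_published(model, descriptors)
    percent = 10.0**logb
    if percent > 100.0:
        return 100.0, True
    return percent, False
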