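"""Goodness-of-fit statistics and the pairwise F-test model comparison.

Conventions used throughout the reports:

* R² / Q²ex — squared Pearson correlation between observed and predicted
  logB on the training / test set.
* SEE — training standard error of estimation,
  ``sqrt(RSS / (n - n_params - 1))``.
* SEP — test standard error of prediction, the plain RMSE
  ``sqrt(RSS / n)`` (no degrees-of-freedom correction).
* F comparison — the ratio of two models' squared SEPs on their test
  sets, judged against the upper-tail F quantile at alpha with
  ``(n_a - 1, n_b - 1)`` degrees of freedom.  Because the ratio may be
  quoted in either orientation, significance uses ``max(F, 1/F)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FComparison",
    "r_squared",
    "predictive_r_squared",
    "see",
    "sep",
    "f_compare",
]


@dataclass
class FComparison:
    model_a: str
    model_b: str
    sep_a: float
    sep_b: float
    n_a: int
    n_b: int
    f_value: float
    f_critical: float
    significant: bool


def r_squared(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_obs) != len(y_pred) or len(y_obs) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.std(y_obs) == 0 or np.std(y_pred) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)


def predictive_r_squared(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """1 - PRESS/TSS: penalises bias and scale error, unlike the Pearson form.

    Provided as an alternative; the pipeline's reports use :func:`r_squared`.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    tss = float(((y_obs - y_obs.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("zero variance in observations")
    return 1.0 - float(((y_obs - y_pred) ** 2).sum()) / tss


def see(y_obs: np.ndarray, y_pred: np.ndarray, n_params: int) -> float:
    """Training standard error of estimation, df-corrected for model size."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = len(y_obs)
    df = n - n_params - 1
    if df <= 0:
        raise ValueError(f"insufficient degrees of freedom: n={n}, n_params={n_params}")
    return float(np.sqrt(((y_obs - y_pred) ** 2).sum() / df))


def sep(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Test standard error of prediction (RMSE, no df correction)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_obs) == 0:
        raise ValueError("empty test set")
    return float(np.sqrt(((y_obs - y_pred) ** 2).mean()))


def f_compare(
    model_a: tuple[str, float, int],
    model_b: tuple[str, float, int],
    alpha: float = 0.05,
) -> FComparison:
    """Compare two models' test errors by the ratio of squared SEPs.

    Each argument is ``(label, sep, n_test)``.  The numerator is the
    first-named model, so the returned f_value may be below 1; the
    significance decision uses ``max(F, 1/F)`` against the critical value.
    """
    name_a, sep_a, n_a = model_a
    name_b, sep_b, n_b = model_b
    if sep_a <= 0 or sep_b <= 0:
        raise ValueError("SEPs must be positive for an F comparison")
    f_value = sep_a**2 / sep_b**2
    f_critical = float(stats.f.ppf(1.0 - alpha, n_a - 1, n_b - 1))
    return FComparison(
        model_a=name_a,
        model_b=name_b,
        sep_a=sep_a,
        sep_b=sep_b,
        n_a=n_a,
        n_b=n_b,
        f_value=float(f_value),
        f_critical=f_critical,
        significant=bool(max(f_value, 1.0 / f_value) > f_critical),
    )
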