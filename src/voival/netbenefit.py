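"""Net-benefit estimators, decision curves, and population-scale interpretation.

At a risk threshold ``z`` the net benefit (NB) of a classification strategy,
in net true-positive units per decision, is

    NB = P(TruePositive) - P(FalsePositive) * z / (1 - z).

The weight ``z/(1-z)`` is the relative cost of a false-positive against a
true-positive classification; its reciprocal is the exchange rate (how many
avoided false positives are worth one true positive). The model strategy
treats subjects with predicted risk at or above ``z``; the two default
strategies are treat-all and treat-none (NB identically zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .data_io import ValidationSample


def _check_threshold(z: float) -> float:
    z = float(z)
    if not (0.0 <= z < 1.0):
        raise ValueError(f"risk threshold must satisfy 0 <= z < 1, got {z!r} "
                         "(at z = 1 the false-positive weight z/(1-z) is undefined)")
    return z


def weight(z: float) -> float:
    """False-positive weight z/(1-z); its reciprocal is the FP-per-TP exchange rate."""
    z = _check_threshold(z)
    return z / (1.0 - z)


def _contributions(s: ValidationSample, z: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject NB contributions for the model and treat-all strategies.

    Ties pi_i == z are classified positive (the indicator is ``>=``).
    """
    w = weight(z)
    treat_all = s.y - (1.0 - s.y) * w
    model = np.where(s.pi >= z, treat_all, 0.0)
    return model, treat_all


def nb_model_hat(s: ValidationSample, z: float) -> float:
    """Sample NB of the model strategy: mean of I(pi_i >= z) {y_i - (1-y_i) z/(1-z)}."""
    model, _ = _contributions(s, z)
    return float(model.mean())


def nb_all_hat(s: ValidationSample, z: float) -> float:
    """Sample NB of treat-all: mean of {y_i - (1-y_i) z/(1-z)} = p - (1-p) z/(1-z)."""
    _, treat_all = _contributions(s, z)
    return float(treat_all.mean())


def dnb_hat(s: ValidationSample, z: float) -> float:
    """Incremental NB of the model over the better default: NB_model - max(0, NB_all).

    The model is recommended iff the result is positive.
    """
    return nb_model_hat(s, z) - max(0.0, nb_all_hat(s, z))


@dataclass(frozen=True)
class DecisionCurve:
    """Per-threshold NB of the model, treat-all, and treat-none strategies."""

    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    n: int

    def __post_init__(self) -> None:
        for name in ("thresholds", "nb_model", "nb_all", "nb_none"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        k = self.thresholds.size
        if not (self.nb_model.size == self.nb_all.size == self.nb_none.size == k):
            raise ValueError("decision-curve columns must have equal length")
        if np.any(self.nb_none != 0.0):
            raise ValueError("treat-none NB must be identically zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "nb_model": self.nb_model,
            "nb_all": self.nb_all,
            "nb_none": self.nb_none,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.to_frame().to_json(path, orient="records", indent=2)


def _check_grid(grid: Sequence[float]) -> np.ndarray:
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be nonempty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing with no duplicates")
    for z in grid:
        _check_threshold(z)
    return grid


def decision_curve(s: ValidationSample, grid: Sequence[float]) -> DecisionCurve:
    """Evaluate the two NB estimators over a strictly increasing threshold grid."""
    grid = _check_grid(grid)
    nb_m = np.array([nb_model_hat(s, z) for z in grid])
    nb_a = np.array([nb_all_hat(s, z) for z in grid])
    return DecisionCurve(thresholds=grid, nb_model=nb_m, nb_all=nb_a,
                         nb_none=np.zeros_like(grid), n=s.n)


class PopulationImpact(NamedTuple):
    tp_equivalent: float
    fp_equivalent: float


def scale_to_population(value_nb: float, z: float, n_decisions: float) -> PopulationImpact:
    """Express an NB-unit quantity as true-positive / false-positive equivalents.

    Over ``n_decisions`` treatment decisions, a quantity of ``value_nb`` NB
    units equals ``value_nb * n_decisions`` extra true positives, or — holding
    true positives fixed — ``value_nb * n_decisions * (1-z)/z`` avoided false
    positives. Linear in both ``value_nb`` and ``n_decisions``.
    """
    z = _check_threshold(z)
    if n_decisions <= 0:
        raise ValueError("n_decisions must be positive")
    if z == 0.0:
        raise ValueError("false-positive equivalent is undefined at z = 0 "
                         "(the exchange rate (1-z)/z diverges)")
    tp = value_nb * n_decisions
    fp = tp * (1.0 - z) / z
    return PopulationImpact(tp_equivalent=tp, fp_equivalent=fp)
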