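"""Ordinary and Bayesian bootstrap machinery for net-benefit posterior draws.

Both bootstrap flavours are implemented as random observation weights on the
per-subject NB contributions, sharing a single code path:

* ``ordinary``  — weights are multinomial(n, uniform)/n counts, the classic
  resampling-with-replacement bootstrap;
* ``bayesian``  — weights are a flat Dirichlet(1, ..., 1) draw (generated as
  normalized unit-rate exponentials), so each weighted statistic is a draw
  from the posterior of the population quantity under a noninformative prior.

Seed contract: one user seed drives a ``numpy`` SeedSequence; bootstrap
iteration ``b`` always uses child stream ``b`` of that sequence, so iteration
``b`` is reproducible in isolation and occupies the same stream position
under either weighting scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ValidationSample
from .netbenefit import _check_grid, _check_threshold, _contributions

SCHEMES = ("ordinary", "bayesian")


def _check_scheme(scheme: str) -> str:
    if scheme not in SCHEMES:
        raise ValueError(f"unknown resampling scheme {scheme!r}; expected one of {SCHEMES}")
    return scheme


def draw_weights(n: int, scheme: str, rng: np.random.Generator) -> np.ndarray:
    """One random weight vector on the n-simplex (sums to 1, nonnegative)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    _check_scheme(scheme)
    if scheme == "ordinary":
        counts = rng.multinomial(n, np.full(n, 1.0 / n))
        return counts / n
    e = rng.standard_exponential(n)
    return e / e.sum()


def _weight_matrix(n: int, B: int, scheme: str, seed) -> np.ndarray:
    """B weight vectors, row b drawn from child stream b of the seed sequence."""
    children = np.random.SeedSequence(seed).spawn(B)
    out = np.empty((B, n))
    for b, child in enumerate(children):
        out[b] = draw_weights(n, scheme, np.random.default_rng(child))
    return out


def weighted_nb(s: ValidationSample, w: np.ndarray, z: float) -> tuple[float, float]:
    """Weighted NB estimators (model, treat-all) for one weight vector.

    With uniform weights this equals the unweighted sample estimators exactly.
    """
    w = np.asarray(w, dtype=float)
    if w.size != s.n:
        raise ValueError(f"weight vector length {w.size} != sample size {s.n}")
    a, b = _contributions(s, z)
    return float(w @ a), float(w @ b)


@dataclass(frozen=True)
class PosteriorDraws:
    """B paired draws of (NB_model, NB_all) at one threshold.

    Under the Bayesian scheme the rows are draws from the joint posterior of
    the true net benefits given the validation sample; under the ordinary
    scheme they are conventional bootstrap replicates, commonly given the
    same interpretation.
    """

    z: float
    nb_model: np.ndarray
    nb_all: np.ndarray
    scheme: str
    seed: object = None

    def __post_init__(self) -> None:
        nb_m = np.asarray(self.nb_model, dtype=float)
        nb_a = np.asarray(self.nb_all, dtype=float)
        if nb_m.size != nb_a.size or nb_m.size < 1:
            raise ValueError("nb_model and nb_all must have equal length B >= 1")
        _check_scheme(self.scheme)
        object.__setattr__(self, "nb_model", nb_m)
        object.__setattr__(self, "nb_all", nb_a)

    @property
    def B(self) -> int:
        return int(self.nb_model.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(1, self.B + 1),
            "nb_model": self.nb_model,
            "nb_all": self.nb_all,
        })


def posterior_draws(
    s: ValidationSample,
    z: float,
    B: int = 10_000,
    scheme: str = "bayesian",
    seed=None,
) -> PosteriorDraws:
    """B bootstrap draws of (NB_model, NB_all) at a single threshold."""
    (d,) = posterior_draws_grid(s, [z], B=B, scheme=scheme, seed=seed)
    return d


def posterior_draws_grid(
    s: ValidationSample,
    grid: Sequence[float],
    B: int = 10_000,
    scheme: str = "bayesian",
    seed=None,
    share_weights: bool = True,
) -> list[PosteriorDraws]:
    """Draws at every threshold of a grid.

    By default the same weight draw ``b`` is reused across all thresholds
    within iteration ``b`` (one bootstrap sample, NBs computed at every
    threshold of interest), preserving cross-threshold correlation.
    ``share_weights=False`` draws fresh weights per threshold instead.
    """
    grid = _check_grid(grid)
    if B < 1:
        raise ValueError("B must be at least 1")
    _check_scheme(scheme)
    results = []
    if share_weights:
        W = _weight_matrix(s.n, B, scheme, seed)
        for z in grid:
            a, b = _contributions(s, z)
            results.append(PosteriorDraws(z=float(z), nb_model=W @ a, nb_all=W @ b,
                                          scheme=scheme, seed=seed))
    else:
        ss = np.random.SeedSequence(seed)
        for z, child in zip(grid, ss.spawn(len(grid))):
            W = _weight_matrix(s.n, B, scheme, child)
            a, b = _contributions(s, z)
            results.append(PosteriorDraws(z=float(z), nb_model=W @ a, nb_all=W @ b,
                                          scheme=scheme, seed=seed))
    return results


def percentile_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval via linear-interpolation quantiles."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot form a percentile interval from an empty vector")
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must lie strictly in (0, 1), got {level!r}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def decision_curve_ci(
    s: ValidationSample,
    grid: Sequence[float],
    B: int = 10_000,
    scheme: str = "bayesian",
    seed=None,
    level: float = 0.95,
    share_weights: bool = True,
) -> pd.DataFrame:
    """Pointwise percentile bands for the model and treat-all decision curves."""
    draws = posterior_draws_grid(s, grid, B=B, scheme=scheme, seed=seed,
                                 share_weights=share_weights)
    rows = []
    for d in draws:
        m_lo, m_hi = percentile_ci(d.nb_model, level)
        a_lo, a_hi = percentile_ci(d.nb_all, level)
        rows.append({"threshold": d.z,
                     "nb_model_lo": m_lo, "nb_model_hi": m_hi,
                     "nb_all_lo": a_lo, "nb_all_hi": a_hi})
    return pd.DataFrame(rows)
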