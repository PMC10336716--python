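"""Synthetic validation samples and ground truths for EVPI experiments.

The data-generating mechanism is a single standard-normal predictor X with

    logit P(Y = 1 | X) = a + b X,

the defaults a = -1.55, b = 0.77 giving an outcome prevalence of 20% and a
correct-model c-statistic of 0.70 — values typical of validation studies.
The candidate model under evaluation predicts with a possibly perturbed
linear predictor a + shift + b X + eps, eps ~ Normal(0, noise_sd):
``miscalibration_shift`` degrades calibration (outcome generation is
unchanged), ``discrimination_noise_sd`` degrades discrimination. With both
perturbations at zero the candidate coincides with the correct model.

Ground-truth prevalence, c-statistic and net benefit are computed by
adaptive quadrature against the normal covariate density, so simulation
output can be checked against exact population values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import expit, logit
from scipy.stats import norm

from .data_io import ValidationSample
from .netbenefit import _check_threshold, weight
from .voi_asymptotic import evpi_asymptotic
from .voi_bootstrap import DegenerateSampleWarning, evpi_bootstrap

_QUAD = dict(epsabs=1e-12, epsrel=1e-12, limit=200)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated validation scenario."""

    intercept: float = -1.55
    slope: float = 0.77
    n: int = 500
    thresholds: tuple[float, ...] = (0.1, 0.2, 0.3)
    reps: int = 200
    B: int = 1_000
    seed: int = 0
    miscalibration_shift: float = 0.0
    discrimination_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.reps < 1:
            raise ValueError("reps must be at least 1")
        if self.discrimination_noise_sd < 0:
            raise ValueError("discrimination_noise_sd must be nonnegative")
        object.__setattr__(self, "thresholds",
                           tuple(float(z) for z in self.thresholds))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        d["thresholds"] = tuple(d.get("thresholds", (0.1, 0.2, 0.3)))
        return cls(**d)


def generate_sample(c: SimConfig, rep_index: int = 0) -> ValidationSample:
    """One simulated validation sample, reproducible given (seed, rep_index).

    Each replicate uses its own child of the configured seed, so replicates
    are mutually independent and individually re-creatable.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=c.seed, spawn_key=(int(rep_index),)))
    x = rng.standard_normal(c.n)
    p_true = expit(c.intercept + c.slope * x)
    y = rng.binomial(1, p_true)
    lp = c.intercept + c.miscalibration_shift + c.slope * x
    if c.discrimination_noise_sd > 0:
        lp = lp + rng.normal(0.0, c.discrimination_noise_sd, size=c.n)
    return ValidationSample(y=y, pi=expit(lp))


# --- population ground truths -------------------------------------------------


def true_prevalence(a: float, b: float) -> float:
    """P(Y = 1) = integral of inverse-logit(a + b x) against the N(0,1) density."""
    if b == 0.0:
        return float(expit(a))
    val, _ = quad(lambda x: expit(a + b * x) * norm.pdf(x), -np.inf, np.inf, **_QUAD)
    return float(val)


def true_cstat(a: float, b: float) -> float:
    """P(pi(X1) > pi(X2) | Y1 = 1, Y2 = 0) for the correct model, by quadrature.

    Evaluated as E[p(X1)(1 - p(X2)) 1(X1 > X2)] / (P0 (1 - P0)) when b > 0,
    with the inner conditional integral nested inside the outer one; the
    b < 0 case follows from the sign-flip symmetry c(a, -b) = 1 - c(a, b).
    """
    if b == 0.0:
        return 0.5
    if b < 0.0:
        return 1.0 - true_cstat(a, -b)
    p0 = true_prevalence(a, b)

    def inner(x1: float) -> float:
        val, _ = quad(lambda t: (1.0 - expit(a + b * t)) * norm.pdf(t),
                      -np.inf, x1, epsabs=1e-11, epsrel=1e-11, limit=200)
        return val

    num, _ = quad(lambda x: expit(a + b * x) * inner(x) * norm.pdf(x),
                  -np.inf, np.inf, epsabs=1e-10, epsrel=1e-10, limit=200)
    return float(num / (p0 * (1.0 - p0)))


def true_nb(a: float, b: float, z: float) -> float:
    """Population NB of the correct model at threshold z, by quadrature.

    E[1(p(X) >= z) (p(X) - (1 - p(X)) z/(1-z))]; since p is monotone in x
    for b != 0, the positive-classification set is a half-line and the
    integral is taken over it directly.
    """
    z = _check_threshold(z)
    w = weight(z)
    if b == 0.0:
        p = float(expit(a))
        return p - (1.0 - p) * w if p >= z else 0.0
    if z == 0.0:
        return true_prevalence(a, b)

    def f(x: float) -> float:
        p = expit(a + b * x)
        return (p - (1.0 - p) * w) * norm.pdf(x)

    x_star = (logit(z) - a) / b
    if b > 0:
        val, _ = quad(f, x_star, np.inf, **_QUAD)
    else:
        val, _ = quad(f, -np.inf, x_star, **_QUAD)
    return float(val)


# --- EVPI experiments ---------------------------------------------------------

_METHODS = ("ordinary", "bayesian", "asymptotic")


def _evpi_one(sample: ValidationSample, z: float, method: str, B: int, seed) -> float:
    if method == "asymptotic":
        return evpi_asymptotic(sample, z).evpi
    return evpi_bootstrap(sample, z, B=B, scheme=method, seed=seed).evpi


def evpi_vs_n_experiment(
    c: SimConfig,
    n_grid: Sequence[int],
    methods: Sequence[str] = ("bayesian", "asymptotic"),
) -> pd.DataFrame:
    """Mean EVPI (with Monte Carlo SE) per sample size, threshold and method.

    For each n in ``n_grid``, ``c.reps`` validation samples are generated
    from the configured mechanism and the EVPI of each method is averaged
    across replicates. Bootstrap methods use ``c.B`` draws per replicate.
    Deterministic given ``c.seed``. Degenerate-sample warnings (expected at
    extreme thresholds in small replicates) are suppressed inside the loop.
    """
    for m in methods:
        if m not in _METHODS:
            raise ValueError(f"unknown method {m!r}; expected subset of {_METHODS}")
    if c.reps < 2:
        raise ValueError("at least 2 replicates are needed for a Monte Carlo SE")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateSampleWarning)
        for i_n, n in enumerate(n_grid):
            cfg = replace(c, n=int(n))
            acc: dict[tuple[float, str], list[float]] = {
                (z, m): [] for z in c.thresholds for m in methods}
            for r in range(c.reps):
                rep_index = i_n * c.reps + r
                sample = generate_sample(cfg, rep_index=rep_index)
                boot_seed = int(np.random.SeedSequence(
                    entropy=c.seed, spawn_key=(rep_index, 1)
                ).generate_state(1)[0] & 0x7FFFFFFF)
                for method in methods:
                    for z in c.thresholds:
                        acc[(z, method)].append(
                            _evpi_one(sample, z, method, cfg.B, boot_seed))
            for (z, method), vals in acc.items():
                vals = np.asarray(vals)
                rows.append({"n": int(n), "threshold": z, "method": method,
                             "mean_evpi": float(vals.mean()),
                             "mc_se": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                             "reps": int(vals.size), "seed": c.seed})
    return pd.DataFrame(rows)


def subsample_evpi_experiment(
    sample: ValidationSample,
    n_grid: Sequence[int],
    thresholds: Sequence[float],
    methods: Sequence[str] = ("bayesian", "asymptotic"),
    reps: int = 200,
    B: int = 1_000,
    seed: int = 0,
) -> pd.DataFrame:
    """EVPI versus subsample size for a user-supplied validation sample.

    Repeatedly draws without replacement from ``sample`` at each size in
    ``n_grid`` (a doubling grid mimics diminishing returns of larger
    validation sets) and averages the EVPI per method and threshold.
    """
    for m in methods:
        if m not in _METHODS:
            raise ValueError(f"unknown method {m!r}; expected subset of {_METHODS}")
    rows = []
    ss = np.random.SeedSequence(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateSampleWarning)
        for i_n, n_sub in enumerate(n_grid):
            n_sub = int(n_sub)
            if n_sub > sample.n:
                raise ValueError(f"subsample size {n_sub} exceeds sample size {sample.n}")
            acc: dict[tuple[float, str], list[float]] = {
                (float(z), m): [] for z in thresholds for m in methods}
            for r in range(reps):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(i_n, r)))
                idx = rng.choice(sample.n, size=n_sub, replace=False)
                sub = ValidationSample(y=sample.y[idx], pi=sample.pi[idx])
                boot_seed = int(np.random.SeedSequence(
                    entropy=seed, spawn_key=(i_n, r, 1)
                ).generate_state(1)[0] & 0x7FFFFFFF)
                for method in methods:
                    for z in thresholds:
                        acc[(float(z), method)].append(
                            _evpi_one(sub, float(z), method, B, boot_seed))
            for (z, method), vals in acc.items():
                vals = np.asarray(vals)
                rows.append({"n": n_sub, "threshold": z, "method": method,
                             "mean_evpi": float(vals.mean()),
                             "mc_se": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                             "reps": int(vals.size), "seed": seed})
    return pd.DataFrame(rows)
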