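"""Core data containers and I/O for validation samples and logistic risk models.

The unit of analysis is a :class:`ValidationSample`: paired binary outcomes
``y`` and predicted risks ``pi`` for ``n`` subjects drawn from the target
population in which a previously developed prediction model is being
externally validated. Predicted risks may be supplied directly (two-column
CSV) or computed by applying a :class:`LogisticModel` — a frozen set of
logistic-regression coefficients — to a covariate table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Union

import numpy as np
import pandas as pd
from scipy.special import expit


class MissingColumnError(KeyError):
    """A required column is absent from the input table."""


class NonBinaryOutcomeError(ValueError):
    """An outcome value other than 0 or 1 was encountered."""


class RiskOutOfRangeError(ValueError):
    """A predicted risk outside [0, 1] was encountered."""


class EmptySampleError(ValueError):
    """The input contains no observations."""


@dataclass(frozen=True)
class ValidationSample:
    """Paired binary outcomes and predicted risks for ``n`` subjects.

    Parameters
    ----------
    y
        Binary outcomes, each exactly 0 or 1.
    pi
        Predicted risks in ``[0, 1]``. Risks of exactly 0 or 1 are accepted:
        they arise from degenerate models and leave all net-benefit formulas
        well defined.
    """

    y: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float).ravel()
        pi = np.asarray(self.pi, dtype=float).ravel()
        if y.size == 0 or pi.size == 0:
            raise EmptySampleError("validation sample must contain at least one subject")
        if y.size != pi.size:
            raise ValueError(f"length mismatch: {y.size} outcomes vs {pi.size} risks")
        if not np.all(np.isin(y, (0.0, 1.0))):
            bad = y[~np.isin(y, (0.0, 1.0))][0]
            raise NonBinaryOutcomeError(f"outcome values must be 0 or 1, got {bad!r}")
        if not np.all((pi >= 0.0) & (pi <= 1.0)):
            bad = pi[~((pi >= 0.0) & (pi <= 1.0))][0]
            raise RiskOutOfRangeError(f"predicted risks must lie in [0, 1], got {bad!r}")
        y.setflags(write=False)
        pi.setflags(write=False)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "pi", pi)

    @property
    def n(self) -> int:
        return int(self.y.size)

    @property
    def prevalence(self) -> float:
        """Sample outcome prevalence."""
        return float(self.y.mean())

    def to_frame(self, outcome_col: str = "y", risk_col: str = "pi") -> pd.DataFrame:
        return pd.DataFrame({outcome_col: self.y.astype(int), risk_col: self.pi})


def read_sample(
    path,
    outcome_col: str = "y",
    risk_col: str = "pi",
) -> ValidationSample:
    """Read a validation sample from a two-column CSV.

    The CSV dialect is comma-separated, header required, UTF-8, '.' decimal.
    Row order is preserved.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptySampleError(f"{path}: file is empty") from exc
    for col in (outcome_col, risk_col):
        if col not in frame.columns:
            raise MissingColumnError(f"{path}: column {col!r} not found "
                                     f"(available: {list(frame.columns)})")
    if len(frame) == 0:
        raise EmptySampleError(f"{path}: no data rows")
    return ValidationSample(y=frame[outcome_col].to_numpy(),
                            pi=frame[risk_col].to_numpy())


def write_sample(
    sample: ValidationSample,
    path,
    outcome_col: str = "y",
    risk_col: str = "pi",
) -> None:
    """Write a validation sample to CSV; round-trips through :func:`read_sample`."""
    sample.to_frame(outcome_col, risk_col).to_csv(path, index=False)


# --- logistic coefficient sets -------------------------------------------------

@dataclass(frozen=True)
class MinCap:
    """Transform x -> min(x, cap), e.g. capping systolic blood pressure at 100."""

    cap: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.minimum(x, self.cap)


@dataclass(frozen=True)
class Identity:
    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)


IDENTITY = Identity()

Transform = Union[Identity, MinCap]


@dataclass(frozen=True)
class ModelTerm:
    name: str
    coefficient: float
    transform: Transform = IDENTITY


@dataclass(frozen=True)
class LogisticModel:
    """A frozen logistic risk model: logit(pi) = intercept + sum coef * transform(x)."""

    intercept: float
    terms: tuple[ModelTerm, ...]
    name: str = ""

    def __post_init__(self) -> None:
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate term names in model: {names}")

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(covariates), float(self.intercept))
        for term in self.terms:
            if term.name not in covariates.columns:
                raise MissingColumnError(
                    f"covariate column {term.name!r} required by the model is missing")
            x = covariates[term.name].to_numpy(dtype=float)
            lp = lp + term.coefficient * term.transform(x)
        return lp

    def predict_risk(self, covariates: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(covariates))

    # JSON round-trip --------------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        terms = []
        for t in d["terms"]:
            tr = t.get("transform", "identity")
            if tr == "identity":
                transform: Transform = IDENTITY
            elif isinstance(tr, dict) and tr.get("type") == "min_cap":
                transform = MinCap(cap=float(tr["cap"]))
            else:
                raise ValueError(f"unknown transform spec: {tr!r}")
            terms.append(ModelTerm(name=t["name"],
                                   coefficient=float(t["coefficient"]),
                                   transform=transform))
        return cls(intercept=float(d["intercept"]), terms=tuple(terms),
                   name=d.get("name", ""))

    def to_dict(self) -> dict:
        terms = []
        for t in self.terms:
            if isinstance(t.transform, MinCap):
                tr: object = {"type": "min_cap", "cap": t.transform.cap}
            else:
                tr = "identity"
            terms.append({"name": t.name, "coefficient": t.coefficient,
                          "transform": tr})
        return {"name": self.name, "intercept": self.intercept, "terms": terms}

    @classmethod
    def from_json(cls, path) -> "LogisticModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def apply_logistic_model(model: LogisticModel, covariates: pd.DataFrame) -> np.ndarray:
    """Predicted risks from a coefficient set applied to a covariate table.

    risk_i = inverse-logit(intercept + sum_j coef_j * transform_j(x_ij));
    every output lies strictly in (0, 1) for finite inputs.
    """
    return model.predict_risk(covariates)


def load_gusto_model() -> LogisticModel:
    """The packaged post-AMI 30-day mortality logistic model (GUSTO-I, non-US fit).

    Coefficients are as published; covariate coding follows the printed
    equation (indicator variables for infarct location and history, Killip
    score as a numeric input, blood pressure entering as min(bp, 100)) and
    has not been re-derived from patient data.
    """
    ref = resources.files("voival").joinpath("fixtures/gusto_mortality.json")
    with ref.open(encoding="utf-8") as fh:
        return LogisticModel.from_dict(json.load(fh))
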