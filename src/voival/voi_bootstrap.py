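"""Bootstrap-based expected value of perfect information for model validation.

Three strategies compete at a threshold ``z``: use the model, treat all,
treat none (NB = 0). With posterior draws (NB_model_b, NB_all_b), b = 1..B:

* expected NB under current information
      ENB_current = max(0, mean_b NB_model_b, mean_b NB_all_b);
* expected NB under perfect information (average NB of the per-draw winner)
      ENB_perfect = mean_b max(0, NB_model_b, NB_all_b);
* EVPI = ENB_perfect - ENB_current, the expected NB lost per decision
  because the truly best strategy is not known with certainty.

Because the current-information term uses the means of the *same* draws,
Jensen's inequality makes the EVPI nonnegative by construction.
``p_useful`` is the posterior probability that the model strategy has the
highest true NB (ties count against the model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import ValidationSample
from .netbenefit import nb_all_hat, nb_model_hat
from .resampling import PosteriorDraws, posterior_draws_grid


class DegenerateSampleWarning(UserWarning):
    """The incremental-NB draws show no sampling variation.

    Typical at extreme thresholds in small samples (e.g. no events below the
    threshold): EVPI is 0 and p_useful is 0 or 1, but such certainty reflects
    a degenerate sample rather than genuine evidence, and the suitability of
    the sample should be reconsidered.
    """


@dataclass(frozen=True)
class VoIResult:
    """Value-of-information summary at one threshold."""

    z: float
    evpi: float
    r_evpi: Optional[float]
    p_useful: float
    enb_current: float
    enb_perfect: float
    winner: str
    B: Optional[int]
    method: str

    def to_dict(self) -> dict:
        return {"threshold": self.z, "evpi": self.evpi, "r_evpi": self.r_evpi,
                "p_useful": self.p_useful, "enb_current": self.enb_current,
                "enb_perfect": self.enb_perfect, "winner": self.winner,
                "B": self.B, "method": self.method}


def results_to_frame(results: Sequence[VoIResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def _winner(enb_model: float, enb_all: float) -> str:
    """Strategy with the highest expected NB; ties resolved against the model
    (and in favour of treat-none), consistent with the strict inequality in
    p_useful."""
    best, who = 0.0, "none"
    if enb_all > best:
        best, who = enb_all, "all"
    if enb_model > best:
        who = "model"
    return who


def relative_evpi_terms(enb_perfect: float, enb_model: float, enb_all: float) -> Optional[float]:
    """Relative EVPI from the three expected-NB terms.

    rEVPI = (ENB_perfect - max(0, E NB_all)) / (max(0, E NB_model, E NB_all)
    - max(0, E NB_all)): the expected gain over the next-best default with
    perfect information, relative to the model's gain with current
    information. Defined only when the model is the current winner and the
    denominator is positive; returns None otherwise.
    """
    if _winner(enb_model, enb_all) != "model":
        return None
    baseline = max(0.0, enb_all)
    denom = max(0.0, enb_model, enb_all) - baseline
    if denom <= 0.0:
        return None
    return (enb_perfect - baseline) / denom


def p_useful(d: PosteriorDraws) -> float:
    """Posterior probability the model strategy has the highest true NB.

    Fraction of draws with NB_model_b strictly greater than max(0, NB_all_b).
    """
    return float(np.mean(d.nb_model > np.maximum(0.0, d.nb_all)))


def _check_degenerate(d: PosteriorDraws) -> None:
    dnb = d.nb_model - np.maximum(0.0, d.nb_all)
    if np.ptp(dnb) == 0.0:
        warnings.warn(
            "incremental-NB draws have zero variance; EVPI 0 and a 0/1 "
            "p_useful here reflect a degenerate sample at this threshold, "
            "not strong evidence", DegenerateSampleWarning, stacklevel=3)


def evpi_from_draws(
    d: PosteriorDraws,
    enb_current_from: str = "draws",
    sample: Optional[ValidationSample] = None,
) -> VoIResult:
    """EVPI, relative EVPI and p_useful from posterior draws at one threshold.

    ``enb_current_from="draws"`` (default) estimates E(NB_model) and
    E(NB_all) by the bootstrap means, which keeps the EVPI nonnegative by
    construction and lets stochastic components of the prediction pipeline
    propagate. ``enb_current_from="sample"`` uses the original-sample
    estimators instead (``sample`` required); Monte Carlo noise can then
    produce small negative EVPIs, which are clamped to zero with a warning.
    """
    if enb_current_from not in ("draws", "sample"):
        raise ValueError("enb_current_from must be 'draws' or 'sample'")
    _check_degenerate(d)
    enb_perfect = float(np.mean(np.maximum(0.0, np.maximum(d.nb_model, d.nb_all))))
    if enb_current_from == "draws":
        e_model = float(d.nb_model.mean())
        e_all = float(d.nb_all.mean())
    else:
        if sample is None:
            raise ValueError("enb_current_from='sample' requires the original sample")
        e_model = nb_model_hat(sample, d.z)
        e_all = nb_all_hat(sample, d.z)
    enb_current = max(0.0, e_model, e_all)
    evpi = enb_perfect - enb_current
    if evpi < 0.0:
        if enb_current_from == "draws" and evpi < -1e-12:
            raise AssertionError(
                f"EVPI {evpi} violates the Jensen guarantee for draw-based means")
        if enb_current_from == "sample" and evpi < -1e-12:
            warnings.warn(f"negative EVPI {evpi:.3g} from Monte Carlo noise "
                          "clamped to 0", UserWarning, stacklevel=2)
        evpi = 0.0
    return VoIResult(
        z=d.z, evpi=evpi,
        r_evpi=relative_evpi_terms(enb_perfect, e_model, e_all),
        p_useful=p_useful(d),
        enb_current=enb_current, enb_perfect=enb_perfect,
        winner=_winner(e_model, e_all), B=d.B, method=d.scheme)


def relative_evpi(d: PosteriorDraws) -> Optional[float]:
    """Relative EVPI from draws; None when the model is not the current winner."""
    enb_perfect = float(np.mean(np.maximum(0.0, np.maximum(d.nb_model, d.nb_all))))
    return relative_evpi_terms(enb_perfect, float(d.nb_model.mean()),
                               float(d.nb_all.mean()))


def evpi_bootstrap(
    s: ValidationSample,
    z: float,
    B: int = 10_000,
    scheme: str = "bayesian",
    seed=None,
) -> VoIResult:
    """Bootstrap EVPI at a single threshold (draws + evpi_from_draws)."""
    (r,) = evpi_curve(s, [z], B=B, scheme=scheme, seed=seed)
    return r


def evpi_curve(
    s: ValidationSample,
    grid: Sequence[float],
    B: int = 10_000,
    scheme: str = "bayesian",
    seed=None,
    share_weights: bool = True,
) -> list[VoIResult]:
    """One VoIResult per threshold; weight draws are shared across thresholds."""
    draws = posterior_draws_grid(s, grid, B=B, scheme=scheme, seed=seed,
                                 share_weights=share_weights)
    return [evpi_from_draws(d) for d in draws]
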