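"""The four analysis methods: ITT, PP, 2SPS and 2SRI.

All four estimate a log hazard ratio from a Cox proportional-hazards fit of
the observed (time, event) outcome, and differ only in the covariate and the
rows used:

* **ITT** regresses on randomised allocation Z, all rows.
* **PP** drops intervention-arm refusers (Z=1, X=0) and regresses on
  treatment received X among the remainder.
* **2SPS** (two-stage predictor substitution) replaces the exposure by its
  first-stage fitted value ``X_hat = E(X | Z)`` and regresses on that.
* **2SRI** (two-stage residual inclusion) keeps the observed exposure X and
  adds the first-stage residual ``R = X - E(X | Z)`` as a second covariate;
  the coefficient of X is the treatment-effect estimate.

With randomisation as the instrument the first stage is saturated, so the
fitted values are simply the arm-wise means of X (a linear and a logistic
first stage coincide).  Standard errors are the model-based ones from the
second-stage fit, without a first-stage correction; simulation summaries use
the empirical spread across replicates instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coxph import CoxResult, DegenerateDesignError, coxph_fit
from .simulate import TrialData

__all__ = [
    "METHODS",
    "FitResult",
    "fit_ph",
    "first_stage",
    "estimate_itt",
    "estimate_pp",
    "estimate_2sps",
    "estimate_2sri",
    "analyze_trial",
]

logger = logging.getLogger(__name__)

METHODS = ("ITT", "PP", "2SPS", "2SRI")


class WeakInstrumentError(DegenerateDesignError):
    """Raised when the first stage carries no information (zero uptake)."""


@dataclass(frozen=True)
class FitResult:
    """One estimator's output on one trial."""

    method: str
    beta_hat: float
    se_hat: float
    p_value: float
    n_used: int


def fit_ph(time, event, covariates) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, Wald p-values).

    Thin public wrapper over the package's partial-likelihood Newton solver;
    accepts one or two covariate columns.
    """
    return coxph_fit(time, event, covariates)


def _as_result(method: str, fit: CoxResult, col: int = 0) -> FitResult:
    return FitResult(
        method=method,
        beta_hat=float(fit.coef[col]),
        se_hat=float(fit.se[col]),
        p_value=float(fit.p_value[col]),
        n_used=fit.n,
    )


def first_stage(z: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fitted values ``E(X | Z)`` and residuals ``X - E(X | Z)``.

    The instrument is binary, so the saturated first stage reduces to the
    arm-wise empirical means of X; residuals sum to zero within each arm.
    """
    z = np.asarray(z)
    x = np.asarray(x, dtype=float)
    if z.shape != x.shape:
        raise ValueError("z and x must have equal lengths")
    in_arm = z == 1
    if not in_arm.any() or in_arm.all():
        raise ValueError("both arms must be present for the first stage")
    fitted = np.where(in_arm, x[in_arm].mean(), x[~in_arm].mean())
    return fitted, x - fitted


def estimate_itt(trial: TrialData) -> FitResult:
    """Intention-to-treat: outcome on allocation Z, everyone analysed."""
    return _as_result("ITT", fit_ph(trial.y, trial.event, trial.z))


def estimate_pp(trial: TrialData) -> FitResult:
    """Per-protocol: drop intervention-arm refusers, fit on treatment received.

    After the exclusion X and Z coincide on the retained rows; X is used as
    the covariate.  The number of rows actually analysed is reported in
    ``n_used``.
    """
    keep = ~((trial.z == 1) & (trial.x == 0))
    x = trial.x[keep]
    if x.sum() == 0:
        raise DegenerateDesignError("no treated individuals left after exclusion")
    return _as_result("PP", fit_ph(trial.y[keep], trial.event[keep], x))


def estimate_2sps(trial: TrialData) -> FitResult:
    """Two-stage predictor substitution: outcome on first-stage fitted values.

    Because ``X_hat`` is an affine function of Z, the 2SPS coefficient equals
    the ITT coefficient divided by the intervention-arm uptake rate and the
    Wald p-values of the two methods coincide.
    """
    fitted, _ = first_stage(trial.z, trial.x)
    if np.ptp(fitted) == 0:
        raise WeakInstrumentError("first-stage fitted values are constant")
    return _as_result("2SPS", fit_ph(trial.y, trial.event, fitted))


def estimate_2sri(trial: TrialData) -> FitResult:
    """Two-stage residual inclusion: outcome on (X, first-stage residual R).

    The residual carries the information in the exposure that the instrument
    does not explain; including it alongside X corrects the naive exposure
    fit for refusal that is informative of risk.  Under perfect compliance R
    is identically zero: the column is dropped with a warning and the fit
    reduces to the single-covariate (= ITT) fit.
    """
    fitted, resid = first_stage(trial.z, trial.x)
    if np.ptp(resid) == 0:
        logger.warning(
            "first-stage residuals identically zero (perfect compliance); "
            "dropping the residual column"
        )
        return _as_result("2SRI", fit_ph(trial.y, trial.event, trial.x))
    fit = fit_ph(trial.y, trial.event, np.column_stack([trial.x, resid]))
    return _as_result("2SRI", fit, col=0)


_ESTIMATORS = {
    "ITT": estimate_itt,
    "PP": estimate_pp,
    "2SPS": estimate_2sps,
    "2SRI": estimate_2sri,
}


def analyze_trial(trial: TrialData, methods=METHODS) -> dict[str, FitResult]:
    """Run the requested estimators on one trial dataset.

    All methods see the *same* dataset, so differences between them reflect
    the methods and not simulation noise.
    """
    return {m: _ESTIMATORS[m](trial) for m in methods}
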