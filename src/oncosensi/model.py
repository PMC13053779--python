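"""The OncoSensi recurrence-risk index.

A logistic regression on Z-scored organoid growth rate, dose-response AUC
and (optionally) HPV status predicts 1-year recurrence after
radiotherapy; the OncoSensi index is the Z-scored linear predictor, so
that index > 0 reads as above-cohort-average recurrence risk
(radiation-resistant) and index < 0 as below-average
(radiation-sensitive).  The coefficients of the published two- and
three-parameter fits are packaged as fixed models; a ridge-stabilized
IRLS fitter re-estimates coefficients on new cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OncoSensiModel",
    "PUBLISHED_MODEL",
    "PUBLISHED_MODEL_HPV",
    "SeparationError",
    "fit_logistic",
    "fit_linear",
    "linear_predictor",
    "oncosensi_index",
    "classify",
    "classify_two_axis",
]


@dataclass(frozen=True)
class OncoSensiModel:
    """Coefficients over Z-scored features, in fixed order (growth, AUC[, HPV])."""

    beta0: float
    beta_growth: float
    beta_auc: float
    beta_hpv: "float | None" = None
    converged: bool = True
    ridge_penalty: float = 0.0

    @property
    def uses_hpv(self) -> bool:
        return self.beta_hpv is not None

    def coefficients(self) -> np.ndarray:
        coefs = [self.beta0, self.beta_growth, self.beta_auc]
        if self.uses_hpv:
            coefs.append(self.beta_hpv)
        return np.asarray(coefs, dtype=float)


#: Published two-parameter fit (growth + AUC) on the 14-patient test set.
PUBLISHED_MODEL = OncoSensiModel(beta0=-1.313, beta_growth=1.324, beta_auc=1.406)

#: Published three-parameter fit additionally carrying standardized HPV status
#: (HPV-positive is protective, hence the negative coefficient).
PUBLISHED_MODEL_HPV = OncoSensiModel(
    beta0=-1.739, beta_growth=2.483, beta_auc=2.411, beta_hpv=-0.5239
)


class SeparationError(RuntimeError):
    """Raised when unpenalized logistic fitting diverges (complete separation)."""


def _design(z_growth, z_auc, z_hpv=None) -> np.ndarray:
    cols = [np.ones_like(np.asarray(z_growth, dtype=float)),
            np.asarray(z_growth, dtype=float),
            np.asarray(z_auc, dtype=float)]
    if z_hpv is not None:
        cols.append(np.asarray(z_hpv, dtype=float))
    return np.column_stack(cols)


def fit_logistic(
    z_growth,
    z_auc,
    labels,
    z_hpv=None,
    ridge_penalty: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> OncoSensiModel:
    """Maximum-(penalized-)likelihood logistic fit via IRLS.

    ``labels`` are 0 (no recurrence) / 1 (recurrence).  The ridge penalty
    (not applied to the intercept) stabilizes small cohorts; with the
    default penalty of 0 a diverging fit -- the signature of complete
    separation -- raises :class:`SeparationError` suggesting a penalized
    refit.
    """
    y = np.asarray(labels, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if len(set(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = _design(z_growth, z_auc, z_hpv)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} observations for {p} coefficients")
    penalty = np.eye(p) * ridge_penalty
    penalty[0, 0] = 0.0

    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if np.max(np.abs(eta)) > 30 and ridge_penalty == 0:
            raise SeparationError(
                "logistic fit diverging (likely complete separation); "
                "retry with ridge_penalty > 0"
            )
        XtWX = X.T @ (X * w[:, None]) + penalty
        grad = X.T @ (y - mu) - penalty @ beta
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError as err:
            raise SeparationError(f"singular IRLS system: {err}") from err
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("IRLS did not reach tolerance; returning last iterate",
                      RuntimeWarning, stacklevel=2)
    return OncoSensiModel(
        beta0=float(beta[0]),
        beta_growth=float(beta[1]),
        beta_auc=float(beta[2]),
        beta_hpv=float(beta[3]) if z_hpv is not None else None,
        converged=converged,
        ridge_penalty=ridge_penalty,
    )


def fit_linear(z_growth, z_auc, labels, z_hpv=None) -> OncoSensiModel:
    """Ordinary-least-squares fit of the 0/1 outcome (comparison only).

    Provided because the source material labels the same coefficients both
    'logistic' and 'linear' regression; the logistic fit is primary.
    """
    y = np.asarray(labels, dtype=float)
    X = _design(z_growth, z_auc, z_hpv)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return OncoSensiModel(
        beta0=float(beta[0]),
        beta_growth=float(beta[1]),
        beta_auc=float(beta[2]),
        beta_hpv=float(beta[3]) if z_hpv is not None else None,
    )


def linear_predictor(model: OncoSensiModel, z_growth, z_auc, z_hpv=None):
    """beta0 + beta_growth*Zg + beta_auc*Za [+ beta_hpv*Zh]."""
    if model.uses_hpv and z_hpv is None:
        raise ValueError("model carries an HPV coefficient; z_hpv is required")
    lp = (model.beta0
          + model.beta_growth * np.asarray(z_growth, dtype=float)
          + model.beta_auc * np.asarray(z_auc, dtype=float))
    if model.uses_hpv:
        lp = lp + model.beta_hpv * np.asarray(z_hpv, dtype=float)
    return lp if np.ndim(lp) else float(lp)


def oncosensi_index(linear_predictors, reference: "tuple[float, float] | None" = None):
    """Z-score the linear predictor over the scored cohort.

    Returns ``(index, (mean, sd))``.  Pass a previously frozen
    ``reference=(mean, sd)`` to score an external cohort on the original
    scale.  Sample SD (n-1); constant predictors are an error.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    if reference is None:
        if lp.size < 2:
            raise ValueError("need at least two patients to standardize")
        mean, sd = float(lp.mean()), float(lp.std(ddof=1))
        if sd == 0:
            raise ValueError("constant linear predictors cannot be Z-scored")
    else:
        mean, sd = reference
    return (lp - mean) / sd, (mean, sd)


def classify(index, cutoff: float = 0.0):
    """index > cutoff -> 'resistant', else 'sensitive' (ties to sensitive)."""
    idx = np.asarray(index, dtype=float)
    labels = np.where(idx > cutoff, "resistant", "sensitive")
    return labels if idx.ndim else str(labels)


def classify_two_axis(z_auc, z_growth):
    """Quadrant call from the signs of (Z_AUC, Z_growth).

    Both positive -> 'strongly resistant'; both non-positive -> 'strongly
    sensitive'; mixed -> 'moderately resistant'.  A Z of exactly 0 counts
    as low.
    """
    za = np.asarray(z_auc, dtype=float)
    zg = np.asarray(z_growth, dtype=float)
    high_a, high_g = za > 0, zg > 0
    labels = np.where(
        high_a & high_g, "strongly resistant",
        np.where(~high_a & ~high_g, "strongly sensitive", "moderately resistant"),
    )
    return labels if za.ndim else str(labels)
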