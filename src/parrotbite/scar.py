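"""Power-law bite-force prediction from the adductor muscle scar.

The insertion of the m. adductor mandibulae externus complex leaves a visible
scar on the parrot mandible. Its length scales with bite force as a power law

    BF = c * scar_length^e,

which is fit as a straight line in log10-log10 space (optionally with
phylogenetic GLS when a tree is supplied): the log-intercept gives
``c = 10^intercept`` and the slope is the exponent ``e``. The published
parrot model has c = 0.94 N and e = 2.195, available here as
:func:`published_model`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .allometry import AllometricFit, PhyloCovariance, pgls_fit

__all__ = [
    "ScarModel",
    "fit_scar_model",
    "predict_bite_force",
    "invert_prediction",
    "prediction_interval",
    "published_model",
]


@dataclass(frozen=True)
class ScarModel:
    """Fitted power law BF = coefficient * scar_length^exponent."""

    coefficient: float   # N at scar length 1 mm
    exponent: float      # dimensionless
    log_intercept: float
    log_slope: float
    fit: AllometricFit | None = None

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be > 0")

    @classmethod
    def from_power_law(cls, coefficient: float, exponent: float) -> "ScarModel":
        """Build a model directly from (coefficient, exponent)."""
        return cls(
            coefficient=float(coefficient),
            exponent=float(exponent),
            log_intercept=float(np.log10(coefficient)),
            log_slope=float(exponent),
        )


def published_model() -> ScarModel:
    """The published parrot scar model, BF = 0.94 * scar_length^2.195."""
    return ScarModel.from_power_law(0.94, 2.195)


def fit_scar_model(
    scar_lengths, bite_forces, cov: PhyloCovariance | None = None, lam="ML"
) -> ScarModel:
    """Fit the scar power law on log10-log10 axes.

    With no tree an ordinary least-squares fit is used (the published
    relationship has phylogenetic signal < 0.001, so GLS collapses to OLS
    there anyway).
    """
    scar = np.asarray(scar_lengths, dtype=float)
    bf = np.asarray(bite_forces, dtype=float)
    if scar.shape != bf.shape or scar.ndim != 1:
        raise ValueError("scar lengths and bite forces must be 1-D and paired")
    if len(scar) < 3:
        raise ValueError("at least 3 paired observations are required")
    bad = np.nonzero((scar <= 0) | (bf <= 0))[0]
    if bad.size:
        raise ValueError(
            f"non-positive scar length or bite force at rows {bad.tolist()}"
        )
    fit = pgls_fit(np.log10(scar), np.log10(bf), cov=cov, lam=lam)
    return ScarModel(
        coefficient=float(10.0**fit.intercept),
        exponent=float(fit.slope),
        log_intercept=fit.intercept,
        log_slope=fit.slope,
        fit=fit,
    )


def predict_bite_force(model: ScarModel, scar_length):
    """BF = c * scar_length^e; vectorized, 0 mm maps to 0 N."""
    scar = np.asarray(scar_length, dtype=float)
    if np.any(scar < 0):
        raise ValueError("scar_length must be >= 0")
    out = model.coefficient * np.power(scar, model.exponent)
    return float(out) if np.isscalar(scar_length) else out


def invert_prediction(model: ScarModel, bite_force):
    """Scar length implied by a bite force: (BF / c)^(1/e)."""
    bf = np.asarray(bite_force, dtype=float)
    if np.any(bf < 0):
        raise ValueError("bite_force must be >= 0")
    out = np.power(bf / model.coefficient, 1.0 / model.exponent)
    return float(out) if np.isscalar(bite_force) else out


def prediction_interval(model: ScarModel, scar_length, level: float = 0.95):
    """Prediction interval for a new observation, on the newton scale.

    Derived from the fit's residual variance on the log10 scale; the
    published relationship carries no intervals, so this is an extra
    diagnostic of this implementation, not a reproduced quantity.
    """
    if model.fit is None:
        raise ValueError("model carries no fit; intervals need fitted residuals")
    f = model.fit
    scar = np.atleast_1d(np.asarray(scar_length, dtype=float))
    if np.any(scar <= 0):
        raise ValueError("scar_length must be > 0 for an interval")
    x0 = np.log10(scar)
    se_pred = np.sqrt(
        f.sigma2 * (1.0 + 1.0 / f.n_species + (x0 - f.x_mean) ** 2 / f.ssx)
    )
    tq = stats.t.ppf(0.5 + level / 2.0, f.df)
    mid = f.intercept + f.slope * x0
    lo = 10.0 ** (mid - tq * se_pred)
    hi = 10.0 ** (mid + tq * se_pred)
    if np.isscalar(scar_length):
        return float(lo[0]), float(hi[0])
    return lo, hi
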