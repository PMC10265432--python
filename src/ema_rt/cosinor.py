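"""Multilevel cosinor model of the diurnal cycle of RTs.

The occasion-level mean is regressed on sin(2*pi*h/24) and cos(2*pi*h/24)
inside the 3-level random-intercept structure (items in occasions in
persons).  With standardization on, values are z-scored first so the
amplitude is in SD units and twice the amplitude is the predicted
peak-to-trough fluctuation within a day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _mlm
from .varcomp import VarianceComponents

__all__ = ["CosinorFit", "DiurnalCurve", "fit_cosinor", "daily_fluctuation", "predict_diurnal"]

_OMEGA = 2.0 * np.pi / 24.0


@dataclass(frozen=True)
class CosinorFit:
    """One-harmonic (24 h) cosinor fit inside the nested variance structure."""

    mu: float
    beta_sin: float
    beta_cos: float
    standardized: bool
    components: VarianceComponents
    scale_mean: float  # z-scoring constants (0/1 when not standardized)
    scale_sd: float

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.beta_sin, self.beta_cos))

    @property
    def acrophase_hour(self) -> float:
        """Clock hour of the predicted maximum.

        For RTs the behavioral best (fastest responses) is the predicted
        minimum, ``(acrophase_hour + 12) % 24``.
        """
        return float(np.arctan2(self.beta_sin, self.beta_cos) / _OMEGA % 24.0)

    @property
    def nadir_hour(self) -> float:
        return float((self.acrophase_hour + 12.0) % 24.0)

    @property
    def daily_fluctuation(self) -> float:
        return daily_fluctuation(self.amplitude)


def daily_fluctuation(amplitude: float) -> float:
    """Peak-to-trough within-day fluctuation: exactly twice the amplitude."""
    if amplitude < 0:
        raise ValueError(f"amplitude must be nonnegative, got {amplitude}")
    return 2.0 * amplitude


def fit_cosinor(
    person, occasion, hour, value, *, standardize: bool = True
) -> CosinorFit:
    """Fit y = mu + b_s sin(wh) + b_c cos(wh) + u_person + v_occasion + e_item.

    ``hour`` is the decimal clock hour of each observation's occasion (must
    be occasion-constant).  With ``standardize=True`` the values are z-scored
    by their grand mean and total SD first, so the amplitude is in SD units.
    """
    hour = np.asarray(hour, dtype=float)
    value = np.asarray(value, dtype=float)
    span = float(hour.max() - hour.min())
    if span <= 0:
        raise ValueError("all observations share one clock hour; cosinor unidentifiable")
    if span <= 12.0:
        import warnings

        warnings.warn(
            f"clock hours span only {span:.1f} h; sine/cosine are nearly collinear",
            stacklevel=2,
        )
    mean, sd = 0.0, 1.0
    y = value
    if standardize:
        mean = float(value.mean())
        sd = float(value.std())
        if sd == 0:
            raise ValueError("values are constant; cannot standardize")
        y = (value - mean) / sd
    x = np.column_stack([np.sin(_OMEGA * hour), np.cos(_OMEGA * hour)])
    fit = _mlm.fit_univariate(person, occasion, y, x_cols=x)
    st = fit.stats
    comps = VarianceComponents(
        levels="three",
        grand_mean=float(fit.beta[0]),
        var_person=fit.s2p,
        var_occasion=fit.s2o,
        var_item=fit.s2e,
        log_likelihood=fit.loglik,
        converged=fit.converged,
        n_persons=st.n_persons,
        n_occasions=st.n_occasions,
        n_observations=st.n_obs,
    )
    return CosinorFit(
        mu=float(fit.beta[0]),
        beta_sin=float(fit.beta[1]),
        beta_cos=float(fit.beta[2]),
        standardized=standardize,
        components=comps,
        scale_mean=mean,
        scale_sd=sd,
    )


@dataclass(frozen=True)
class DiurnalCurve:
    """Predicted mean diurnal profile on an hour grid."""

    hours: np.ndarray
    predicted: np.ndarray
    min_hour: float
    max_hour: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hour": self.hours, "predicted": self.predicted})


def predict_diurnal(fit: CosinorFit, hours=None) -> DiurnalCurve:
    """Evaluate mu + b_s sin + b_c cos on a grid (default 6.0-24.0, step 0.25)."""
    if hours is None:
        hours = np.arange(6.0, 24.0 + 1e-9, 0.25)
    hours = np.asarray(hours, dtype=float)
    pred = fit.mu + fit.beta_sin * np.sin(_OMEGA * hours) + fit.beta_cos * np.cos(
        _OMEGA * hours
    )
    return DiurnalCurve(
        hours=hours,
        predicted=pred,
        min_hour=float(hours[np.argmin(pred)]),
        max_hour=float(hours[np.argmax(pred)]),
    )
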