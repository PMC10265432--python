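"""Bivariate multilevel correlations between two measures.

The 3-level model estimates the between-person correlation among person
intercepts (level 3) and the within-person correlation among occasion
deviations (level 2), with each measure's item-level noise modeled at
level 1 — so both correlations are corrected for within-occasion
unreliability.  The 2-level manifest variant drops level 1 and correlates
observed occasion means, which attenuates the within-person correlation by
roughly the square root of the product of the occasion-mean reliabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _mlm
from .varcomp import VarianceComponents

__all__ = [
    "LatentCorrelations",
    "fit_bivariate3",
    "fit_bivariate2_manifest",
    "person_covariate_corr",
]

_BOUNDARY = 1e-8


@dataclass(frozen=True)
class LatentCorrelations:
    """Level-specific correlations between two measures."""

    r_between: float  # person-intercept correlation (NaN if a variance is at floor)
    r_within: float  # occasion-deviation correlation
    model: str  # "three_level" | "two_level_manifest"
    components_a: VarianceComponents
    components_b: VarianceComponents
    cross_cov_person: float
    cross_cov_occasion: float
    converged: bool


def _obs_arrays(obs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept a DataFrame with person_id/occasion_id/value or a 3-tuple."""
    if isinstance(obs, pd.DataFrame):
        cols = obs.columns
        value_col = "value" if "value" in cols else "log_rt"
        return (
            obs["person_id"].to_numpy(),
            obs["occasion_id"].to_numpy(),
            obs[value_col].to_numpy(dtype=float),
        )
    person, occasion, value = obs
    return np.asarray(person), np.asarray(occasion), np.asarray(value, dtype=float)


def _wrap(fit: _mlm.BivariateFit, model: str) -> LatentCorrelations:
    def comp(s2p, s2o, s2e, mu):
        return VarianceComponents(
            levels="three" if s2e is not None else "two",
            grand_mean=float(mu),
            var_person=s2p,
            var_occasion=s2o,
            var_item=s2e,
            log_likelihood=fit.loglik,
            converged=fit.converged,
            n_persons=fit.data.n_persons,
            n_occasions=len(fit.data.person),
            n_observations=fit.data.n_obs_a + fit.data.n_obs_b,
        )

    rb = fit.r_person
    if fit.s2pa <= _BOUNDARY or fit.s2pb <= _BOUNDARY:
        rb = float("nan")
    rw = fit.r_occasion
    if fit.s2oa <= _BOUNDARY or fit.s2ob <= _BOUNDARY:
        rw = float("nan")
    return LatentCorrelations(
        r_between=rb,
        r_within=rw,
        model=model,
        components_a=comp(fit.s2pa, fit.s2oa, fit.s2ea, fit.mu[0]),
        components_b=comp(fit.s2pb, fit.s2ob, fit.s2eb, fit.mu[1]),
        cross_cov_person=fit.r_person * float(np.sqrt(fit.s2pa * fit.s2pb)),
        cross_cov_occasion=fit.r_occasion * float(np.sqrt(fit.s2oa * fit.s2ob)),
        converged=fit.converged,
    )


def fit_bivariate3(obs_a, obs_b, *, level1_a: bool = True, level1_b: bool = True) -> LatentCorrelations:
    """3-level latent correlations between two measures aligned on
    (person, occasion).

    Multiple items/trials per occasion are allowed; a measure observed once
    per occasion (e.g. a single rating) is admitted with ``level1_x=False``,
    fixing its level-1 variance at zero.  Occasions where only one measure
    is valid contribute through that measure's marginal likelihood.
    """
    pa, oa, va = _obs_arrays(obs_a)
    pb, ob, vb = _obs_arrays(obs_b)
    fit = _mlm.fit_bivariate(pa, oa, va, pb, ob, vb, level1_a=level1_a, level1_b=level1_b)
    return _wrap(fit, "three_level")


def fit_bivariate2_manifest(occasion_means_a, occasion_means_b) -> LatentCorrelations:
    """2-level manifest correlations on observed occasion means (no level-1
    unreliability correction)."""
    pa, oa, va = _obs_arrays(occasion_means_a)
    pb, ob, vb = _obs_arrays(occasion_means_b)
    for name, p, o in (("a", pa, oa), ("b", pb, ob)):
        if pd.MultiIndex.from_arrays([p, o]).duplicated().any():
            raise ValueError(f"measure {name}: expected one mean per (person, occasion)")
    fit = _mlm.fit_bivariate(pa, oa, va, pb, ob, vb, level1_a=False, level1_b=False)
    return _wrap(fit, "two_level_manifest")


def person_covariate_corr(obs, covariate, *, three_level: bool = True) -> float:
    """ML correlation between the latent person intercept of ``obs`` and an
    error-free person-level covariate (Series indexed by person id, or a
    mapping)."""
    person, occasion, value = _obs_arrays(obs)
    if not isinstance(covariate, pd.Series):
        covariate = pd.Series(dict(covariate))
    fit = _mlm.fit_person_covariate(
        person, occasion, value, covariate, three_level=three_level
    )
    return fit.r
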