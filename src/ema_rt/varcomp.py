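"""Maximum-likelihood variance components of log-RT, 2- and 3-level.

The 3-level model is items (or trials) nested in measurement occasions
nested in persons; the 2-level model works on one value per occasion
(typically the occasion mean).  A balanced-design nested-ANOVA moment
estimator is provided as an independent oracle — with ML-consistent
divisors, so on fully balanced data with interior estimates it coincides
with the ML optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _mlm

__all__ = ["VarianceComponents", "fit_varcomp3", "fit_varcomp2", "varcomp3_moments"]


@dataclass(frozen=True)
class VarianceComponents:
    """Random-intercept variance decomposition of a nested design."""

    levels: str  # "two" | "three"
    grand_mean: float
    var_person: float
    var_occasion: float
    var_item: float | None
    log_likelihood: float
    converged: bool
    n_persons: int
    n_occasions: int
    n_observations: int

    @property
    def total(self) -> float:
        return self.var_person + self.var_occasion + (self.var_item or 0.0)


def fit_varcomp3(person, occasion, value) -> VarianceComponents:
    """ML fit of y_pij = mu + u_p + v_pi + e_pij on (person, occasion, value)
    triples.  Handles unbalanced designs exactly (per-person block
    likelihood); variances are optimized on a log scale and floored at 1e-10.
    """
    fit = _mlm.fit_univariate(person, occasion, value, two_level=False)
    st = fit.stats
    return VarianceComponents(
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


def fit_varcomp2(person, value) -> VarianceComponents:
    """ML fit of y_pi = mu + u_p + eps_pi on (person, occasion-value) pairs."""
    person = np.asarray(person)
    if len(np.unique(person)) < 2:
        raise ValueError("between-person variance needs at least 2 persons")
    occasion = np.arange(len(person))  # each value is its own occasion
    fit = _mlm.fit_univariate(person, occasion, value, two_level=True)
    st = fit.stats
    return VarianceComponents(
        levels="two",
        grand_mean=float(fit.beta[0]),
        var_person=fit.s2p,
        var_occasion=fit.s2o,
        var_item=None,
        log_likelihood=fit.loglik,
        converged=fit.converged,
        n_persons=st.n_persons,
        n_occasions=st.n_occasions,
        n_observations=st.n_occasions,
    )


def varcomp3_moments(person, occasion, value) -> VarianceComponents:
    """Expected-mean-squares (nested ANOVA) estimator for balanced designs.

    Strata sums of squares are divided by ML-consistent counts — the person
    stratum by the number of persons — so that, when all estimates are
    interior, the result equals the profile-ML optimum.  Negative solutions
    are truncated at zero.  Refuses unbalanced input.
    """
    person = np.asarray(person)
    occasion = np.asarray(occasion)
    value = np.asarray(value, dtype=float)
    persons, pcode = np.unique(person, return_inverse=True)
    occ_key = np.char.add(np.char.add(person.astype(str), "\x1f"), occasion.astype(str))
    occs, ocode = np.unique(occ_key, return_inverse=True)
    P = len(persons)
    n_per_occ = np.bincount(ocode)
    if len(set(n_per_occ)) != 1:
        raise ValueError("unbalanced design: occasions have differing item counts")
    I = int(n_per_occ[0])
    occ_person = np.zeros(len(occs), dtype=int)
    occ_person[ocode] = pcode
    occ_per_person = np.bincount(occ_person, minlength=P)
    if len(set(occ_per_person)) != 1:
        raise ValueError("unbalanced design: persons have differing occasion counts")
    O = int(occ_per_person[0])
    if P < 2 or O < 2 or I < 1:
        raise ValueError("need >= 2 persons and >= 2 occasions per person")

    grand = float(value.mean())
    occ_mean = np.bincount(ocode, weights=value) / I
    person_mean = np.bincount(pcode, weights=value) / (O * I)

    ss_item = float(np.sum((value - occ_mean[ocode]) ** 2))
    ss_occ = I * float(np.sum((occ_mean - person_mean[occ_person]) ** 2))
    ss_person = I * O * float(np.sum((person_mean - grand) ** 2))

    # ML-consistent stratum divisors: P*O*(I-1), P*(O-1), P
    lam1 = ss_item / (P * O * (I - 1)) if I > 1 else 0.0
    lam2 = ss_occ / (P * (O - 1))
    lam3 = ss_person / P
    s2e = max(lam1, 0.0)
    s2o = max((lam2 - lam1) / I, 0.0)
    s2p = max((lam3 - lam2) / (I * O), 0.0)
    return VarianceComponents(
        levels="three",
        grand_mean=grand,
        var_person=s2p,
        var_occasion=s2o,
        var_item=s2e,
        log_likelihood=float("nan"),
        converged=True,
        n_persons=P,
        n_occasions=P * O,
        n_observations=len(value),
    )
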