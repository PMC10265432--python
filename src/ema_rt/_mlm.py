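"""Internal Gaussian likelihood machinery for nested random-intercept models.

All models here share one trick: with exchangeable within-occasion structure
and occasion-constant fixed effects, the exact likelihood of a person's data
only needs per-occasion sufficient statistics (count, mean, within-occasion
sum of squares).  For the model

    y_pij = x_pi' beta + u_p + v_pi + e_pij,
    u ~ N(0, s2p), v ~ N(0, s2o), e ~ N(0, s2e),

writing tau_i = s2o + s2e / n_i for the occasion-mean variance, each person's
block covariance is s2p * J + diag(tau) and both its determinant and inverse
come from a rank-one update:

    -2 log L = N log 2pi
             + sum_i [(n_i - 1) log s2e] + SSW / s2e
             + sum_i log(s2e + n_i s2o)
             + sum_p log(1 + s2p * a_p)
             + sum_i r_i^2 / tau_i - sum_p s2p * b_p^2 / (1 + s2p * a_p)

with a_p = sum_i 1/tau_i, b_p = sum_i r_i/tau_i and r_i = m_i - x_i' beta.
beta is profiled out by GLS.  Everything is vectorized with bincount over
person codes, so one likelihood evaluation is O(#occasions).

Variances are optimized as s2 = FLOOR + exp(theta) (smooth floor instead of
a boundary-constrained search); correlations as tanh(z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

FLOOR = 1e-10
LOG2PI = float(np.log(2.0 * np.pi))
_THETA_LO, _THETA_HI = -25.0, 12.0
_Z_LIM = 7.0


@dataclass
class OccasionStats:
    """Per-occasion sufficient statistics, sorted by person code."""

    person: np.ndarray  # int codes 0..n_persons-1, one per occasion
    n: np.ndarray  # items per occasion
    mean: np.ndarray
    ss: np.ndarray  # within-occasion sum of squares
    x: np.ndarray  # (n_occ, k) occasion-level fixed-effect design
    n_persons: int
    person_labels: np.ndarray
    occasion_labels: np.ndarray

    @property
    def n_obs(self) -> int:
        return int(self.n.sum())

    @property
    def n_occasions(self) -> int:
        return len(self.n)


def occasion_stats(person, occasion, value, x_cols=None) -> OccasionStats:
    """Collapse item-level observations to per-occasion sufficient stats.

    ``x_cols`` is an optional (n_obs, k) array of occasion-constant fixed
    covariates (no intercept column needed; one is prepended).
    """
    value = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(value)):
        raise ValueError("values must be finite")
    df = pd.DataFrame({"p": np.asarray(person), "o": np.asarray(occasion), "y": value})
    k = 0
    if x_cols is not None:
        x_cols = np.atleast_2d(np.asarray(x_cols, dtype=float))
        if x_cols.shape[0] != len(df):
            x_cols = x_cols.T
        k = x_cols.shape[1]
        for j in range(k):
            df[f"x{j}"] = x_cols[:, j]
    g = df.groupby(["p", "o"], sort=True, observed=True)
    agg = g["y"].agg(["size", "mean"])
    ss = g["y"].apply(lambda s: float(((s - s.mean()) ** 2).sum()))
    persons, codes = np.unique(agg.index.get_level_values(0), return_inverse=True)
    x = np.ones((len(agg), k + 1))
    if k:
        xf = g[[f"x{j}" for j in range(k)]].first()
        x[:, 1:] = xf.to_numpy()
    return OccasionStats(
        person=codes.astype(np.int64),
        n=agg["size"].to_numpy(dtype=float),
        mean=agg["mean"].to_numpy(dtype=float),
        ss=ss.to_numpy(dtype=float),
        x=x,
        n_persons=len(persons),
        person_labels=np.asarray(persons),
        occasion_labels=agg.index.get_level_values(1).to_numpy(),
    )


def _nll_profile(st: OccasionStats, s2p: float, s2o: float, s2e: float | None):
    """-2 log L with beta profiled out by GLS.  Returns (nll, beta).

    ``s2e=None`` means a pure 2-level model: each occasion is a single
    observation with residual variance s2o (n must be all ones, ss zero).
    """
    P = st.n_persons
    if s2e is None:
        tau = np.full(st.n_occasions, s2o)
        level1 = 0.0
        logdet_occ = float(np.sum(np.log(tau)))
        n_obs = st.n_occasions
    else:
        tau = s2o + s2e / st.n
        df1 = st.n - 1.0
        level1 = float(np.sum(df1) * np.log(s2e) + st.ss.sum() / s2e)
        logdet_occ = float(np.sum(np.log(s2e + st.n * s2o)))
        n_obs = st.n_obs
    w = 1.0 / tau
    a = np.bincount(st.person, weights=w, minlength=P)
    denom = 1.0 + s2p * a
    shrink = s2p / denom  # per person

    # GLS for beta: X' Sigma^-1 X and X' Sigma^-1 m
    k = st.x.shape[1]
    wx = st.x * w[:, None]
    sp_wx = np.empty((P, k))
    for j in range(k):
        sp_wx[:, j] = np.bincount(st.person, weights=wx[:, j], minlength=P)
    sp_wy = np.bincount(st.person, weights=w * st.mean, minlength=P)
    xtsx = wx.T @ st.x - sp_wx.T @ (shrink[:, None] * sp_wx)
    xtsy = wx.T @ st.mean - sp_wx.T @ (shrink * sp_wy)
    beta = np.linalg.solve(xtsx, xtsy)

    r = st.mean - st.x @ beta
    b = np.bincount(st.person, weights=w * r, minlength=P)
    quad = float(np.sum(w * r * r) - np.sum(shrink * b * b))
    logdet = logdet_occ + float(np.sum(np.log(denom)))
    nll = n_obs * LOG2PI + level1 + logdet + quad
    return nll, beta


@dataclass
class UnivariateFit:
    s2p: float
    s2o: float
    s2e: float | None
    beta: np.ndarray
    loglik: float
    converged: bool
    stats: OccasionStats


def _minimize(fun, theta0, bounds):
    res = optimize.minimize(
        fun, theta0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-13, "gtol": 1e-10, "maxiter": 500},
    )
    # Nelder-Mead polish: cheap, and tightens to the 1e-8 ll-difference rule
    res2 = optimize.minimize(
        fun, res.x, method="Nelder-Mead", bounds=bounds,
        options={"fatol": 1e-9, "xatol": 1e-7, "maxiter": 4000},
    )
    best = res2 if res2.fun <= res.fun else res
    converged = bool(res.success or res2.success)
    return np.asarray(best.x), float(best.fun), converged


def fit_univariate(
    person, occasion, value, x_cols=None, *, two_level: bool = False
) -> UnivariateFit:
    """ML fit of the 2- or 3-level random-intercept model.

    ``two_level=True`` treats each (person, occasion) value as a single
    level-1 observation of the model y_pi = x'beta + u_p + eps_pi.
    """
    st = occasion_stats(person, occasion, value, x_cols)
    if st.n_persons < 2:
        raise ValueError("at least 2 persons are required")
    if two_level:
        if np.any(st.n > 1):
            raise ValueError("two-level input must have one value per occasion")
    else:
        if not np.any(st.n >= 2):
            raise ValueError("at least one occasion needs >= 2 items for a 3-level fit")
    occ_per_person = np.bincount(st.person, minlength=st.n_persons)
    if not np.any(occ_per_person >= 2):
        raise ValueError("at least one person needs >= 2 occasions")

    total_var = float(np.var(st.mean)) + float(st.ss.sum() / max(st.n_obs, 1))
    if total_var < FLOOR:
        # degenerate: all observations identical
        beta = np.zeros(st.x.shape[1])
        beta[0] = st.mean[0]
        nll, _ = _nll_profile(st, FLOOR, FLOOR, None if two_level else FLOOR)
        return UnivariateFit(
            FLOOR, FLOOR, None if two_level else FLOOR, beta, -0.5 * nll, True, st
        )

    theta0 = _univariate_start(st, two_level)
    bounds = [(_THETA_LO, _THETA_HI)] * len(theta0)

    def fun(theta):
        s2 = FLOOR + np.exp(theta)
        if two_level:
            nll, _ = _nll_profile(st, s2[0], s2[1], None)
        else:
            nll, _ = _nll_profile(st, s2[0], s2[1], s2[2])
        return nll

    theta, fval, converged = _minimize(fun, theta0, bounds)
    s2 = FLOOR + np.exp(theta)
    if two_level:
        nll, beta = _nll_profile(st, s2[0], s2[1], None)
        return UnivariateFit(s2[0], s2[1], None, beta, -0.5 * nll, converged, st)
    nll, beta = _nll_profile(st, s2[0], s2[1], s2[2])
    return UnivariateFit(s2[0], s2[1], s2[2], beta, -0.5 * nll, converged, st)


def _univariate_start(st: OccasionStats, two_level: bool) -> np.ndarray:
    """Crude moment-based starting values on the theta (log) scale."""
    pm = np.bincount(st.person, weights=st.mean) / np.bincount(st.person)
    v_person = max(float(np.var(pm)), 1e-4)
    v_occ = max(float(np.var(st.mean - pm[st.person])), 1e-4)
    if two_level:
        return np.log(np.array([v_person, v_occ]))
    df1 = np.maximum(st.n - 1.0, 0.0).sum()
    v_item = max(float(st.ss.sum() / max(df1, 1.0)), 1e-4)
    nbar = float(st.n.mean())
    v_occ = max(v_occ - v_item / nbar, 1e-4)
    v_person = max(v_person - v_occ / 2.0, 1e-4)
    return np.log(np.array([v_person, v_occ, v_item]))


# ---------------------------------------------------------------------------
# Bivariate (two measures, correlated person and occasion effects)


@dataclass
class BivariateData:
    """Aligned per-occasion stats for two measures (union of occasions)."""

    person: np.ndarray  # occasion-level person codes
    has_a: np.ndarray
    has_b: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    m_a: np.ndarray
    m_b: np.ndarray
    ss_a: float
    ss_b: float
    df_a: float  # sum(n_a - 1) over occasions with a
    df_b: float
    n_persons: int
    n_obs_a: int
    n_obs_b: int


def align_bivariate(st_a: OccasionStats, st_b: OccasionStats) -> BivariateData:
    ka = pd.MultiIndex.from_arrays(
        [st_a.person_labels[st_a.person], st_a.occasion_labels]
    )
    kb = pd.MultiIndex.from_arrays(
        [st_b.person_labels[st_b.person], st_b.occasion_labels]
    )
    union = ka.union(kb)
    persons = np.unique(union.get_level_values(0))
    pcode = pd.Series(np.arange(len(persons)), index=persons)

    def place(keys, vals, default=0.0):
        s = pd.Series(vals, index=keys)
        return s.reindex(union, fill_value=default).to_numpy(dtype=float)

    has_a = place(ka, np.ones(len(ka))) > 0
    has_b = place(kb, np.ones(len(kb))) > 0
    if not np.any(has_a & has_b):
        raise ValueError("measures share no (person, occasion); cannot correlate")
    return BivariateData(
        person=pcode[union.get_level_values(0)].to_numpy(),
        has_a=has_a,
        has_b=has_b,
        n_a=place(ka, st_a.n),
        n_b=place(kb, st_b.n),
        m_a=place(ka, st_a.mean),
        m_b=place(kb, st_b.mean),
        ss_a=float(st_a.ss.sum()),
        ss_b=float(st_b.ss.sum()),
        df_a=float((st_a.n - 1.0).sum()),
        df_b=float((st_b.n - 1.0).sum()),
        n_persons=len(persons),
        n_obs_a=st_a.n_obs,
        n_obs_b=st_b.n_obs,
    )


def _bivariate_nll(bd: BivariateData, params: dict) -> tuple[float, np.ndarray]:
    """-2 log L of the joint model, means profiled by GLS.

    params: s2pa, s2pb, rp, s2oa, s2ob, ro, s2ea, s2eb (level-1 variances
    may be None for single-observation measures).
    """
    P = bd.n_persons
    s2ea, s2eb = params["s2ea"], params["s2eb"]
    cp = params["rp"] * np.sqrt(params["s2pa"] * params["s2pb"])
    co = params["ro"] * np.sqrt(params["s2oa"] * params["s2ob"])

    level1 = 0.0
    n_obs = 0
    tau_a = np.where(bd.has_a, params["s2oa"], np.nan)
    if s2ea is not None:
        tau_a = tau_a + np.where(bd.has_a, s2ea / np.maximum(bd.n_a, 1.0), 0.0)
        level1 += bd.df_a * np.log(s2ea) + bd.ss_a / s2ea
    tau_b = np.where(bd.has_b, params["s2ob"], np.nan)
    if s2eb is not None:
        tau_b = tau_b + np.where(bd.has_b, s2eb / np.maximum(bd.n_b, 1.0), 0.0)
        level1 += bd.df_b * np.log(s2eb) + bd.ss_b / s2eb
    n_obs = bd.n_obs_a + bd.n_obs_b

    both = bd.has_a & bd.has_b
    only_a = bd.has_a & ~bd.has_b
    only_b = bd.has_b & ~bd.has_a

    # per-occasion W^-1 entries (2x2; zero-padded where a measure is absent)
    iaa = np.zeros(len(bd.person))
    iab = np.zeros(len(bd.person))
    ibb = np.zeros(len(bd.person))
    logdet_w = np.zeros(len(bd.person))
    det_both = tau_a * tau_b - co * co
    if np.any(both):
        if np.any(det_both[both] <= 0):
            return np.inf, np.zeros(2)
        iaa[both] = tau_b[both] / det_both[both]
        ibb[both] = tau_a[both] / det_both[both]
        iab[both] = -co / det_both[both]
        logdet_w[both] = np.log(det_both[both])
    iaa[only_a] = 1.0 / tau_a[only_a]
    logdet_w[only_a] = np.log(tau_a[only_a])
    ibb[only_b] = 1.0 / tau_b[only_b]
    logdet_w[only_b] = np.log(tau_b[only_b])

    ma = np.where(bd.has_a, bd.m_a, 0.0)
    mb = np.where(bd.has_b, bd.m_b, 0.0)

    # person-level aggregates
    def psum(v):
        return np.bincount(bd.person, weights=v, minlength=P)

    Maa, Mab, Mbb = psum(iaa), psum(iab), psum(ibb)
    ga = psum(iaa * ma + iab * mb)
    gb = psum(iab * ma + ibb * mb)

    dpa, dpb = params["s2pa"], params["s2pb"]
    # K = I + D M, S = (I + D M)^-1 D (symmetric)
    K11 = 1.0 + dpa * Maa + cp * Mab
    K12 = dpa * Mab + cp * Mbb
    K21 = cp * Maa + dpb * Mab
    K22 = 1.0 + cp * Mab + dpb * Mbb
    detK = K11 * K22 - K12 * K21
    if np.any(detK <= 0):
        return np.inf, np.zeros(2)
    S11 = (K22 * dpa - K12 * cp) / detK
    S12 = (K22 * cp - K12 * dpb) / detK
    S22 = (-K21 * cp + K11 * dpb) / detK

    # GLS for (mu_a, mu_b): A mu = rhs
    MSM11 = Maa * (S11 * Maa + S12 * Mab) + Mab * (S12 * Maa + S22 * Mab)
    MSM12 = Maa * (S11 * Mab + S12 * Mbb) + Mab * (S12 * Mab + S22 * Mbb)
    MSM22 = Mab * (S11 * Mab + S12 * Mbb) + Mbb * (S12 * Mab + S22 * Mbb)
    A = np.array(
        [
            [np.sum(Maa - MSM11), np.sum(Mab - MSM12)],
            [np.sum(Mab - MSM12), np.sum(Mbb - MSM22)],
        ]
    )
    rhs = np.array(
        [
            np.sum(ga - (Maa * (S11 * ga + S12 * gb) + Mab * (S12 * ga + S22 * gb))),
            np.sum(gb - (Mab * (S11 * ga + S12 * gb) + Mbb * (S12 * ga + S22 * gb))),
        ]
    )
    mu = np.linalg.solve(A, rhs)

    ra = np.where(bd.has_a, bd.m_a - mu[0], 0.0)
    rb = np.where(bd.has_b, bd.m_b - mu[1], 0.0)
    quad_w = float(np.sum(iaa * ra * ra + 2.0 * iab * ra * rb + ibb * rb * rb))
    gra = ga - (Maa * mu[0] + Mab * mu[1])
    grb = gb - (Mab * mu[0] + Mbb * mu[1])
    corr = float(np.sum(S11 * gra * gra + 2.0 * S12 * gra * grb + S22 * grb * grb))
    nll = (
        n_obs * LOG2PI
        + level1
        + float(np.sum(logdet_w))
        + float(np.sum(np.log(detK)))
        + quad_w
        - corr
    )
    return nll, mu


@dataclass
class BivariateFit:
    s2pa: float
    s2pb: float
    s2oa: float
    s2ob: float
    s2ea: float | None
    s2eb: float | None
    r_person: float
    r_occasion: float
    mu: np.ndarray
    loglik: float
    converged: bool
    data: BivariateData


def fit_bivariate(
    person_a, occasion_a, value_a, person_b, occasion_b, value_b,
    *, level1_a: bool = True, level1_b: bool = True,
) -> BivariateFit:
    """ML fit of the bivariate nested model with cross-measure correlations
    at the person and occasion levels.  ``level1_x=False`` fixes that
    measure's item-level variance at zero (single observation per occasion).
    """
    st_a = occasion_stats(person_a, occasion_a, value_a)
    st_b = occasion_stats(person_b, occasion_b, value_b)
    for st, flag, name in ((st_a, level1_a, "a"), (st_b, level1_b, "b")):
        if not flag and np.any(st.n > 1):
            raise ValueError(f"measure {name} declared single-item but has multi-item occasions")
    bd = align_bivariate(st_a, st_b)
    if bd.n_persons < 2:
        raise ValueError("at least 2 persons are required")

    fa = fit_univariate(person_a, occasion_a, value_a, two_level=not level1_a)
    fb = fit_univariate(person_b, occasion_b, value_b, two_level=not level1_b)
    r0p = _naive_person_corr(st_a, st_b)
    r0o = _naive_occasion_corr(st_a, st_b)

    free = ["s2pa", "s2pb", "zp", "s2oa", "s2ob", "zo"]
    theta0 = [
        np.log(max(fa.s2p, 1e-8)), np.log(max(fb.s2p, 1e-8)), np.arctanh(r0p),
        np.log(max(fa.s2o, 1e-8)), np.log(max(fb.s2o, 1e-8)), np.arctanh(r0o),
    ]
    bounds = [(_THETA_LO, _THETA_HI), (_THETA_LO, _THETA_HI), (-_Z_LIM, _Z_LIM)] * 2
    if level1_a:
        free.append("s2ea")
        theta0.append(np.log(max(fa.s2e, 1e-8)))
        bounds.append((_THETA_LO, _THETA_HI))
    if level1_b:
        free.append("s2eb")
        theta0.append(np.log(max(fb.s2e, 1e-8)))
        bounds.append((_THETA_LO, _THETA_HI))

    def unpack(theta):
        d = dict(zip(free, theta))
        return {
            "s2pa": FLOOR + np.exp(d["s2pa"]),
            "s2pb": FLOOR + np.exp(d["s2pb"]),
            "rp": np.tanh(d["zp"]),
            "s2oa": FLOOR + np.exp(d["s2oa"]),
            "s2ob": FLOOR + np.exp(d["s2ob"]),
            "ro": np.tanh(d["zo"]),
            "s2ea": FLOOR + np.exp(d["s2ea"]) if level1_a else None,
            "s2eb": FLOOR + np.exp(d["s2eb"]) if level1_b else None,
        }

    def fun(theta):
        nll, _ = _bivariate_nll(bd, unpack(theta))
        return nll

    theta, fval, converged = _minimize(fun, np.asarray(theta0), bounds)
    # coordinate-block polish: the person block (s2pa, s2pb, zp) can sit on a
    # ridge when the occasion-level correlation saturates (e.g. duplicated
    # measures), so re-optimize it and the occasion block separately
    blocks = [np.array([0, 1, 2]), np.arange(3, len(theta0))]
    for _ in range(2):
        improved = False
        for idx in blocks:
            def block_fun(sub, idx=idx):
                full = theta.copy()
                full[idx] = sub
                return fun(full)

            res = optimize.minimize(
                block_fun, theta[idx], method="Nelder-Mead",
                bounds=[bounds[j] for j in idx],
                options={"fatol": 1e-9, "xatol": 1e-7, "maxiter": 2000},
            )
            if res.fun < fval - 1e-9:
                theta = theta.copy()
                theta[idx] = np.clip(res.x, [b[0] for b in np.asarray(bounds)[idx]],
                                     [b[1] for b in np.asarray(bounds)[idx]])
                fval = fun(theta)
                improved = True
        if not improved:
            break
    params = unpack(theta)
    nll, mu = _bivariate_nll(bd, params)
    return BivariateFit(
        s2pa=params["s2pa"], s2pb=params["s2pb"],
        s2oa=params["s2oa"], s2ob=params["s2ob"],
        s2ea=params["s2ea"], s2eb=params["s2eb"],
        r_person=float(params["rp"]), r_occasion=float(params["ro"]),
        mu=mu, loglik=-0.5 * nll, converged=converged, data=bd,
    )


def _person_means(st: OccasionStats) -> np.ndarray:
    return np.bincount(st.person, weights=st.mean, minlength=st.n_persons) / np.bincount(
        st.person, minlength=st.n_persons
    )


def _naive_person_corr(st_a: OccasionStats, st_b: OccasionStats) -> float:
    pa = pd.Series(_person_means(st_a), index=st_a.person_labels)
    pb = pd.Series(_person_means(st_b), index=st_b.person_labels)
    shared = pa.index.intersection(pb.index)
    if len(shared) < 3:
        return 0.0
    r = float(np.corrcoef(pa[shared], pb[shared])[0, 1])
    return float(np.clip(np.nan_to_num(r), -0.95, 0.95))


def _naive_occasion_corr(st_a: OccasionStats, st_b: OccasionStats) -> float:
    da = pd.Series(
        st_a.mean - _person_means(st_a)[st_a.person],
        index=pd.MultiIndex.from_arrays(
            [st_a.person_labels[st_a.person], st_a.occasion_labels]
        ),
    )
    db = pd.Series(
        st_b.mean - _person_means(st_b)[st_b.person],
        index=pd.MultiIndex.from_arrays(
            [st_b.person_labels[st_b.person], st_b.occasion_labels]
        ),
    )
    shared = da.index.intersection(db.index)
    if len(shared) < 3:
        return 0.0
    r = float(np.corrcoef(da[shared], db[shared])[0, 1])
    return float(np.clip(np.nan_to_num(r), -0.95, 0.95))


# ---------------------------------------------------------------------------
# Person-level covariate correlation


@dataclass
class CovariateCorrFit:
    r: float
    s2p: float
    s2o: float
    s2e: float | None
    s2x: float
    mu: float
    mu_x: float
    loglik: float
    converged: bool


def fit_person_covariate(
    person, occasion, value, covariate: pd.Series, *, three_level: bool = True
) -> CovariateCorrFit:
    """ML correlation between the latent person intercept and an error-free
    person-level covariate.

    ``covariate`` is indexed by person id and must cover every modeled person.
    """
    st = occasion_stats(person, occasion, value)
    if st.n_persons < 3:
        raise ValueError("at least 3 persons are required")
    missing = set(st.person_labels) - set(covariate.index)
    if missing:
        raise ValueError(f"covariate missing for persons: {sorted(missing)[:5]}")
    x = covariate.loc[st.person_labels].to_numpy(dtype=float)
    if float(np.var(x)) == 0.0:
        raise ValueError("covariate is constant; correlation undefined")

    base = fit_univariate(person, occasion, value, two_level=not three_level)
    s2e_free = three_level

    free_n = 7 if s2e_free else 6

    def unpack(theta):
        mu, mux = theta[0], theta[1]
        s2p = FLOOR + np.exp(theta[2])
        s2o = FLOOR + np.exp(theta[3])
        s2x = FLOOR + np.exp(theta[4])
        z = theta[5]
        s2e = (FLOOR + np.exp(theta[6])) if s2e_free else None
        return mu, mux, s2p, s2o, s2e, s2x, np.tanh(z)

    def fun(theta):
        mu, mux, s2p, s2o, s2e, s2x, r = unpack(theta)
        c = r * np.sqrt(s2p * s2x)
        P = st.n_persons
        if s2e is None:
            tau = np.full(st.n_occasions, s2o)
            level1 = 0.0
            logdet_occ = float(np.sum(np.log(tau)))
            n_obs = st.n_occasions
        else:
            tau = s2o + s2e / st.n
            level1 = float(
                np.sum(st.n - 1.0) * np.log(s2e) + st.ss.sum() / s2e
            )
            logdet_occ = float(np.sum(np.log(s2e + st.n * s2o)))
            n_obs = st.n_obs
        w = 1.0 / tau
        r_i = st.mean - mu
        a = np.bincount(st.person, weights=w, minlength=P)
        b = np.bincount(st.person, weights=w * r_i, minlength=P)
        denom = 1.0 + s2p * a
        quad = float(np.sum(w * r_i * r_i) - np.sum(s2p / denom * b * b))
        nll = n_obs * LOG2PI + level1 + logdet_occ + float(np.sum(np.log(denom))) + quad
        # conditional covariate term: x_p | y_p
        condvar = s2x - c * c * a / denom
        if np.any(condvar <= 0):
            return np.inf
        condmean = mux + c * b / denom
        nll += float(
            P * LOG2PI + np.sum(np.log(condvar)) + np.sum((x - condmean) ** 2 / condvar)
        )
        return nll

    pm = _person_means(st)
    r0 = float(np.clip(np.nan_to_num(np.corrcoef(pm, x)[0, 1]), -0.95, 0.95))
    theta0 = [
        float(base.beta[0]), float(np.mean(x)),
        np.log(max(base.s2p, 1e-8)), np.log(max(base.s2o, 1e-8)),
        np.log(max(float(np.var(x)), 1e-8)), np.arctanh(r0),
    ]
    bounds = [
        (None, None), (None, None),
        (_THETA_LO, 30.0), (_THETA_LO, 30.0), (_THETA_LO, 30.0),
        (-_Z_LIM, _Z_LIM),
    ]
    if s2e_free:
        theta0.append(np.log(max(base.s2e, 1e-8)))
        bounds.append((_THETA_LO, 30.0))
    theta, fval, converged = _minimize(fun, np.asarray(theta0), bounds)
    mu, mux, s2p, s2o, s2e, s2x, r = unpack(theta)
    return CovariateCorrFit(
        r=float(r), s2p=s2p, s2o=s2o, s2e=s2e, s2x=s2x,
        mu=float(mu), mu_x=float(mux), loglik=-0.5 * fval, converged=converged,
    )
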