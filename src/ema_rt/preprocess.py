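"""Validity filters, log transform, and session-level cognitive scoring.

Filters only flag records (``valid`` + ``invalid_reason``); nothing is
deleted, so filtering is idempotent and exclusion accounting stays exact.
Reasons are disjoint with RT-range precedence, which makes the exclusion
percentages additive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import Measure

__all__ = [
    "REASON_RT_RANGE",
    "REASON_LOW_ACCURACY",
    "ExclusionSummary",
    "SessionScore",
    "filter_ema_rts",
    "filter_ss_trials",
    "exclusion_summary",
    "log_rt",
    "add_log_rt",
    "d_prime",
    "score_gng_session",
    "score_ss_session",
    "score_sessions",
]

REASON_RT_RANGE = "rt_range"
REASON_LOW_ACCURACY = "low_accuracy"

#: Default validity windows (seconds) and accuracy cutoff.
EMA_RT_RANGE = (0.2, 30.0)
SS_RT_RANGE = (0.2, 5.0)
SS_MIN_ACCURACY = 0.70


def _check_range(lo: float, hi: float) -> None:
    if lo <= 0:
        raise ValueError(f"lower RT bound must be positive, got {lo}")
    if hi <= lo:
        raise ValueError(f"upper RT bound must exceed lower, got ({lo}, {hi})")


def _ensure_reason(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "invalid_reason" not in df.columns:
        df["invalid_reason"] = ""
    return df


def filter_ema_rts(
    df: pd.DataFrame, lo: float = EMA_RT_RANGE[0], hi: float = EMA_RT_RANGE[1]
) -> pd.DataFrame:
    """Flag EMA item RTs outside ``[lo, hi]`` seconds as invalid.

    Boundaries are inclusive (the exclusion rule is strict: RTs below ``lo``
    or above ``hi`` are flagged).  Non-EMA rows pass through untouched.
    """
    _check_range(lo, hi)
    df = _ensure_reason(df)
    ema = df["measure"] == Measure.EMA.value
    rt = df["rt_seconds"].to_numpy()
    bad = ema.to_numpy() & ((rt < lo) | (rt > hi))
    ok = ema.to_numpy() & ~bad
    df.loc[bad, "valid"] = False
    df.loc[bad, "invalid_reason"] = REASON_RT_RANGE
    df.loc[ok, "valid"] = True
    df.loc[ok, "invalid_reason"] = ""
    return df


def filter_ss_trials(
    df: pd.DataFrame,
    lo: float = SS_RT_RANGE[0],
    hi: float = SS_RT_RANGE[1],
    min_accuracy: float = SS_MIN_ACCURACY,
) -> pd.DataFrame:
    """Flag Symbol Search trials by RT range and session accuracy.

    A trial is invalid if its RT falls outside ``[lo, hi]`` (inclusive
    boundaries) or if its whole session has raw accuracy strictly below
    ``min_accuracy``.  Session accuracy is computed over all trials, before
    any RT-range exclusion.  A trial failing both is counted under the
    RT-range reason.
    """
    _check_range(lo, hi)
    if not (0 < min_accuracy <= 1):
        raise ValueError(f"min_accuracy must be in (0, 1], got {min_accuracy}")
    df = _ensure_reason(df)
    ss = df["measure"] == Measure.SYMBOL_SEARCH.value
    sub = df.loc[ss]
    if sub.empty:
        warnings.warn("no SYMBOL_SEARCH records to filter", stacklevel=2)
        return df
    acc = (
        sub["correct"]
        .astype(float)
        .groupby([sub["person_id"], sub["occasion_id"]], observed=True)
        .transform("mean")
    )
    rt = sub["rt_seconds"].to_numpy()
    bad_rt = (rt < lo) | (rt > hi)
    bad_acc = (acc.to_numpy() < min_accuracy) & ~bad_rt
    idx = sub.index
    df.loc[idx, "valid"] = ~(bad_rt | bad_acc)
    reasons = np.where(bad_rt, REASON_RT_RANGE, np.where(bad_acc, REASON_LOW_ACCURACY, ""))
    df.loc[idx, "invalid_reason"] = reasons
    return df


@dataclass(frozen=True)
class ExclusionSummary:
    """Counts and percentages per (disjoint) exclusion reason."""

    n_total: int
    n_rt_range: int
    n_low_accuracy: int

    @property
    def n_excluded(self) -> int:
        return self.n_rt_range + self.n_low_accuracy

    # exact (unrounded) percentages ------------------------------------
    @property
    def pct_rt_range_exact(self) -> float:
        return 100.0 * self.n_rt_range / self.n_total if self.n_total else 0.0

    @property
    def pct_low_accuracy_exact(self) -> float:
        return 100.0 * self.n_low_accuracy / self.n_total if self.n_total else 0.0

    @property
    def pct_excluded_exact(self) -> float:
        return 100.0 * self.n_excluded / self.n_total if self.n_total else 0.0

    # reported (2-decimal) percentages ---------------------------------
    @property
    def pct_rt_range(self) -> float:
        return round(self.pct_rt_range_exact, 2)

    @property
    def pct_low_accuracy(self) -> float:
        return round(self.pct_low_accuracy_exact, 2)

    @property
    def pct_excluded(self) -> float:
        return round(self.pct_excluded_exact, 2)

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_rt_range": self.n_rt_range,
            "n_low_accuracy": self.n_low_accuracy,
            "n_excluded": self.n_excluded,
            "pct_rt_range": self.pct_rt_range,
            "pct_low_accuracy": self.pct_low_accuracy,
            "pct_excluded": self.pct_excluded,
        }


def exclusion_summary(
    df: pd.DataFrame | None = None,
    *,
    measure: str | None = None,
    n_total: int | None = None,
    n_rt_range: int | None = None,
    n_low_accuracy: int = 0,
) -> ExclusionSummary:
    """Summarize exclusions either from a filtered frame or from raw counts.

    With a frame, counts come from the ``invalid_reason`` column written by
    the filters (optionally restricted to one measure).  With keyword counts,
    the summary is computed directly — reasons must already be disjoint.
    """
    if df is not None:
        if "invalid_reason" not in df.columns:
            raise ValueError("frame has no 'invalid_reason' column; apply filters first")
        sub = df if measure is None else df[df["measure"] == measure]
        reasons = sub["invalid_reason"]
        return ExclusionSummary(
            n_total=len(sub),
            n_rt_range=int((reasons == REASON_RT_RANGE).sum()),
            n_low_accuracy=int((reasons == REASON_LOW_ACCURACY).sum()),
        )
    if n_total is None or n_rt_range is None:
        raise ValueError("provide either a frame or n_total and n_rt_range")
    return ExclusionSummary(
        n_total=n_total, n_rt_range=n_rt_range, n_low_accuracy=n_low_accuracy
    )


def log_rt(rt_seconds):
    """Natural log of RT seconds.  Input must be strictly positive."""
    arr = np.asarray(rt_seconds, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError("rt_seconds must be strictly positive")
    out = np.log(arr)
    return float(out) if np.isscalar(rt_seconds) else out


def add_log_rt(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``log_rt`` column: natural log for valid records, NaN otherwise."""
    df = df.copy()
    valid = df["valid"].to_numpy(dtype=bool)
    vals = np.full(len(df), np.nan)
    vals[valid] = np.log(df.loc[valid, "rt_seconds"].to_numpy())
    df["log_rt"] = vals
    return df


# ---------------------------------------------------------------------------
# Session scoring


@dataclass(frozen=True)
class SessionScore:
    """Per-(person, occasion, measure) summary of a cognitive session."""

    person_id: str
    occasion_id: str
    measure: str
    accuracy: float
    mean_log_rt_accurate: float
    median_rt_accurate: float
    n_valid_trials: int
    d_prime: float = float("nan")
    hit_rate: float = float("nan")
    fa_rate: float = float("nan")


def d_prime(n_hits: int, n_targets: int, n_fas: int, n_nontargets: int) -> tuple[float, float, float]:
    """Signal-detection sensitivity with the 1/(2N) zero/one-rate correction.

    Returns ``(d_prime, hit_rate, fa_rate)`` where rates of 0 or 1 are
    replaced by ``1/(2N)`` and ``1 - 1/(2N)`` (N = trials of that type) so
    the normal quantiles stay finite.
    """
    if n_targets <= 0 or n_nontargets <= 0:
        raise ValueError("both target and non-target trials are required for d'")
    hr = _corrected_rate(n_hits, n_targets)
    fr = _corrected_rate(n_fas, n_nontargets)
    return float(norm.ppf(hr) - norm.ppf(fr)), hr, fr


def _corrected_rate(k, n):
    rate = np.asarray(k, dtype=float) / n
    rate = np.where(rate <= 0, 1.0 / (2 * np.asarray(n, dtype=float)), rate)
    rate = np.where(rate >= 1, 1.0 - 1.0 / (2 * np.asarray(n, dtype=float)), rate)
    return float(rate) if rate.ndim == 0 else rate


def _gng_tapped(df: pd.DataFrame) -> np.ndarray:
    # tap iff (target and correct) or (non-target and incorrect)
    correct = df["correct"].to_numpy(dtype=bool)
    target = df["is_target"].to_numpy(dtype=bool)
    return np.where(target, correct, ~correct)


def score_gng_session(trials: pd.DataFrame) -> SessionScore:
    """Score one Go–No Go session (all rows must share person and occasion)."""
    scores = score_sessions(trials, measure=Measure.GO_NO_GO.value)
    if len(scores) != 1:
        raise ValueError("expected exactly one (person, occasion) session")
    return _row_to_score(scores.iloc[0])


def score_ss_session(trials: pd.DataFrame) -> SessionScore:
    """Score one Symbol Search session (filters should be applied first)."""
    scores = score_sessions(trials, measure=Measure.SYMBOL_SEARCH.value)
    if len(scores) != 1:
        raise ValueError("expected exactly one (person, occasion) session")
    return _row_to_score(scores.iloc[0])


def _row_to_score(row: pd.Series) -> SessionScore:
    return SessionScore(
        person_id=str(row["person_id"]),
        occasion_id=str(row["occasion_id"]),
        measure=str(row["measure"]),
        accuracy=float(row["accuracy"]),
        mean_log_rt_accurate=float(row["mean_log_rt_accurate"]),
        median_rt_accurate=float(row["median_rt_accurate"]),
        n_valid_trials=int(row["n_valid_trials"]),
        d_prime=float(row.get("d_prime", np.nan)),
        hit_rate=float(row.get("hit_rate", np.nan)),
        fa_rate=float(row.get("fa_rate", np.nan)),
    )


def score_sessions(df: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Vectorized session scoring for every (person, occasion) of a measure.

    For SYMBOL_SEARCH: accuracy over all trials, mean log RT and median RT
    over valid accurate trials.  For GO_NO_GO: additionally hit/false-alarm
    rates and d'; sessions lacking either stimulus type get NaN d' and are
    flagged in ``d_prime_defined``.
    """
    measure = Measure(measure).value
    sub = df[df["measure"] == measure]
    if sub.empty:
        raise ValueError(f"no {measure} records to score")
    if "valid" not in sub.columns:
        raise ValueError("records must carry a 'valid' column")
    keys = [sub["person_id"], sub["occasion_id"]]
    g = sub.groupby(keys, observed=True, sort=True)
    correct = sub["correct"].astype(float)
    acc = correct.groupby(keys, observed=True, sort=True).mean()

    scorable = sub["valid"].to_numpy(dtype=bool) & sub["correct"].to_numpy(dtype=bool)
    acc_sub = sub.loc[scorable].copy()
    acc_sub["log_rt"] = np.log(acc_sub["rt_seconds"].to_numpy())
    acc_keys = [acc_sub["person_id"], acc_sub["occasion_id"]]
    gacc = acc_sub.groupby(acc_keys, observed=True, sort=True)
    mean_log = gacc["log_rt"].mean()
    median_rt = gacc["rt_seconds"].median()

    out = pd.DataFrame(
        {
            "accuracy": acc,
            "n_valid_trials": g["valid"].sum().astype(int),
        }
    )
    out["mean_log_rt_accurate"] = mean_log
    out["median_rt_accurate"] = median_rt

    if measure == Measure.GO_NO_GO.value:
        tapped = _gng_tapped(sub)
        target = sub["is_target"].to_numpy(dtype=bool)
        tmp = pd.DataFrame(
            {
                "n_targets": target.astype(int),
                "n_hits": (tapped & target).astype(int),
                "n_nontargets": (~target).astype(int),
                "n_fas": (tapped & ~target).astype(int),
            },
            index=sub.index,
        )
        agg = tmp.groupby(keys, observed=True, sort=True).sum()
        defined = (agg["n_targets"] > 0) & (agg["n_nontargets"] > 0)
        n_t = agg["n_targets"].to_numpy(dtype=float)
        n_nt = agg["n_nontargets"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            hr = _corrected_rate(agg["n_hits"].to_numpy(), np.where(n_t > 0, n_t, 1))
            fr = _corrected_rate(agg["n_fas"].to_numpy(), np.where(n_nt > 0, n_nt, 1))
        dp = norm.ppf(hr) - norm.ppf(fr)
        out["hit_rate"] = np.where(defined, hr, np.nan)
        out["fa_rate"] = np.where(defined, fr, np.nan)
        out["d_prime"] = np.where(defined, dp, np.nan)
        out["d_prime_defined"] = defined.to_numpy()

    out = out.reset_index(names=["person_id", "occasion_id"])
    out.insert(2, "measure", measure)
    return out
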