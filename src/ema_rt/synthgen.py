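"""Seeded generator of study-shaped synthetic data.

Log-RTs are Gaussian with person/occasion/item variance components
(lognormal on the seconds scale), so the analysis models are correctly
specified for the clean part of the data.  Cross-measure structure is
injected through correlated person intercepts and correlated occasion
deviations; a 24 h cosine signal, fatigue coupling, careless ultrafast
responses, interruption outliers, and MCAR missingness are layered on top.
Identical seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import ItemCatalog, Measure, ResponseType, RT_COLUMNS

__all__ = ["SynthConfig", "StudyTruth", "SynthStudy", "generate_study", "true_params_report"]

_OMEGA = 2.0 * np.pi / 24.0
_MEASURES = ("EMA", "SYMBOL_SEARCH", "GO_NO_GO")


@dataclass(frozen=True)
class SynthConfig:
    """Full generative specification.  Defaults mirror the study design
    (198 persons, 14 days, 5-6 prompts/day, 22 EMA items, 20 Symbol Search
    trials and 75 Go-No Go trials per prompt) with variance components
    back-solved from the published reliability table (approximation, not
    truth)."""

    # design
    n_persons: int = 198
    n_days: int = 14
    prompts_per_day: tuple[int, int] = (5, 6)
    p_six_prompts: float = 0.5
    waking_window: tuple[float, float] = (6.0, 24.0)
    n_ss_trials: int = 20
    n_gng_trials: int = 75
    n_gng_targets: int = 50
    measures: tuple[str, ...] = _MEASURES
    #: optional restriction of the default 22-item catalog (None = all items)
    items: tuple[str, ...] | None = None

    # EMA log-RT components (slider baseline)
    mu_log_rt_ema: float = 0.79  # ~2.2 s
    sigma2_p_ema: float = 0.0776
    sigma2_o_ema: float = 0.05
    sigma2_e_ema: float = 0.1756
    # per-response-type tweaks: mean offset and level-1 variance multiplier
    mu_offset_mc: float = 0.5
    mu_offset_checkbox: float = 0.3
    e_var_multiplier_mc: float = 4.0
    e_var_multiplier_checkbox: float = 3.0

    # Symbol Search log-RT components
    mu_log_rt_ss: float = 0.41  # ~1.5 s
    sigma2_p_ss: float = 0.0644
    sigma2_o_ss: float = 0.02
    sigma2_e_ss: float = 0.1263
    ss_accuracy: float = 0.95
    ss_careless_session_rate: float = 0.01
    ss_careless_accuracy: float = 0.5

    # Go-No Go: d' structure and (plumbing) trial RTs
    gng_dprime_mean: float = 2.0
    gng_dprime_sd_person: float = 0.5
    gng_dprime_sd_occasion: float = 0.3
    gng_criterion: float = 0.0
    mu_log_rt_gng: float = -0.7  # ~0.5 s
    sigma2_p_gng: float = 0.02
    sigma2_o_gng: float = 0.01
    sigma2_e_gng: float = 0.05

    # cross-measure correlations (person / occasion levels)
    r_between: float = 0.55  # EMA-SS person intercepts
    r_within: float = 0.35  # EMA-SS occasion deviations
    r_between_gng_ema: float = 0.10
    r_between_gng_ss: float = -0.15
    r_within_gng_ema: float = 0.0
    r_within_gng_ss: float = 0.0

    # diurnal cosine (standardized amplitude in total-SD units; acrophase =
    # clock hour of slowest predicted RT)
    amplitude_ema: float = 0.16
    amplitude_ss: float = 0.34
    acrophase: float = 3.5

    # fatigue rating and its coupling into the EMA occasion effect
    fatigue_mean: float = 42.7
    fatigue_sd_person: float = 15.0
    fatigue_sd_occasion: float = 11.0
    fatigue_coupling: float = 0.03  # log-RT shift per SD of occasion fatigue

    # person covariates
    age_mean: float = 39.8
    age_sd: float = 14.4
    age_range: tuple[float, float] = (18.0, 75.0)
    r_age: float = 0.5  # corr(age, EMA person intercept)
    phq8_mean: float = 5.44
    phq8_sd: float = 4.30

    # contamination and missingness
    careless_rate: float = 0.013
    careless_range: tuple[float, float] = (0.05, 0.19)
    interruption_rate: float = 0.005
    interruption_mean_s: float = 60.0
    missing_rate: float = 0.08

    seed: int = 42

    def __post_init__(self):
        for name in ("p_six_prompts", "careless_rate", "interruption_rate",
                     "missing_rate", "ss_careless_session_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        _check_psd(self._bp_matrix(), "person-level (between) correlation block")
        _check_psd(self._wp_matrix(), "occasion-level (within) correlation block")

    def _bp_corr(self):
        return {
            "ema_ss": self.r_between,
            "ema_gng": self.r_between_gng_ema,
            "ss_gng": self.r_between_gng_ss,
        }

    def _bp_matrix(self) -> np.ndarray:
        r = self._bp_corr()
        return np.array(
            [
                [1.0, r["ema_ss"], r["ema_gng"]],
                [r["ema_ss"], 1.0, r["ss_gng"]],
                [r["ema_gng"], r["ss_gng"], 1.0],
            ]
        )

    def _wp_matrix(self) -> np.ndarray:
        return np.array(
            [
                [1.0, self.r_within, self.r_within_gng_ema],
                [self.r_within, 1.0, self.r_within_gng_ss],
                [self.r_within_gng_ema, self.r_within_gng_ss, 1.0],
            ]
        )

    # ------------------------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @staticmethod
    def from_yaml(path: str | Path) -> "SynthConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("prompts_per_day", "waking_window", "careless_range",
                  "age_range", "measures", "items"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return SynthConfig(**d)

    @staticmethod
    def paper_like(**overrides) -> "SynthConfig":
        """The default preset (components back-solved from the published
        reliability table); keyword overrides applied on top."""
        return replace(SynthConfig(), **overrides)


def _check_psd(mat: np.ndarray, name: str) -> None:
    eig = np.linalg.eigvalsh(mat)
    if eig.min() < -1e-10:
        raise ValueError(
            f"{name} is not positive semi-definite (min eigenvalue {eig.min():.3g})"
        )


@dataclass(frozen=True)
class StudyTruth:
    """Ground-truth parameters actually used by one generation run."""

    config: SynthConfig
    sd_total_ema: float
    sd_total_ss: float
    amplitude_log_ema: float  # cosine amplitude on the log-RT scale
    amplitude_log_ss: float
    # occasion-level variance of EMA log-RT including coupling (cosine signal
    # excluded: it is a fixed effect of hour, approx adds amplitude^2/2)
    effective_sigma2_o_ema: float
    n_occasions: int
    n_records: int


@dataclass(frozen=True)
class SynthStudy:
    records: pd.DataFrame
    covariates: pd.DataFrame
    truth: StudyTruth


def generate_study(config: SynthConfig) -> SynthStudy:
    """Generate the long table, covariates, and the true-parameter record."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    catalog = ItemCatalog.default()
    P = cfg.n_persons

    # --- person level -------------------------------------------------
    bp_sds = np.array(
        [np.sqrt(cfg.sigma2_p_ema), np.sqrt(cfg.sigma2_p_ss), cfg.gng_dprime_sd_person]
    )
    bp_cov = cfg._bp_matrix() * np.outer(bp_sds, bp_sds)
    u = rng.multivariate_normal(np.zeros(3), bp_cov, size=P)
    u_ema, u_ss, u_gng = u.T
    z_ema = u_ema / bp_sds[0] if bp_sds[0] > 0 else np.zeros(P)
    age_noise = rng.standard_normal(P)
    age = cfg.age_mean + cfg.age_sd * (
        cfg.r_age * z_ema + np.sqrt(max(1.0 - cfg.r_age**2, 0.0)) * age_noise
    )
    age = np.clip(np.round(age, 1), *cfg.age_range)
    phq8 = np.clip(
        np.round(cfg.phq8_mean + cfg.phq8_sd * rng.standard_normal(P)), 0, 24
    ).astype(int)
    fat_person = cfg.fatigue_sd_person * rng.standard_normal(P)
    u_gng_rt = np.sqrt(cfg.sigma2_p_gng) * rng.standard_normal(P)

    person_ids = np.array([f"p{i:03d}" for i in range(P)])
    covariates = pd.DataFrame({"person_id": person_ids, "age": age, "phq8": phq8})

    # --- occasion level -----------------------------------------------
    lo, hi = cfg.prompts_per_day
    n_prompts = np.where(
        rng.random((P, cfg.n_days)) < cfg.p_six_prompts, hi, lo
    )  # per person-day
    occ_person = np.repeat(np.arange(P), n_prompts.sum(axis=1))
    day = np.concatenate(
        [np.repeat(np.arange(cfg.n_days), n_prompts[p]) for p in range(P)]
    )
    slot = np.concatenate(
        [np.concatenate([np.arange(k) for k in n_prompts[p]]) for p in range(P)]
    )
    k_of_day = np.concatenate(
        [np.concatenate([np.full(k, k) for k in n_prompts[p]]) for p in range(P)]
    )
    w0, w1 = cfg.waking_window
    width = (w1 - w0) / k_of_day
    hour = w0 + (slot + rng.random(len(slot))) * width
    hour = np.minimum(hour, np.nextafter(24.0, 0.0))
    n_occ = len(occ_person)
    occ_ids = np.array([f"d{d:02d}s{s}" for d, s in zip(day, slot)])

    wp_sds = np.array(
        [np.sqrt(cfg.sigma2_o_ema), np.sqrt(cfg.sigma2_o_ss), cfg.gng_dprime_sd_occasion]
    )
    wp_cov = cfg._wp_matrix() * np.outer(wp_sds, wp_sds)
    v = rng.multivariate_normal(np.zeros(3), wp_cov, size=n_occ)
    v_ema, v_ss, v_gng = v.T
    fat_occ = cfg.fatigue_sd_occasion * rng.standard_normal(n_occ)
    fatigue_value = np.clip(
        np.round(cfg.fatigue_mean + fat_person[occ_person] + fat_occ), 0, 100
    )
    v_gng_rt = np.sqrt(cfg.sigma2_o_gng) * rng.standard_normal(n_occ)

    sd_total_ema = float(
        np.sqrt(cfg.sigma2_p_ema + cfg.sigma2_o_ema + cfg.sigma2_e_ema)
    )
    sd_total_ss = float(np.sqrt(cfg.sigma2_p_ss + cfg.sigma2_o_ss + cfg.sigma2_e_ss))
    amp_ema = cfg.amplitude_ema * sd_total_ema
    amp_ss = cfg.amplitude_ss * sd_total_ss
    cos_signal = np.cos(_OMEGA * (hour - cfg.acrophase))
    if cfg.fatigue_sd_occasion > 0:
        coupling_term = cfg.fatigue_coupling * fat_occ / cfg.fatigue_sd_occasion
    else:
        coupling_term = 0.0
    occ_ema = v_ema + amp_ema * cos_signal + coupling_term
    occ_ss = v_ss + amp_ss * cos_signal

    frames = []

    # --- EMA rows ------------------------------------------------------
    if "EMA" in cfg.measures:
        if cfg.items is not None:
            unknown = set(cfg.items) - set(catalog.item_ids())
            if unknown:
                raise ValueError(f"unknown item id(s) in config: {sorted(unknown)}")
            item_ids = np.array(list(cfg.items))
        else:
            item_ids = np.array(catalog.item_ids())
        rtypes = np.array([catalog.items[i].response_type.value for i in item_ids])
        mu_item = np.full(len(item_ids), cfg.mu_log_rt_ema)
        mu_item[rtypes == ResponseType.multiple_choice.value] += cfg.mu_offset_mc
        mu_item[rtypes == ResponseType.checkbox.value] += cfg.mu_offset_checkbox
        e_sd_item = np.full(len(item_ids), np.sqrt(cfg.sigma2_e_ema))
        e_sd_item[rtypes == ResponseType.multiple_choice.value] *= np.sqrt(
            cfg.e_var_multiplier_mc
        )
        e_sd_item[rtypes == ResponseType.checkbox.value] *= np.sqrt(
            cfg.e_var_multiplier_checkbox
        )
        n_items = len(item_ids)
        occ_idx = np.repeat(np.arange(n_occ), n_items)
        item_idx = np.tile(np.arange(n_items), n_occ)
        log_rt = (
            mu_item[item_idx]
            + u_ema[occ_person[occ_idx]]
            + occ_ema[occ_idx]
            + e_sd_item[item_idx] * rng.standard_normal(len(occ_idx))
        )
        rt = np.exp(log_rt)
        # contamination (EMA only)
        careless = rng.random(len(rt)) < cfg.careless_rate
        rt[careless] = rng.uniform(*cfg.careless_range, size=careless.sum())
        interrupted = (rng.random(len(rt)) < cfg.interruption_rate) & ~careless
        rt[interrupted] += rng.exponential(
            cfg.interruption_mean_s, size=interrupted.sum()
        )
        response_value = np.full(len(rt), np.nan)
        fat_pos = np.flatnonzero(item_ids == "fatigue")
        if fat_pos.size:
            fmask = item_idx == fat_pos[0]
            response_value[fmask] = fatigue_value[occ_idx[fmask]]
        frames.append(
            _make_frame(
                person_ids[occ_person[occ_idx]],
                occ_ids[occ_idx],
                hour[occ_idx],
                Measure.EMA.value,
                item_ids[item_idx],
                np.round(rt, 3),
                correct=None,
                is_target=None,
                response_value=response_value,
            )
        )

    # --- Symbol Search rows -------------------------------------------
    if "SYMBOL_SEARCH" in cfg.measures:
        T = cfg.n_ss_trials
        occ_idx = np.repeat(np.arange(n_occ), T)
        trial = np.tile(np.arange(T), n_occ)
        log_rt = (
            cfg.mu_log_rt_ss
            + u_ss[occ_person[occ_idx]]
            + occ_ss[occ_idx]
            + np.sqrt(cfg.sigma2_e_ss) * rng.standard_normal(len(occ_idx))
        )
        careless_session = rng.random(n_occ) < cfg.ss_careless_session_rate
        p_correct = np.where(careless_session, cfg.ss_careless_accuracy, cfg.ss_accuracy)
        correct = rng.random(len(occ_idx)) < p_correct[occ_idx]
        frames.append(
            _make_frame(
                person_ids[occ_person[occ_idx]],
                occ_ids[occ_idx],
                hour[occ_idx],
                Measure.SYMBOL_SEARCH.value,
                np.array([f"t{t:02d}" for t in range(T)])[trial],
                np.round(np.exp(log_rt), 3),
                correct=correct,
                is_target=None,
                response_value=None,
            )
        )

    # --- Go-No Go rows -------------------------------------------------
    if "GO_NO_GO" in cfg.measures:
        T = cfg.n_gng_trials
        occ_idx = np.repeat(np.arange(n_occ), T)
        trial = np.tile(np.arange(T), n_occ)
        is_target = trial < cfg.n_gng_targets
        dprime = cfg.gng_dprime_mean + u_gng[occ_person[occ_idx]] + v_gng[occ_idx]
        from scipy.stats import norm

        p_tap = np.where(
            is_target,
            norm.cdf(dprime / 2.0 + cfg.gng_criterion),
            norm.cdf(cfg.gng_criterion - dprime / 2.0),
        )
        tapped = rng.random(len(occ_idx)) < p_tap
        correct = tapped == is_target
        log_rt = (
            cfg.mu_log_rt_gng
            + u_gng_rt[occ_person[occ_idx]]
            + v_gng_rt[occ_idx]
            + np.sqrt(cfg.sigma2_e_gng) * rng.standard_normal(len(occ_idx))
        )
        frames.append(
            _make_frame(
                person_ids[occ_person[occ_idx]],
                occ_ids[occ_idx],
                hour[occ_idx],
                Measure.GO_NO_GO.value,
                np.array([f"g{t:02d}" for t in range(T)])[trial],
                np.round(np.exp(log_rt), 3),
                correct=correct,
                is_target=is_target,
                response_value=None,
            )
        )

    records = pd.concat(frames, ignore_index=True)
    if cfg.missing_rate > 0:
        keep = rng.random(len(records)) >= cfg.missing_rate
        records = records.loc[keep].reset_index(drop=True)

    truth = StudyTruth(
        config=cfg,
        sd_total_ema=sd_total_ema,
        sd_total_ss=sd_total_ss,
        amplitude_log_ema=float(amp_ema),
        amplitude_log_ss=float(amp_ss),
        effective_sigma2_o_ema=float(cfg.sigma2_o_ema + cfg.fatigue_coupling**2),
        n_occasions=n_occ,
        n_records=len(records),
    )
    return SynthStudy(records=records, covariates=covariates, truth=truth)


def _make_frame(
    person, occasion, hour, measure, item, rt, *, correct, is_target, response_value
) -> pd.DataFrame:
    n = len(rt)
    rt = np.maximum(rt, 0.001)  # 3-decimal recording floor; RTs must stay positive
    df = pd.DataFrame(
        {
            "person_id": person,
            "occasion_id": occasion,
            "timestamp_hour": hour,
            "measure": measure,
            "item_id": item,
            "rt_seconds": rt,
            "correct": pd.array(
                correct if correct is not None else [None] * n, dtype="boolean"
            ),
            "is_target": pd.array(
                is_target if is_target is not None else [None] * n, dtype="boolean"
            ),
            "response_value": response_value
            if response_value is not None
            else np.full(n, np.nan),
            "valid": np.ones(n, dtype=bool),
        },
        columns=RT_COLUMNS,
    )
    return df


def true_params_report(truth: StudyTruth) -> pd.DataFrame:
    """Machine-readable ground truth for recovery tests (parameter, value)."""
    cfg = truth.config
    rows = {
        "sigma2_p_ema": cfg.sigma2_p_ema,
        "sigma2_o_ema": cfg.sigma2_o_ema,
        "sigma2_e_ema": cfg.sigma2_e_ema,
        "sigma2_p_ss": cfg.sigma2_p_ss,
        "sigma2_o_ss": cfg.sigma2_o_ss,
        "sigma2_e_ss": cfg.sigma2_e_ss,
        "r_between": cfg.r_between,
        "r_within": cfg.r_within,
        "amplitude_ema": cfg.amplitude_ema,
        "amplitude_ss": cfg.amplitude_ss,
        "acrophase": cfg.acrophase,
        "fatigue_coupling": cfg.fatigue_coupling,
        "r_age": cfg.r_age,
        "sd_total_ema": truth.sd_total_ema,
        "sd_total_ss": truth.sd_total_ss,
        "amplitude_log_ema": truth.amplitude_log_ema,
        "amplitude_log_ss": truth.amplitude_log_ss,
        "effective_sigma2_o_ema": truth.effective_sigma2_o_ema,
        "n_occasions": truth.n_occasions,
        "n_records": truth.n_records,
        "seed": cfg.seed,
    }
    return pd.DataFrame({"parameter": list(rows), "value": list(rows.values())})
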