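import numpy as np
import pandas as pd
import pytest

from ema_rt.datamodel import Measure, RT_COLUMNS
from ema_rt.synthgen import SynthConfig, generate_study


def make_frame(rows):
    """Build a long-table frame from dicts with defaults filled in."""
    defaults = {
        "person_id": "p0",
        "occasion_id": "o0",
        "timestamp_hour": 10.0,
        "measure": Measure.EMA.value,
        "item_id": "pa_happy",
        "rt_seconds": 1.0,
        "correct": None,
        "is_target": None,
        "response_value": np.nan,
        "valid": True,
    }
    full = [{**defaults, **r} for r in rows]
    df = pd.DataFrame(full, columns=RT_COLUMNS)
    df["correct"] = pd.array(df["correct"], dtype="boolean")
    df["is_target"] = pd.array(df["is_target"], dtype="boolean")
    df["response_value"] = df["response_value"].astype(float)
    return df


def simulate_nested(seed, P, O, I, s2p, s2o, s2e, mu=0.0):
    """Direct three-level Gaussian simulation (independent of synthgen)."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, np.sqrt(s2p), P)
    v = rng.normal(0.0, np.sqrt(s2o), (P, O))
    e = rng.normal(0.0, np.sqrt(s2e), (P, O, I))
    y = mu + u[:, None, None] + v[:, :, None] + e
    person = np.repeat(np.arange(P), O * I)
    occasion = np.tile(np.repeat(np.arange(O), I), P)
    return person, occasion, y.ravel()


@pytest.fixture(scope="session")
def clean_study():
    """Small contamination-free EMA+SS study shared across model tests."""
    cfg = SynthConfig(
        n_persons=50,
        n_days=4,
        prompts_per_day=(5, 5),
        p_six_prompts=0.0,
        measures=("EMA", "SYMBOL_SEARCH"),
        careless_rate=0.0,
        interruption_rate=0.0,
        missing_rate=0.0,
        amplitude_ema=0.0,
        amplitude_ss=0.0,
        fatigue_coupling=0.0,
        seed=2024,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def default_small_study():
    """Default preset scaled down, contamination included."""
    cfg = SynthConfig(n_persons=25, n_days=4, seed=99)
    return generate_study(cfg)
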