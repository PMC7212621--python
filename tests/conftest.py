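import numpy as np
import pandas as pd
import pytest

from diarycal import GeneratorConfig, generate_cohort, deduplicate, window_entries, collapse_weeks


@pytest.fixture(scope="session")
def small_cohort():
    """Default-mechanism cohort, small enough for fast unit tests."""
    cfg = GeneratorConfig(n_participants=120, seed=42)
    participants, diary, latent = generate_cohort(cfg)
    return cfg, participants, diary, latent


@pytest.fixture(scope="session")
def full_cohort():
    """Fully observed cohort: the diary equals the latent truth."""
    cfg = GeneratorConfig(n_participants=60, seed=7, entry_mechanism="full", followup_jitter_days=0)
    participants, diary, latent = generate_cohort(cfg)
    return cfg, participants, diary, latent


@pytest.fixture(scope="session")
def small_weeks(small_cohort):
    _, participants, diary, _ = small_cohort
    entries = window_entries(deduplicate(diary), participants)
    return entries, collapse_weeks(entries, participants), participants


def make_participants(n=3, duration=70, start="2020-01-01"):
    base = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(1, n + 1)],
            "sex": ["female", "male"] * (n // 2) + ["female"] * (n % 2),
            "baseline_date": [base] * n,
            "followup_date": [base + pd.Timedelta(days=duration)] * n,
            "baseline_tlfb": [20.0] * n,
            "followup_tlfb": [10.0] * n,
            "audit_baseline": [15] * n,
            "audit_followup": [12] * n,
        }
    )


def make_entries(rows):
    """rows: list of (pid, day_offset_or_date, drinks) with dates as strings allowed."""
    recs = []
    for pid, when, drinks in rows:
        date = pd.Timestamp("2020-01-01") + pd.Timedelta(days=when) if isinstance(when, int) else pd.Timestamp(when)
        recs.append({"participant_id": pid, "date": date, "drinks": float(drinks)})
    return pd.DataFrame(recs)
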