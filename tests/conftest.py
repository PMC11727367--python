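import numpy as np
import pandas as pd
import pytest

from emomem.trial_io import TRIAL_COLUMNS, validate_trials
from emomem.synthetic_data import (
    CategoryTruth,
    GroundTruth,
    SimulationConfig,
    StudyGroupBlock,
)

CATS3 = ("pleasant", "unpleasant", "neutral")


def trials_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble raw row dicts into a validated trial table."""
    df = pd.DataFrame(rows)
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return validate_trials(df[TRIAL_COLUMNS])


def make_row(**kw) -> dict:
    row = {
        "participant_id": "p1",
        "study": "S2",
        "group": "control",
        "environment": "EEG",
        "encoding_instruction": "binding",
        "retrieval_task": "remember_know",
        "n_new_items": 3,
        "item_id": "i1",
        "item_status": "old",
        "context_category": "neutral",
        "recognition_response": "remember",
        "source_response": "neutral",
    }
    row.update(kw)
    return row


@pytest.fixture
def rk_participant_trials() -> pd.DataFrame:
    """One Remember/Know participant: 4 old neutral + 2 old pleasant + 3 new.

    Hand-auditable: of the 4 neutral items, 3 are judged know (2 attributed
    neutral, 1 pleasant) and 1 remember (attributed neutral); both pleasant
    items are judged remember (1 correct, 1 attributed neutral); of the 3
    new items, 1 draws a know false alarm attributed pleasant.
    """
    rows = [
        make_row(item_id="o1", context_category="neutral",
                 recognition_response="know", source_response="neutral"),
        make_row(item_id="o2", context_category="neutral",
                 recognition_response="know", source_response="neutral"),
        make_row(item_id="o3", context_category="neutral",
                 recognition_response="know", source_response="pleasant"),
        make_row(item_id="o4", context_category="neutral",
                 recognition_response="remember", source_response="neutral"),
        make_row(item_id="o5", context_category="pleasant",
                 recognition_response="remember", source_response="pleasant"),
        make_row(item_id="o6", context_category="pleasant",
                 recognition_response="remember", source_response="neutral"),
        make_row(item_id="n1", item_status="new", context_category=None,
                 recognition_response="know", source_response="pleasant"),
        make_row(item_id="n2", item_status="new", context_category=None,
                 recognition_response="new", source_response=None),
        make_row(item_id="n3", item_status="new", context_category=None,
                 recognition_response="new", source_response=None),
    ]
    return trials_frame(rows)


def flat_truth(r=0.35, f=0.8, rho_rec=0.55, rho_fam=0.40, *, epsilon=0.02,
               criterion=1.0, sigma_participant=0.0, sigma_studygroup=0.0,
               categories=CATS3, **per_category) -> GroundTruth:
    """Ground truth with identical parameters per category unless overridden.

    ``per_category`` accepts e.g. ``r_pleasant=0.5`` to override one field of
    one category.
    """
    cats = {}
    for c in categories:
        kw = {"r": r, "f": f, "rho_rec": rho_rec, "rho_fam": rho_fam}
        for field in list(kw):
            if f"{field}_{c}" in per_category:
                kw[field] = per_category[f"{field}_{c}"]
        cats[c] = CategoryTruth(**kw)
    return GroundTruth(categories=cats, epsilon=epsilon, criterion_know=criterion,
                       sigma_participant=sigma_participant,
                       sigma_studygroup=sigma_studygroup)


def one_block_config(truth: GroundTruth, *, n_participants=10, task="remember_know",
                     n_old=20, n_new=30, categories=CATS3, seed=0,
                     group="control") -> SimulationConfig:
    block = StudyGroupBlock("S2", group, n_participants, task, "binding", "EEG",
                            tuple(categories), n_old, n_new)
    return SimulationConfig(design=(block,), truth=truth, seed=seed)


@pytest.fixture
def small_sim_table() -> pd.DataFrame:
    """Scored index table from a small two-block simulation (seeded)."""
    from emomem.synthetic_data import simulate_trials
    from emomem.indices import build_index_table

    truth = flat_truth(sigma_participant=0.3)
    blocks = (
        StudyGroupBlock("S2", "control", 12, "remember_know", "free_viewing",
                        "EEG", CATS3, 20, 40),
        StudyGroupBlock("S5", "control", 12, "remember_know", "binding",
                        "MRI", CATS3, 20, 40),
    )
    cfg = SimulationConfig(design=blocks, truth=truth, seed=20)
    trials, _ = simulate_trials(cfg)
    return build_index_table(trials)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
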