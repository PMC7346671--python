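import numpy as np
import pandas as pd
import pytest

from sbpatterns.containers import ClassCode, ClassifiedDay, EPOCHS_PER_DAY
from sbpatterns.synthetic import PFModelTruth, default_config


def make_day(
    participant_id="P0",
    date="2024-01-01",
    wake=420.0,
    bed=1320.0,
    sedentary_minutes=None,
    nonwear_minutes=(),
    mvpa_minutes=(),
):
    """Build a ClassifiedDay from minute-level descriptions.

    ``sedentary_minutes`` is an iterable of minute-of-day indices classified
    sedentary; awake minutes not listed are light. In-bed windows follow
    the wake/bed clock times.
    """
    classes = np.full(1440, int(ClassCode.LIGHT), dtype=np.int8)
    classes[: int(wake)] = int(ClassCode.INBED)
    classes[int(bed):] = int(ClassCode.INBED)
    if sedentary_minutes is not None:
        classes[np.asarray(list(sedentary_minutes), int)] = int(ClassCode.SEDENTARY)
    if mvpa_minutes:
        classes[np.asarray(list(mvpa_minutes), int)] = int(ClassCode.MVPA)
    if nonwear_minutes:
        classes[np.asarray(list(nonwear_minutes), int)] = int(ClassCode.NONWEAR)
    epoch_classes = np.repeat(classes, 4)
    assert epoch_classes.shape == (EPOCHS_PER_DAY,)
    return ClassifiedDay(
        participant_id=participant_id,
        date=pd.Timestamp(date),
        epoch_classes=epoch_classes,
        wake_minutes=float(wake),
        bed_minutes=float(bed),
    )


@pytest.fixture
def clean_config():
    """Deterministic, noise- and missingness-free generator configuration."""
    return default_config(
        n_participants=1,
        archetype_noise_sd=0.0,
        wake_time_sd_min=0.0,
        sleep_time_sd_min=0.0,
        sleeplog_missing_rate=0.0,
        full_sleeplog_missing_rate=0.0,
        nonwear_bout_rate=0.0,
        nonadherent_day_rate=0.0,
        low_adherence_participant_rate=0.0,
        inbed_nonzero_rate=0.0,
        covariate_missing_rate=0.0,
        mvpa_day_sd=0.0,
        pattern_mixtures=[[1.0, 0.0, 0.0, 0.0]] * 4,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A moderately sized default-configuration cohort shared across tests."""
    from sbpatterns.synthetic import generate_cohort

    cfg = default_config(n_participants=120, seed=17)
    return cfg, generate_cohort(cfg)
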