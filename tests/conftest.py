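import numpy as np
import pandas as pd
import pytest

from actispiro.accelerometry import process_participants
from actispiro.activity_density import cohort_densities
from actispiro.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12 participants, full 9-day 5-s epoch recordings."""
    cfg = CohortConfig(
        n_participants=12,
        seed=7,
        group_proportions=(0.25, 0.25, 0.25, 0.25),
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def processed(small_cohort):
    cfg, cohort = small_cohort
    return process_participants(cohort.epoch_table, cohort.sleep_log, n_days=cfg.n_days)


@pytest.fixture(scope="session")
def densities(processed):
    return cohort_densities(processed["waking"], processed["summary"])


@pytest.fixture(scope="session")
def fof_grids():
    x_grid = np.linspace(0.0, 0.30, 40)
    t_grid = np.arange(0.05, 6.001, 0.05)
    return x_grid, t_grid


def make_day_epochs(participant_id, day_index, accs, worn=None, start_s=7 * 3600,
                    epoch_s=5.0):
    """Helper: one day's epoch frame starting at ``start_s``."""
    n = len(accs)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "day_index": day_index,
            "epoch_start_s": start_s + epoch_s * np.arange(n),
            "acc_g": np.asarray(accs, dtype=float),
            "worn": np.ones(n, dtype=bool) if worn is None else np.asarray(worn),
        }
    )


def make_sleep_log(participant_id, days, weekdays, wake_s=7 * 3600, onset_s=23 * 3600):
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "day_index": days,
            "weekday": weekdays,
            "wake_onset_s": wake_s,
            "sleep_onset_s": onset_s,
        }
    )
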