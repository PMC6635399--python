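import numpy as np
import pandas as pd
import pytest

from actispiro.accelerometry import (
    classify_epochs,
    correct_nonwear,
    extract_waking_epochs,
    select_participants,
    summarize_activity,
    validate_days,
)
from conftest import make_day_epochs, make_sleep_log


class TestClassification:
    @pytest.mark.parametrize(
        "acc,level",
        [
            (0.02, 0),  # below the 0.03 g sedentary bound
            (0.05, 1),  # light range
            (0.03, 1),  # light bound is inclusive
            (0.10, 2),  # MVPA bound is inclusive
            (0.0999, 1),
            (0.5, 2),
            (0.0, 0),
        ],
    )
    def test_cutpoints(self, acc, level):
        assert classify_epochs(np.array([acc]))[0] == level

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            classify_epochs(np.array([-0.01]))

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(3)
        acc = rng.lognormal(np.log(0.03), 1.2, 100_000)
        fast = classify_epochs(acc)
        slow = np.array(
            [0 if a < 0.03 else (2 if a >= 0.10 else 1) for a in acc], dtype=np.int8
        )
        assert np.array_equal(fast, slow)

    def test_raising_mvpa_cut_never_increases_mvpa(self):
        rng = np.random.default_rng(4)
        acc = rng.lognormal(np.log(0.04), 1.0, 5000)
        counts = [
            (classify_epochs(acc, mvpa_cut=c) == 2).sum()
            for c in (0.08, 0.10, 0.12, 0.2)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestWakingExtraction:
    def test_window_minutes_and_boundaries(self):
        # full-day epochs; waking window 07:00-23:00 => 960 min
        n_day = 17280
        frames = [
            make_day_epochs(1, d, np.full(n_day, 0.05), start_s=0.0)
            for d in (1, 2, 3)
        ]
        epochs = pd.concat(frames)
        sleep = make_sleep_log(1, [1, 2, 3], [0, 1, 2])
        waking = extract_waking_epochs(epochs, sleep, n_days=3)
        assert set(waking["day_index"]) == {2}  # first and last days dropped
        assert len(waking) * 5 / 60 == 960
        # half-open window: epoch at sleep onset excluded, at wake included
        assert waking["epoch_start_s"].min() == 7 * 3600
        assert waking["epoch_start_s"].max() == 23 * 3600 - 5

    def test_nine_days_yield_seven(self):
        frames = [
            make_day_epochs(1, d, np.full(100, 0.05)) for d in range(1, 10)
        ]
        sleep = make_sleep_log(1, list(range(1, 10)), [d % 7 for d in range(1, 10)])
        waking = extract_waking_epochs(pd.concat(frames), sleep, n_days=9)
        assert sorted(waking["day_index"].unique()) == [2, 3, 4, 5, 6, 7, 8]

    def test_missing_sleep_log_day_dropped_and_invalid(self):
        frames = [make_day_epochs(1, d, np.full(100, 0.05)) for d in (1, 2, 3, 4)]
        sleep = make_sleep_log(1, [1, 2, 4], [0, 1, 3])  # day 3 missing
        waking = extract_waking_epochs(pd.concat(frames), sleep, n_days=4)
        assert 3 not in set(waking["day_index"])


class TestValidity:
    def _one_day(self, wear_fraction, day=2, weekday=0):
        n = 300
        worn = np.zeros(n, dtype=bool)
        worn[: int(round(wear_fraction * n))] = True
        epochs = make_day_epochs(1, day, np.full(n, 0.05), worn=worn)
        sleep = make_sleep_log(1, [day], [weekday],
                               wake_s=7 * 3600, onset_s=7 * 3600 + n * 5)
        sleep["day_index"] = day
        return epochs, sleep

    @pytest.mark.parametrize("frac,valid", [(0.70, True), (2 / 3, True), (0.60, False)])
    def test_wear_fraction_rule(self, frac, valid):
        epochs, sleep = self._one_day(frac)
        sleep = pd.concat([sleep, make_sleep_log(1, [1, 3], [6, 1])])
        v = validate_days(epochs, sleep, n_days=3)
        assert bool(v.loc[v["day_index"] == 2, "valid"].iloc[0]) is valid

    @pytest.mark.parametrize(
        "n_wd,n_we,included",
        [(2, 2, True), (5, 1, False), (1, 2, False), (7, 0, False), (3, 2, True)],
    )
    def test_selection_rule(self, n_wd, n_we, included):
        rows = []
        for i in range(n_wd):
            rows.append({"participant_id": 1, "day_index": i + 2, "is_weekend": False,
                         "waking_minutes": 960.0, "wear_fraction_waking": 1.0, "valid": True})
        for i in range(n_we):
            rows.append({"participant_id": 1, "day_index": 20 + i, "is_weekend": True,
                         "waking_minutes": 960.0, "wear_fraction_waking": 1.0, "valid": True})
        sel = select_participants(pd.DataFrame(rows))
        assert bool(sel["included"].iloc[0]) is included
        if not included:
            assert sel["reason"].iloc[0] != ""


class TestNonwearCorrection:
    def _two_day_setup(self, gap_len=360):
        n = 1000
        d2 = make_day_epochs(1, 2, np.full(n, 0.05))
        worn = np.ones(n, dtype=bool)
        worn[100 : 100 + gap_len] = False
        d3 = make_day_epochs(1, 3, np.full(n, 0.09), worn=worn)
        epochs = pd.concat([d2, d3])
        validities = pd.DataFrame(
            {
                "participant_id": [1, 1],
                "day_index": [2, 3],
                "is_weekend": [False, True],
                "waking_minutes": [n * 5 / 60.0] * 2,
                "wear_fraction_waking": [1.0, 1 - gap_len / n],
                "valid": [True, True],
            }
        )
        return epochs, validities, gap_len

    def test_fully_worn_unchanged(self):
        epochs, validities, _ = self._two_day_setup(gap_len=0)
        out = correct_nonwear(epochs, validities)
        assert not out["imputed"].any()
        assert np.allclose(
            out.sort_values(["day_index", "epoch_start_s"])["acc_g"],
            epochs.sort_values(["day_index", "epoch_start_s"])["acc_g"],
        )

    def test_gap_filled_with_same_slot_mean(self):
        # other day holds constant 0.05 at those clock slots
        epochs, validities, gap = self._two_day_setup()
        out = correct_nonwear(epochs, validities)
        filled = out[out["imputed"]]
        assert len(filled) == gap
        assert np.allclose(filled["acc_g"], 0.05)

    def test_imputed_bookkeeping_matches_direct_count(self):
        epochs, validities, gap = self._two_day_setup(gap_len=123)
        out = correct_nonwear(epochs, validities)
        direct = int((~epochs["worn"]).sum())
        assert int(out["imputed"].sum()) == direct == 123


class TestSummaries:
    def _per_day_table(self, wd_mvpa, we_mvpa):
        frames, rows = [], []
        day = 2
        for m in wd_mvpa:
            rows.append((day, False, m))
            day += 1
        for m in we_mvpa:
            rows.append((day, True, m))
            day += 1
        for day_index, weekend, mvpa_min in rows:
            n_mvpa = int(mvpa_min * 12)  # 12 five-second epochs per minute
            n_rest = 240
            acc = np.concatenate([np.full(n_mvpa, 0.2), np.full(n_rest, 0.01)])
            frames.append(make_day_epochs(1, day_index, acc))
        epochs = pd.concat(frames)
        validities = pd.DataFrame(
            {
                "participant_id": 1,
                "day_index": [r[0] for r in rows],
                "is_weekend": [r[1] for r in rows],
                "waking_minutes": 999.0,
                "wear_fraction_waking": 1.0,
                "valid": True,
            }
        )
        return epochs, validities

    def test_five_two_reweighting_hand_computed(self):
        epochs, validities = self._per_day_table([60, 60, 60], [80, 80])
        summ = summarize_activity(epochs, validities)
        assert summ["mvpa_min"].iloc[0] == pytest.approx((5 * 60 + 2 * 80) / 7)

    def test_plain_mean_when_all_seven_valid(self):
        epochs, validities = self._per_day_table([55] * 5, [55] * 2)
        summ = summarize_activity(epochs, validities)
        assert summ["mvpa_min"].iloc[0] == pytest.approx(55.0)

    def test_reweighting_equals_plain_mean_when_equal(self):
        epochs, validities = self._per_day_table([70, 70], [70, 70])
        summ = summarize_activity(epochs, validities)
        assert summ["mvpa_min"].iloc[0] == pytest.approx(70.0)

    def test_levels_partition_waking(self, processed):
        s = processed["summary"]
        total = s["sedentary_min"] + s["light_min"] + s["mvpa_min"]
        assert np.allclose(total, s["waking_min"], atol=1e-6)

    def test_raises_without_weekend_days(self):
        epochs, validities = self._per_day_table([60, 60], [])
        with pytest.raises(ValueError, match="excluded"):
            summarize_activity(epochs, validities)
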