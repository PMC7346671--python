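"""Preprocessing chain: minute aggregation, Choi non-wear, bed times,
cutpoint classification, adherence filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbpatterns.containers import ClassCode, EpochSeries, EPOCHS_PER_DAY
from sbpatterns.preprocessing import (
    aggregate_minutes,
    choi_nonwear,
    classify_epochs,
    filter_cohort,
    resolve_bed_times,
)
from sbpatterns.pipeline import preprocess_cohort
from sbpatterns.preprocessing import CHOI_WINDOW_MIN

from conftest import make_day


def series_from_counts(counts, pid="P0"):
    return EpochSeries(pid, pd.Timestamp("2024-01-01"), np.asarray(counts, np.int32))


def minutes_to_epochs(minute_counts):
    """Spread minute-level totals into 4 epochs/minute (all in epoch 0)."""
    out = np.zeros(len(minute_counts) * 4, dtype=np.int32)
    out[::4] = minute_counts
    return out


class TestAggregateMinutes:
    def test_sums_four_epochs(self):
        assert aggregate_minutes(series_from_counts([10, 10, 10, 10]))[0] == 40

    def test_zeros_stay_zero(self):
        assert np.all(aggregate_minutes(series_from_counts([0] * 40)) == 0)

    def test_partial_trailing_minute_dropped(self):
        out = aggregate_minutes(series_from_counts([1] * 10))
        assert out.shape == (2,)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_groupby_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 600, 4 * 300)
        s = series_from_counts(counts)
        frame = s.to_frame()
        oracle = (
            frame.set_index("timestamp")["vm_counts"].resample("1min").sum().to_numpy()
        )
        assert np.array_equal(aggregate_minutes(s), oracle)


class TestChoiNonwear:
    def test_spike_tolerated_inside_long_zero_run(self):
        # 100 zeros | 1 nonzero | 100 zeros, bounded by activity: the spike
        # is flanked by >=30 zeros each side, so the whole 201-min span is
        # non-wear.
        m = np.array([500] * 10 + [0] * 100 + [50] + [0] * 100 + [500] * 10)
        nw = choi_nonwear(m)
        assert not nw[:10].any() and not nw[-10:].any()
        assert nw[10:211].all() and nw.sum() == 201

    def test_89_minutes_below_window_is_wear(self):
        m = np.array([500] * 5 + [0] * 89 + [500] * 5)
        assert not choi_nonwear(m).any()

    def test_90_minutes_is_nonwear(self):
        m = np.array([500] * 5 + [0] * CHOI_WINDOW_MIN + [500] * 5)
        nw = choi_nonwear(m)
        assert nw[5:95].all() and nw.sum() == 90

    def test_three_minute_interruption_splits_runs(self):
        # Interruption exceeds the 2-min tolerance: sides evaluated
        # separately; 100 >= 90 -> non-wear, 80 < 90 -> wear.
        m = np.array([500] * 5 + [0] * 100 + [60, 60, 60] + [0] * 80 + [500] * 5)
        nw = choi_nonwear(m)
        assert nw[5:105].all()
        assert not nw[105:108].any()
        assert not nw[108:].any()

    def test_short_flank_not_tolerated(self):
        # Left zero run of 29 < 30-min stream frame: spike not tolerated;
        # only the right 100-min run qualifies.
        m = np.array([500] * 5 + [0] * 29 + [50] + [0] * 100 + [500] * 5)
        nw = choi_nonwear(m)
        assert not nw[5:35].any()
        assert nw[35:135].all()

    def test_idempotent_after_zeroing_detected_nonwear(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 300, 2000)
        m[200:400] = 0
        m[300] = 17  # tolerated spike
        nw = choi_nonwear(m)
        zeroed = m.copy()
        zeroed[nw] = 0
        assert np.array_equal(choi_nonwear(zeroed), nw)

    def test_invariant_to_prepending_worn_day(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 300, 1000)
        m[100:350] = 0
        prefix = rng.integers(1, 300, 1440)
        assert np.array_equal(choi_nonwear(np.concatenate([prefix, m]))[1440:], choi_nonwear(m))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            choi_nonwear(np.array([]))


class TestResolveBedTimes:
    @staticmethod
    def logs(rows):
        return pd.DataFrame(rows, columns=["participant_id", "date", "in_bed", "out_of_bed"])

    def test_mean_of_available_times(self):
        logs = self.logs(
            [
                ("P0", "2024-01-01", "22:00", "07:00"),
                ("P0", "2024-01-02", "23:00", "07:00"),
                ("P0", "2024-01-03", "", "07:00"),
            ]
        )
        out = resolve_bed_times(logs)
        assert out.loc[2, "in_bed"] == pytest.approx(22.5 * 60)
        assert out.loc[2, "in_bed_imputed"]

    def test_population_constants_when_all_missing(self):
        logs = self.logs([("P0", "2024-01-01", "", ""), ("P0", "2024-01-02", "", "")])
        out = resolve_bed_times(logs)
        assert (out["in_bed"] == 22 * 60 + 45).all()
        assert (out["out_of_bed"] == 7 * 60 + 22).all()

    def test_no_missing_is_identity(self):
        logs = self.logs(
            [("P0", "2024-01-01", "22:15", "06:45"), ("P0", "2024-01-02", "23:05", "07:30")]
        )
        out = resolve_bed_times(logs)
        assert out["in_bed"].tolist() == [22 * 60 + 15, 23 * 60 + 5]
        assert not out["in_bed_imputed"].any()

    def test_circular_mean_across_midnight(self):
        logs = self.logs(
            [
                ("P0", "2024-01-01", "23:30", "07:00"),
                ("P0", "2024-01-02", "00:30", "07:00"),
                ("P0", "2024-01-03", "", "07:00"),
            ]
        )
        out = resolve_bed_times(logs)
        assert out.loc[2, "in_bed"] % 1440 == pytest.approx(0.0, abs=1e-9)


class TestClassifyEpochs:
    @staticmethod
    def one_day_series(fill=100):
        counts = np.full(EPOCHS_PER_DAY, fill, dtype=np.int32)
        return EpochSeries("P0", pd.Timestamp("2024-01-01"), counts)

    @staticmethod
    def bed_times():
        return pd.DataFrame(
            {
                "participant_id": ["P0"],
                "date": [pd.Timestamp("2024-01-01")],
                "in_bed": [22 * 60.0],
                "out_of_bed": [6 * 60.0],
            }
        )

    @pytest.mark.parametrize(
        "count,expected",
        [
            (18, ClassCode.SEDENTARY),  # boundary: at the sedentary cutpoint
            (519, ClassCode.LIGHT),  # boundary: not yet above the MVPA cutpoint
            (520, ClassCode.MVPA),
            (0, ClassCode.SEDENTARY),
        ],
    )
    def test_cutpoint_boundaries(self, count, expected):
        s = self.one_day_series()
        s.counts[12 * 240] = count  # noon epoch, awake and worn
        wear = np.ones(1440, dtype=bool)
        [day] = classify_epochs(s, wear, self.bed_times())
        assert day.epoch_classes[12 * 240] == int(expected)

    def test_inbed_takes_precedence_over_intensity_and_nonwear(self):
        s = self.one_day_series()
        wear = np.ones(1440, dtype=bool)
        wear[:120] = False  # non-wear inside the in-bed window
        [day] = classify_epochs(s, wear, self.bed_times())
        assert (day.epoch_classes[: 6 * 240] == int(ClassCode.INBED)).all()
        assert (day.epoch_classes[22 * 240 :] == int(ClassCode.INBED)).all()

    def test_class_partition_covers_day(self):
        s = self.one_day_series()
        wear = np.ones(1440, dtype=bool)
        wear[600:700] = False
        [day] = classify_epochs(s, wear, self.bed_times())
        assert sum(day.class_counts().values()) == EPOCHS_PER_DAY

    def test_wear_mask_must_cover_span(self):
        s = self.one_day_series()
        with pytest.raises(ValueError):
            classify_epochs(s, np.ones(100, dtype=bool), self.bed_times())


class TestFilterCohort:
    def test_below_four_adherent_days_excluded(self):
        days = [make_day(date=f"2024-01-0{i}") for i in range(1, 4)]
        assert filter_cohort(days).participants == []

    def test_exactly_four_600min_days_included(self):
        # wake 06:00, bed 16:00 -> exactly 600 awake-wear minutes
        days = [make_day(date=f"2024-01-0{i}", wake=360, bed=960) for i in range(1, 5)]
        assert all(d.awake_wear_minutes == 600 for d in days)
        summary = filter_cohort(days)
        assert summary.participants == ["P0"]
        assert len(summary.days) == 4

    def test_all_adherent_identity(self):
        days = [
            make_day(participant_id=p, date=f"2024-01-0{i}")
            for p in ("P0", "P1")
            for i in range(1, 6)
        ]
        summary = filter_cohort(days)
        assert summary.participants == ["P0", "P1"]
        assert summary.n_days_input == len(summary.days)

    def test_participant_means_are_day_averages(self):
        days = [
            make_day(date="2024-01-01", sedentary_minutes=range(420, 720)),
            make_day(date="2024-01-02", sedentary_minutes=range(420, 820)),
            make_day(date="2024-01-03", sedentary_minutes=range(420, 920)),
            make_day(date="2024-01-04", sedentary_minutes=range(420, 1020)),
        ]
        means = filter_cohort(days).participant_means
        assert means.loc[0, "total_sedentary_min"] == pytest.approx(450.0)


class TestInjectedNonwearRecovery:
    def test_injected_bouts_fully_detected(self, small_cohort):
        """Every injected >=90-min zero bout is recovered by the Choi mask,
        and detected non-wear lies only within genuinely zero spans."""
        cfg, (series, logs, cov, panel, truth) = small_cohort
        bouts = truth.nonwear_bouts
        by_pid = {s.participant_id: s for s in series}
        checked = 0
        for row in bouts.itertuples():
            s = by_pid[row.participant_id]
            minutes = aggregate_minutes(s)
            nw = choi_nonwear(minutes)
            day_offset = (pd.Timestamp(row.date) - s.start).days * 1440
            lo, hi = day_offset + int(row.start_min), day_offset + int(row.end_min)
            assert nw[lo:hi].all()
            checked += 1
        assert checked > 0
        # false positives only inside zero spans (tolerated spikes aside)
        for s in series[:10]:
            minutes = aggregate_minutes(s)
            nw = choi_nonwear(minutes)
            if nw.any():
                assert (minutes[nw] > 0).mean() <= 2 / CHOI_WINDOW_MIN
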