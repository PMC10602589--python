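"""Stimulus generation: noise intervals, period schedules, blocks, scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from evaccum import stimgen
from evaccum.stimgen import (
    CONDITIONS,
    Direction,
    Outcome,
    PeriodKind,
    ResponseEvent,
    TaskConfig,
    generate_block,
    sample_noise_intervals,
    schedule_periods,
    score_responses,
)

from conftest import make_block_from_series, make_schedule


class TestNoiseIntervals:
    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_durations_within_truncation_bounds_and_tile(self, seed):
        cfg = TaskConfig()
        d = sample_noise_intervals(300.0, cfg, seed)
        assert np.all(d[:-1] >= cfg.isi_min_s)
        assert np.all(d <= cfg.isi_max_s)
        assert np.isclose(d.sum(), 300.0)

    def test_degenerate_total_shorter_than_minimum(self):
        d = sample_noise_intervals(0.005, TaskConfig(), 0)
        assert len(d) == 1 and np.isclose(d[0], 0.005)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            sample_noise_intervals(0.0, TaskConfig(), 0)

    def test_mean_matches_truncated_exponential_quadrature(self):
        """Empirical mean of ~1e5 draws vs numeric integration of the
        truncated density (rejection truncation preserves the exponential
        shape within the bounds)."""
        cfg = TaskConfig()
        mu, a, b = cfg.isi_mean_s, cfg.isi_min_s, cfg.isi_max_s
        pdf = lambda t: np.exp(-t / mu) / mu
        z, _ = integrate.quad(pdf, a, b)
        m1, _ = integrate.quad(lambda t: t * pdf(t), a, b)
        m2, _ = integrate.quad(lambda t: t * t * pdf(t), a, b)
        mean_true = m1 / z
        sd_true = np.sqrt(m2 / z - mean_true**2)

        d = sample_noise_intervals(26_000.0, cfg, 12345)[:-1]  # drop clipped tail
        assert len(d) > 90_000
        se = sd_true / np.sqrt(len(d))
        assert abs(d.mean() - mean_true) < 3 * se


class TestSchedule:
    def test_condition_parameters_respected(self):
        sched = schedule_periods(CONDITIONS["short-frequent"], 300.0, 3)
        kinds = [p.kind for p in sched]
        assert all(
            a is not b for a, b in zip(kinds, kinds[1:])
        ), "periods must alternate"
        for p in sched:
            if p.kind is PeriodKind.RESPONSE:
                assert p.nominal_duration_s == 3.0
                assert abs(p.mean_coherence) in {0.3, 0.4, 0.5}
            else:
                assert 3.0 <= p.nominal_duration_s <= 8.0
                assert p.mean_coherence == 0.0
        onsets = [p.onset_s for p in sched]
        ends = [p.onset_s + p.nominal_duration_s for p in sched]
        assert np.allclose(onsets[1:], ends[:-1]), "periods tile without gaps"

    def test_minimal_block_holds_both_kinds(self):
        sched = schedule_periods(CONDITIONS["long-rare"], 50.0, 0)
        kinds = {p.kind for p in sched}
        assert kinds == {PeriodKind.BASELINE, PeriodKind.RESPONSE}

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            schedule_periods(CONDITIONS["long-rare"], 5.0, 0)

    def test_response_count_matches_renewal_oracle(self):
        """Mean response periods per block vs an independent alternating
        renewal simulation."""
        cond = CONDITIONS["long-rare"]
        counts = []
        for seed in range(200):
            sched = schedule_periods(cond, 300.0, seed)
            counts.append(
                sum(1 for p in sched if p.kind is PeriodKind.RESPONSE)
            )
        rng = np.random.default_rng(99)
        oracle = []
        for _ in range(2000):
            t, n = 0.0, 0
            while True:
                t += rng.uniform(5.0, 40.0)
                if t >= 300.0 - 0.010:
                    break
                n += 1
                t += 5.0
            oracle.append(n)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts)) + np.std(
            oracle, ddof=1
        ) / np.sqrt(len(oracle))
        assert abs(np.mean(counts) - np.mean(oracle)) < 3.5 * se


class TestBlocks:
    def test_samples_in_range_and_expected_length(self):
        blk = generate_block(CONDITIONS["short-rare"], seed=7)
        assert len(blk.coherence) == 30_000
        assert np.all(np.abs(blk.coherence) <= 1.0)

    def test_piecewise_constant_on_interval_boundaries(self):
        blk = generate_block(CONDITIONS["long-frequent"], seed=11)
        change = np.flatnonzero(np.diff(blk.coherence) != 0) + 1
        starts = {
            min(int(round(iv.onset_s * blk.fs_hz)), len(blk.coherence) - 1)
            for iv in blk.intervals
        }
        assert set(change) <= starts

    def test_zero_variance_noise_equals_period_means(self):
        cfg = TaskConfig(sd_baseline=1e-12, sd_response=1e-12)
        blk = generate_block(CONDITIONS["short-frequent"], cfg, seed=5)
        vals = np.unique(np.round(blk.coherence, 6))
        assert set(vals) <= {-0.5, -0.4, -0.3, 0.0, 0.3, 0.4, 0.5}

    def test_all_baseline_zero_noise_block_is_flat_zero(self):
        cfg = TaskConfig(sd_baseline=1e-12, sd_response=1e-12)
        sched = make_schedule(
            [(PeriodKind.BASELINE, 0.0, 60.0, 0.0)], 60.0
        )
        blk = generate_block(
            CONDITIONS["long-rare"], cfg, seed=1, duration_s=60.0, schedule=sched
        )
        assert np.allclose(blk.coherence, 0.0)

    def test_deterministic_for_fixed_seed(self):
        b1 = generate_block(CONDITIONS["long-rare"], seed=42)
        b2 = generate_block(CONDITIONS["long-rare"], seed=42)
        assert np.array_equal(b1.coherence, b2.coherence)
        assert [p.onset_s for p in b1.schedule] == [p.onset_s for p in b2.schedule]

    def test_noise_draws_shared_across_conditions(self):
        """RARE and FREQUENT blocks on one seed share interval durations:
        the noise process is condition-independent."""
        br = generate_block(CONDITIONS["long-rare"], seed=3)
        bf = generate_block(CONDITIONS["long-frequent"], seed=3)
        dr = [iv.duration_s for iv in br.intervals]
        df = [iv.duration_s for iv in bf.intervals]
        assert np.allclose(dr, df)


def _score_oracle(block, presses, cfg):
    """Independent outcome labelling by explicit period-table membership."""
    tab = [
        [p.onset_s, p.onset_s + p.nominal_duration_s, p.mean_coherence, False]
        for p in block.schedule.periods
        if p.kind is PeriodKind.RESPONSE
    ]
    labels = []
    for ev in presses:
        hit = None
        for row in tab:
            on, end, mean, claimed = row
            if claimed:
                continue
            end_eff = min(end, block.duration_s)
            if on <= ev.time_s < min(end_eff + cfg.response_tolerance_s,
                                     row[1] + cfg.response_tolerance_s):
                hit = row
                break
        if hit is None:
            labels.append(Outcome.FALSE_ALARM)
        else:
            hit[3] = True
            good = (ev.direction is Direction.RIGHT) == (hit[2] > 0)
            labels.append(Outcome.CORRECT if good else Outcome.INCORRECT)
            hit[1] = min(hit[1], ev.time_s)  # period terminates at the press
    misses = sum(1 for row in tab if not row[3])
    return labels, misses


class TestScoring:
    def _toy_block(self):
        sched = make_schedule(
            [
                (PeriodKind.BASELINE, 0.0, 5.0, 0.0),
                (PeriodKind.RESPONSE, 5.0, 3.0, 0.4),
                (PeriodKind.BASELINE, 8.0, 5.0, 0.0),
                (PeriodKind.RESPONSE, 13.0, 3.0, -0.3),
                (PeriodKind.BASELINE, 16.0, 4.0, 0.0),
            ],
            20.0,
        )
        return make_block_from_series(np.zeros(2000), schedule=sched)

    def test_tolerance_window_press_counts_correct(self):
        blk = self._toy_block()
        res = score_responses(
            blk, [ResponseEvent(8.4, Direction.RIGHT)]
        )
        assert res.scored[0].outcome is Outcome.CORRECT
        assert res.scored[0].points == 3.0

    def test_no_presses_all_misses(self):
        sched = make_schedule(
            [
                (PeriodKind.BASELINE, 0.0, 4.0, 0.0),
                (PeriodKind.RESPONSE, 4.0, 3.0, 0.3),
                (PeriodKind.BASELINE, 7.0, 4.0, 0.0),
                (PeriodKind.RESPONSE, 11.0, 3.0, -0.4),
                (PeriodKind.BASELINE, 14.0, 4.0, 0.0),
                (PeriodKind.RESPONSE, 18.0, 3.0, 0.5),
                (PeriodKind.BASELINE, 21.0, 4.0, 0.0),
                (PeriodKind.RESPONSE, 25.0, 3.0, 0.3),
            ],
            28.0,
        )
        blk = make_block_from_series(np.zeros(2800), schedule=sched)
        res = score_responses(blk, [])
        assert res.misses == 4
        assert res.total_points == -6.0

    def test_early_termination_and_second_press_false_alarm(self):
        blk = self._toy_block()
        res = score_responses(
            blk,
            [
                ResponseEvent(5.5, Direction.RIGHT),
                ResponseEvent(6.5, Direction.RIGHT),
            ],
        )
        assert [s.outcome for s in res.scored] == [
            Outcome.CORRECT,
            Outcome.FALSE_ALARM,
        ]
        p = res.schedule.periods[1]
        assert p.actual_end_s == 5.5

    def test_wrong_direction_is_incorrect(self):
        blk = self._toy_block()
        res = score_responses(blk, [ResponseEvent(13.5, Direction.RIGHT)])
        assert res.scored[0].outcome is Outcome.INCORRECT
        assert res.scored[0].points == -3.0

    def test_unsorted_presses_rejected(self):
        blk = self._toy_block()
        with pytest.raises(ValueError):
            score_responses(
                blk,
                [ResponseEvent(6.0, Direction.LEFT), ResponseEvent(5.0, Direction.LEFT)],
            )

    @pytest.mark.parametrize("seed", range(25))
    def test_outcomes_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        blk = generate_block(CONDITIONS["short-frequent"], seed=seed,
                             duration_s=120.0)
        times = np.sort(rng.uniform(0, 119.9, size=rng.integers(1, 25)))
        presses = [
            ResponseEvent(float(t), Direction.RIGHT if rng.random() < 0.5
                          else Direction.LEFT)
            for t in times
        ]
        res = score_responses(blk, presses)
        labels, misses = _score_oracle(blk, presses, blk.cfg)
        assert [s.outcome for s in res.scored] == labels
        assert res.misses == misses

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        times=st.lists(
            st.floats(min_value=0.0, max_value=99.9, allow_nan=False),
            max_size=20,
        ),
        dirs=st.lists(st.booleans(), min_size=20, max_size=20),
        seed=st.integers(min_value=0, max_value=50),
    )
    def test_conservation_holds_for_arbitrary_press_sequences(
        self, times, dirs, seed
    ):
        blk = generate_block(CONDITIONS["short-frequent"], seed=seed,
                             duration_s=100.0)
        presses = [
            ResponseEvent(float(t), Direction.RIGHT if d else Direction.LEFT)
            for t, d in zip(sorted(times), dirs)
        ]
        res = score_responses(blk, presses)
        assert res.total_points == (
            3.0 * res.n_correct
            - 3.0 * res.n_incorrect
            - 1.5 * (res.n_false_alarm + res.misses)
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_points_conservation_identity(self, seed):
        rng = np.random.default_rng(100 + seed)
        blk = generate_block(CONDITIONS["long-frequent"], seed=seed,
                             duration_s=100.0)
        times = np.sort(rng.uniform(0, 99.9, size=15))
        presses = [
            ResponseEvent(float(t),
                          Direction.RIGHT if rng.random() < 0.5 else Direction.LEFT)
            for t in times
        ]
        res = score_responses(blk, presses)
        expect = (
            3.0 * res.n_correct
            - 3.0 * res.n_incorrect
            - 1.5 * (res.n_false_alarm + res.misses)
        )
        assert res.total_points == expect
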