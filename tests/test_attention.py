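"""Heart-rate-defined sustained-attention detection and indices."""

import numpy as np
import pytest

from dyadpredict import attention as A
from dyadpredict.simulate import CardiacSimConfig, simulate_ibi


def full_looking(n_ibis, ibi_ms=500.0, onset=0.0):
    duration = n_ibis * ibi_ms / 1000.0
    return A.LookingRecord(
        intervals=[(onset, onset + duration)],
        task_onset_s=onset,
        task_duration_s=duration,
    )


class TestDetection:
    def test_flat_series_no_phase(self, ibi_factory):
        series = ibi_factory([500.0] * 40)
        phases = A.detect_sustained_attention(series, full_looking(40))
        assert all(p.kind == "inattention" for p in phases)

    def test_hand_traced_open_close(self, ibi_factory):
        # 5 baseline beats at 500, 8 at 530 (opens at the first 530),
        # 6 at 470 (closes at the first 470 of the 5-run)
        ibis = [500.0] * 5 + [530.0] * 8 + [470.0] * 6
        series = ibi_factory(ibis)
        phases = A.detect_sustained_attention(series, full_looking(len(ibis)))
        sa = [p for p in phases if p.kind == "sustained_attention"]
        assert len(sa) == 1
        t_first_530 = series.beat_times_s[5]
        t_first_470 = series.beat_times_s[13]
        assert sa[0].onset_s == pytest.approx(t_first_530)
        assert sa[0].offset_s == pytest.approx(t_first_470)
        assert sa[0].baseline_median_ms == pytest.approx(500.0)

    def test_looking_requirement_blocks_onset(self, ibi_factory):
        # gaze arrives only after the elevated-IBI stretch: no qualifying run
        # has its first beat inside a looking interval, so no phase opens
        ibis = [500.0] * 5 + [530.0] * 8 + [470.0] * 6
        series = ibi_factory(ibis)
        looking = A.LookingRecord(
            intervals=[(float(series.beat_times_s[13]), float(series.beat_times_s[-1]))],
            task_onset_s=0.0,
            task_duration_s=float(series.beat_times_s[-1]),
        )
        phases = A.detect_sustained_attention(series, looking)
        assert not [p for p in phases if p.kind == "sustained_attention"]

    def test_pure_acceleration_no_phase(self, ibi_factory):
        # monotonically shrinking IBIs (speeding heart) never satisfy onset
        ibis = np.linspace(600.0, 400.0, 50)
        series = ibi_factory(ibis)
        phases = A.detect_sustained_attention(series, full_looking(50, 500.0))
        assert not [p for p in phases if p.kind == "sustained_attention"]

    def test_too_few_beats(self, ibi_factory):
        with pytest.raises(ValueError, match="10 beats"):
            A.detect_sustained_attention(
                ibi_factory([500.0] * 5), full_looking(5)
            )

    def test_phases_tile_task_window(self):
        cfg = CardiacSimConfig(
            baseline_ibi_ms=400.0,
            rmssd_target_ms=12.0,
            decel_epochs=[(30.0, 60.0, 25.0), (120.0, 150.0, 25.0)],
            duration_s=200.0,
            seed=4,
        )
        series = simulate_ibi(cfg)
        looking = A.LookingRecord(
            intervals=[(0.0, 200.0)], task_onset_s=0.0, task_duration_s=200.0
        )
        phases = A.detect_sustained_attention(series, looking)
        assert phases[0].onset_s == pytest.approx(0.0)
        assert phases[-1].offset_s == pytest.approx(200.0)
        for a, b in zip(phases, phases[1:]):
            assert b.onset_s == pytest.approx(a.offset_s)

    def test_replay_invariant_on_random_series(self):
        n_checked = 0
        for seed in range(30):
            cfg = CardiacSimConfig(
                baseline_ibi_ms=420.0,
                rmssd_target_ms=15.0,
                decel_epochs=[(40.0, 80.0, 30.0)],
                duration_s=150.0,
                seed=seed,
            )
            series = simulate_ibi(cfg)
            looking = A.LookingRecord(
                intervals=[(0.0, 150.0)], task_onset_s=0.0, task_duration_s=150.0
            )
            for p in A.detect_sustained_attention(series, looking):
                if p.kind == "sustained_attention":
                    assert A.replay_phase_onset(series, looking, p)
                    n_checked += 1
        assert n_checked > 10


class TestDurations:
    def test_no_phases_zero(self):
        assert A.total_sa_duration([]) == 0.0

    def test_additivity(self):
        phases = [
            A.AttentionPhase("sustained_attention", 0.0, 10.0),
            A.AttentionPhase("inattention", 10.0, 20.0),
            A.AttentionPhase("sustained_attention", 20.0, 35.0),
        ]
        assert A.total_sa_duration(phases) == pytest.approx(25.0)

    def test_matches_brute_force(self, rng):
        t = np.sort(rng.uniform(0, 300, size=20))
        phases = [
            A.AttentionPhase(
                "sustained_attention" if i % 2 else "inattention",
                t[2 * i_],
                t[2 * i_ + 1],
            )
            for i_, i in enumerate(rng.integers(0, 2, size=10))
        ]
        brute = sum(
            p.offset_s - p.onset_s
            for p in phases
            if p.kind == "sustained_attention"
        )
        assert A.total_sa_duration(phases) == pytest.approx(brute)


class TestDeceleration:
    def test_simple_subtraction(self, ibi_factory):
        # 10 beats of 500 before onset at t=5, then SA phase of 530s
        ibis = [500.0] * 10 + [530.0] * 10
        series = ibi_factory(ibis)
        onset = series.beat_times_s[10]
        phases = [
            A.AttentionPhase(
                "sustained_attention", onset, float(series.beat_times_s[-1])
            )
        ]
        d = A.heart_rate_deceleration(series, phases, task_onset_s=onset)
        assert d == pytest.approx(30.0)

    def test_equal_means_zero(self, ibi_factory):
        ibis = [500.0] * 20
        series = ibi_factory(ibis)
        onset = series.beat_times_s[10]
        phases = [
            A.AttentionPhase(
                "sustained_attention", onset, float(series.beat_times_s[-1])
            )
        ]
        assert A.heart_rate_deceleration(series, phases, onset) == pytest.approx(0.0)

    def test_no_sa_gives_nan(self, ibi_factory):
        series = ibi_factory([500.0] * 20)
        phases = [A.AttentionPhase("inattention", 2.0, 9.0)]
        assert np.isnan(A.heart_rate_deceleration(series, phases, task_onset_s=2.0))

    def test_empty_prestim_errors(self, ibi_factory):
        series = ibi_factory([500.0] * 20, t0_s=100.0)
        phases = [A.AttentionPhase("sustained_attention", 101.0, 105.0)]
        with pytest.raises(ValueError, match="pre-stimulus"):
            A.heart_rate_deceleration(series, phases, task_onset_s=50.0)

    def test_planted_deceleration_recovered(self):
        recovered = []
        for seed in range(25):
            cfg = CardiacSimConfig(
                baseline_ibi_ms=400.0,
                rmssd_target_ms=10.0,
                decel_epochs=[(t0, t0 + 50.0, 20.0) for t0 in (20.0, 80.0, 140.0)],
                duration_s=220.0,
                seed=seed,
            )
            series = simulate_ibi(cfg)
            looking = A.LookingRecord(
                intervals=[(10.0, 220.0)], task_onset_s=10.0, task_duration_s=210.0
            )
            phases = A.detect_sustained_attention(series, looking)
            d = A.heart_rate_deceleration(series, phases, task_onset_s=10.0)
            if np.isfinite(d):
                recovered.append(d)
        assert len(recovered) >= 20
        assert abs(np.mean(recovered) - 20.0) < 5.0

    def test_monotone_response_to_planted_delta(self):
        # stronger planted decelerations should not shrink SA time where the
        # stimulus acts (inside the epochs), for a clear majority of seeds;
        # total SA time also counts spontaneous phases, which are delta-free
        epochs_at = [(30.0, 70.0), (100.0, 140.0)]

        def sa_inside_epochs(delta, seed):
            cfg = CardiacSimConfig(
                baseline_ibi_ms=400.0,
                rmssd_target_ms=10.0,
                decel_epochs=[(a, b, delta) for a, b in epochs_at],
                duration_s=180.0,
                seed=seed,
            )
            series = simulate_ibi(cfg)
            looking = A.LookingRecord(
                intervals=[(0.0, 180.0)], task_onset_s=0.0, task_duration_s=180.0
            )
            inside = 0.0
            for p in A.detect_sustained_attention(series, looking):
                if p.kind == "sustained_attention":
                    for a, b in epochs_at:
                        inside += max(0.0, min(p.offset_s, b) - max(p.onset_s, a))
            return inside

        wins = sum(
            sa_inside_epochs(25.0, seed) >= sa_inside_epochs(0.0, seed)
            for seed in range(30)
        )
        assert wins >= 20
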