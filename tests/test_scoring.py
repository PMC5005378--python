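"""Threshold classifier and sleep-architecture statistics."""
import numpy as np
import pytest

from circasleep import (
    Hypnogram,
    Recording,
    StructureError,
    architecture_stats,
    compute_epoch_features,
    make_schedule,
    score_epochs,
    ScoringThresholds,
)
from circasleep.scoring import EpochFeatures
from circasleep.validation import architecture_fraction_error, scoring_agreement


def _sine_recording(freq, n_epochs=3, fs=200.0, emg_level=0.0):
    t = np.arange(n_epochs * 800) / fs
    return Recording(
        eeg=np.sin(2 * np.pi * freq * t),
        emg=np.full(t.size, emg_level),
        fs=fs,
    )


class TestFeatures:
    def test_pure_2hz_is_swa_dominated(self):
        f = compute_epoch_features(_sine_recording(2.0))
        assert (f.swa_power / f.total_power > 0.9).all()

    def test_pure_8hz_is_theta_dominated(self):
        f = compute_epoch_features(_sine_recording(8.0))
        assert (f.theta_power / f.total_power > 0.9).all()

    def test_zero_signal_zero_features(self):
        rec = Recording(eeg=np.zeros(1600), emg=np.zeros(1600), fs=200.0)
        f = compute_epoch_features(rec)
        assert (f.swa_power == 0).all() and (f.emg_rms == 0).all()


def _features(swa, theta, total, emg):
    n = len(swa)
    return EpochFeatures(
        swa_power=np.asarray(swa, float),
        theta_power=np.asarray(theta, float),
        total_power=np.asarray(total, float),
        emg_rms=np.asarray(emg, float),
    )


THR = ScoringThresholds(emg_threshold=1.0)


class TestRules:
    def test_high_emg_is_wake_regardless_of_eeg(self):
        f = _features([10.0], [0.1], [10.5], [5.0])  # SWA-dominated EEG
        assert score_epochs(f, THR).states[0] == "W"

    def test_low_emg_high_swa_ratio_is_nrem(self):
        f = _features([0.8], [0.05], [1.0], [0.1])
        assert score_epochs(f, THR).states[0] == "N"

    def test_theta_dominance_is_rem_in_sleep_context(self):
        # NREM context first, then a theta-dominant low-EMG epoch
        f = _features(
            [0.8, 0.8, 0.1], [0.05, 0.05, 0.5], [1.0, 1.0, 1.0], [0.1, 0.1, 0.1]
        )
        assert list(score_epochs(f, THR).states) == ["N", "N", "R"]

    def test_rem_without_sleep_context_relabeled_wake(self):
        # theta-dominant sleep epochs straight out of long wake
        f = _features(
            [0.1] * 8 + [0.1, 0.1],
            [0.05] * 8 + [0.5, 0.5],
            [1.0] * 10,
            [5.0] * 8 + [0.1, 0.1],
        )
        states = score_epochs(f, THR).states
        assert list(states[8:]) == ["W", "W"]

    def test_rem_context_survives_brief_awakening(self):
        f = _features(
            [0.8] * 5 + [0.1, 0.1],
            [0.05] * 5 + [0.05, 0.5],
            [1.0] * 7,
            [0.1] * 5 + [5.0, 0.1],
        )
        states = score_epochs(f, THR).states
        assert states[-1] == "R"  # one-epoch wake intrusion looked through

    def test_all_zero_features_wake_with_warning(self):
        f = _features([0.0], [0.0], [0.0], [0.0])
        with pytest.warns(UserWarning, match="all-zero"):
            states = score_epochs(f, THR).states
        assert states[0] == "W"

    def test_rule_stage_permutation_invariant(self):
        """Without REM in play, scoring is a pure per-epoch function."""
        rng = np.random.default_rng(0)
        n = 50
        f = _features(
            rng.random(n), np.zeros(n), np.ones(n), rng.choice([0.1, 5.0], n)
        )
        base = score_epochs(f, THR).states
        perm = rng.permutation(n)
        fp = _features(
            f.swa_power[perm], f.theta_power[perm], f.total_power[perm],
            f.emg_rms[perm],
        )
        assert np.array_equal(score_epochs(fp, THR).states, base[perm])


class TestArchitecture:
    sched = make_schedule(24.0, 0.5, n_days=1)

    def test_all_wake_day(self):
        hyp = Hypnogram(states=np.full(21600, "W"))
        arch = architecture_stats(hyp, self.sched)
        t = arch.table
        for phase in ("photophase", "scotophase"):
            row = t[(t.state == "W") & (t.phase == phase)].iloc[0]
            assert row.total_time_pct == pytest.approx(100.0)
        assert arch.brief_awakenings == 0
        # one maximal wake run overall (assigned to its starting phase)
        assert t[t.state == "W"].episode_count.sum() == 1

    def test_brief_awakening_example(self):
        hyp = Hypnogram(states=np.array(list("NNWWNN")))
        arch = architecture_stats(hyp, self.sched)
        assert arch.brief_awakenings == 1
        t = arch.table
        assert t[t.state == "N"].episode_count.sum() == 2
        # the brief awakening is not a wake episode
        assert t[t.state == "W"].episode_count.sum() == 0
        # 4 NREM epochs of 4 s
        assert (hyp.states == "N").sum() * 4 == 16

    def test_time_pct_sums_to_100_per_phase(self):
        rng = np.random.default_rng(3)
        hyp = Hypnogram(states=rng.choice(list("WNR"), size=21600))
        arch = architecture_stats(hyp, self.sched)
        for phase in ("photophase", "scotophase"):
            s = arch.table[arch.table.phase == phase].total_time_pct.sum()
            assert s == pytest.approx(100.0, abs=1e-9)

    def test_empty_hypnogram_raises(self):
        with pytest.raises(StructureError):
            architecture_stats(Hypnogram(states=np.array([], dtype="<U1")), self.sched)

    def test_fractions_match_generator_stationary(self):
        assert architecture_fraction_error(seed=4) <= 0.03


class TestAgreement:
    def test_agreement_on_short_simulation(self):
        assert scoring_agreement(seed=10, hours=6.0) >= 0.90
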