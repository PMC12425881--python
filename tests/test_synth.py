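"""Synthetic session generator: movement vocabulary, target trajectories,
synergies, and the session model."""

import numpy as np
import pytest

import myokf as mk
from myokf.movements import DOF_AXES, MOVEMENTS, REST
from myokf.synth import generate_raw_emg, session_sequence


class TestMovementVocabulary:
    def test_eight_movements_two_per_axis(self):
        non_rest = [m for m in MOVEMENTS.values() if m.code != REST]
        assert len(non_rest) == 8
        for axis in DOF_AXES:
            dirs = sorted(m.direction for m in non_rest if m.dof_axis == axis)
            assert dirs == [-1, 1]

    @pytest.mark.parametrize("bad", [{"rise_s": 0}, {"rest_s": -1}, {"reps": 0}])
    def test_protocol_rejects_nonpositive_durations(self, bad):
        with pytest.raises(ValueError):
            mk.TrialProtocol(**bad)

    def test_default_trapezoid_sample_convention(self, protocol):
        trap = protocol.trapezoid()
        assert len(trap) == 133
        assert protocol.rise_n == 21 and protocol.hold_n == 91 and protocol.fall_n == 21
        assert trap[0] == pytest.approx(1 / 21)
        assert trap.max() == 1.0
        assert np.all(trap > 0)


class TestTargetKinematics:
    def test_single_movement_trapezoid(self, protocol):
        kin, labels, cols = mk.generate_target_kinematics(protocol, ["HC"], mode="uni")
        assert cols == ["HC"]
        win = mk.attempt_windows(labels, "HC")[0]
        assert win.stop - win.start == 133
        assert kin[win, 0].max() == 1.0
        # rest everywhere else
        mask = np.ones(len(labels), bool)
        mask[win] = False
        assert np.all(kin[mask] == 0)

    def test_empty_sequence_all_rest(self, protocol):
        kin, labels, _ = mk.generate_target_kinematics(protocol, [], mode="uni")
        assert np.all(kin == 0)
        assert np.all(labels == REST)

    def test_bi_mode_extension_peaks_negative(self, protocol):
        kin, labels, cols = mk.generate_target_kinematics(protocol, ["HO"], mode="bi")
        assert cols == ["hand"]
        assert kin.min() == -1.0
        assert kin.max() == 0.0

    def test_bi_mode_shares_axis_column(self, protocol):
        kin, labels, cols = mk.generate_target_kinematics(protocol, ["HC", "HO"], mode="bi")
        assert cols == ["hand"]
        assert kin.shape[1] == 1
        assert kin.max() == 1.0 and kin.min() == -1.0

    def test_labels_rest_exactly_where_kinematics_zero(self, protocol):
        seq = session_sequence(mk.TrialProtocol(reps=2))
        kin, labels, _ = mk.generate_target_kinematics(protocol, seq, mode="bi")
        moving = np.abs(kin).max(axis=1) > 0
        assert np.array_equal(moving, labels != REST)

    def test_unknown_label_rejected(self, protocol):
        with pytest.raises(ValueError, match="unknown movement"):
            mk.generate_target_kinematics(protocol, ["XX"])


class TestSynergies:
    def test_disjoint_supports_without_crosstalk(self):
        s = mk.generate_synergies(mk.SynthConfig(crosstalk=0.0, seed=3))
        support = s > 0
        assert support.shape == (8, 32)
        # pairwise disjoint: each electrode belongs to exactly one movement
        assert np.all(support.sum(axis=0) == 1)

    def test_full_crosstalk_strictly_positive(self):
        s = mk.generate_synergies(mk.SynthConfig(crosstalk=1.0, seed=3))
        assert np.all(s > 0)

    def test_deterministic_under_seed(self):
        cfg = mk.SynthConfig(seed=11)
        assert np.array_equal(mk.generate_synergies(cfg), mk.generate_synergies(cfg))

    def test_too_few_electrodes_rejected(self):
        with pytest.raises(ValueError, match="electrodes"):
            mk.generate_synergies(mk.SynthConfig(n_electrodes=4))


class TestSessionModel:
    def test_noiseless_features_equal_synergy_weighted_activation(self, fast_protocol, clean_config):
        kin, labels, _ = mk.generate_target_kinematics(fast_protocol, ["HC", "WF"], mode="bi")
        ses = mk.generate_session(kin, labels, clean_config, protocol=fast_protocol)
        syn = mk.generate_synergies(clean_config)
        env = np.abs(kin).max(axis=1)
        hc_row, wf_row = list(MOVEMENTS).index("HC"), list(MOVEMENTS).index("WF")
        expected = np.zeros_like(ses.features)
        expected[labels == "HC"] = np.outer(env[labels == "HC"], syn[hc_row])
        expected[labels == "WF"] = np.outer(env[labels == "WF"], syn[wf_row])
        np.testing.assert_allclose(ses.features, expected, atol=1e-12)

    def test_rest_equals_baseline_exactly_when_clean(self, fast_protocol, clean_config):
        import dataclasses

        cfg = dataclasses.replace(clean_config, baseline=0.25)
        kin, labels, _ = mk.generate_target_kinematics(fast_protocol, ["HC"], mode="bi")
        ses = mk.generate_session(kin, labels, cfg, protocol=fast_protocol)
        assert np.all(ses.features[labels == REST] == 0.25)

    def test_bit_identical_under_seed(self, fast_protocol):
        cfg = mk.SynthConfig(seed=5)
        kin, labels, _ = mk.generate_target_kinematics(fast_protocol, ["HC"], mode="bi")
        a = mk.generate_session(kin, labels, cfg, protocol=fast_protocol)
        b = mk.generate_session(kin, labels, cfg, protocol=fast_protocol)
        assert np.array_equal(a.features, b.features)

    def test_injected_lag_peaks_cross_correlation(self, fast_protocol):
        cfg = mk.SynthConfig(
            crosstalk=0.0, noise_sd=0.0, baseline=0.0, lag_ms=200.0, session_gain_sd=0.0, seed=2
        )
        kin, labels, _ = mk.generate_target_kinematics(fast_protocol, ["HC"] * 3, mode="bi")
        ses = mk.generate_session(kin, labels, cfg, protocol=fast_protocol)
        env = np.abs(kin).max(axis=1)
        ch = ses.features[:, np.argmax(ses.features.max(axis=0))]
        t = len(env)
        corrs = [
            np.corrcoef(env[: t - lag], ch[lag:])[0, 1] if lag else np.corrcoef(env, ch)[0, 1]
            for lag in range(15)
        ]
        best = int(np.argmax(corrs))
        assert best == round(0.2 * ses.rate_hz)  # 200 ms at 30 Hz = 6 samples

    def test_rest_noise_mean_near_baseline(self, fast_protocol):
        cfg = mk.SynthConfig(
            crosstalk=0.0, noise_sd=0.03, baseline=0.5, lag_ms=0.0, session_gain_sd=0.0, seed=9
        )
        kin, labels, _ = mk.generate_target_kinematics(fast_protocol, ["HC"], mode="bi")
        ses = mk.generate_session(kin, labels, cfg, protocol=fast_protocol)
        rest = ses.features[labels == REST]
        se = 0.03 / np.sqrt(rest.size)
        assert abs(rest.mean() - 0.5) < 3 * se

    def test_lag_spanning_rest_period_rejected(self, fast_protocol):
        cfg = mk.SynthConfig(lag_ms=3200.0)
        kin, labels, _ = mk.generate_target_kinematics(fast_protocol, ["HC"], mode="bi")
        with pytest.raises(ValueError, match="unidentifiable"):
            mk.generate_session(kin, labels, cfg, protocol=fast_protocol)

    def test_participant_sessions_share_synergies_but_differ(self):
        proto = mk.TrialProtocol(reps=1)
        train, test = mk.generate_participant(mk.SynthConfig(seed=4), proto)
        assert train.features.shape == test.features.shape
        assert not np.array_equal(train.features, test.features)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            mk.SynthConfig(crosstalk=1.5)
        with pytest.raises(ValueError):
            mk.SynthConfig(noise_sd=-0.1)


class TestRawMode:
    def test_raw_mav_tracks_feature_envelope(self, fast_protocol, clean_config):
        import dataclasses

        cfg = dataclasses.replace(clean_config, baseline=0.3)
        kin, labels, _ = mk.generate_target_kinematics(fast_protocol, ["HC"], mode="bi")
        ses = mk.generate_session(kin, labels, cfg, protocol=fast_protocol)
        raw = generate_raw_emg(ses, cfg)
        assert raw.shape == (ses.features.shape[0] * 33, ses.features.shape[1])
        mav = mk.compute_mav(raw, mk.FeatureConfig(raw_rate_hz=33 * 30))
        rest = np.asarray(ses.labels) == REST
        n = min(len(mav), len(rest))
        assert abs(mav[rest[:n]].mean() - 0.3) / 0.3 < 0.15
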