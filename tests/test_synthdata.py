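"""Generator: sensor transfer, schedules, templates, minutes, datasets."""

import numpy as np
import pytest

from sleepmat import synthdata as sd


class TestSensorTransfer:
    params = sd.PiezoParams()

    def test_zero_force_gives_zero_voltage(self):
        assert sd.sensor_transfer(0.0, 2 * np.pi * 1.2, self.params) == 0.0

    def test_high_frequency_limit(self):
        # (omega RM CM)^2 >= 100 -> within 1% of beta*d33*Fm/CM
        p = self.params
        omega = 10.0 / (p.RM * p.CM)
        expected = p.beta * p.d33 * 2.0 / p.CM
        got = sd.sensor_transfer(2.0, omega, p)
        assert got == pytest.approx(expected, rel=0.01)

    def test_closed_form_at_unit_corner(self):
        # omega RM CM = 1: U = d33 * RM * omega * beta / sqrt(2)
        p = self.params
        omega = 1.0 / (p.RM * p.CM)
        expected = p.d33 * 1.0 * omega * p.RM * p.beta / np.sqrt(2.0)
        assert sd.sensor_transfer(1.0, omega, p) == pytest.approx(expected,
                                                                  rel=1e-12)

    def test_monotone_in_force(self):
        omega = 2 * np.pi * 1.2
        forces = np.linspace(0, 5, 11)
        volts = [sd.sensor_transfer(f, omega, self.params) for f in forces]
        assert np.all(np.diff(volts) > 0)

    def test_invalid_omega_rejected(self):
        with pytest.raises(ValueError):
            sd.sensor_transfer(1.0, 0.0, self.params)

    def test_d33_bound_enforced(self):
        with pytest.raises(ValueError):
            sd.PiezoParams(d33=700e-12)


class TestPostureSchedule:
    @pytest.mark.parametrize("seed", range(8))
    def test_full_night_change_count(self, seed):
        sched = sd.make_posture_schedule(420, seed)
        assert 16 <= len(sched.segments) <= 26
        assert sched.total_minutes == 420

    def test_one_hour_schedule_conserves_minutes(self):
        sched = sd.make_posture_schedule(60, 0)
        assert len(sched.segments) >= 1
        assert sched.total_minutes == 60

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sd.make_posture_schedule(59, 0)

    def test_long_run_supine_fraction(self):
        # Monte-Carlo average of the segment sampler vs the target mix
        total = 0
        supine = 0
        for seed in range(400):
            sched = sd.make_posture_schedule(420, seed)
            for posture, dur in sched.segments:
                total += dur
                if posture == "supine":
                    supine += dur
        assert supine / total == pytest.approx(0.4978, abs=0.05)

    def test_minute_labels_expand_segments(self):
        sched = sd.PostureSchedule([("supine", 3), ("left_lateral", 2)])
        assert sched.minute_labels() == ["supine"] * 3 + ["left_lateral"] * 2
        assert sched.n_changes == 1


class TestTemplates:
    @pytest.mark.parametrize("posture", sd.POSTURES)
    def test_weights_normalised(self, posture):
        t = sd.make_template(posture)
        for w in (t.resp_weights, t.bcg_weights):
            assert w.shape == (4, 8)
            assert w.max() == pytest.approx(1.0)
            assert (w >= 0).all()

    def test_supine_has_widest_contact(self):
        n_half = {p: (sd.make_template(p).resp_weights > 0.5).sum()
                  for p in sd.POSTURES}
        assert n_half["supine"] > n_half["right_lateral"]
        assert n_half["supine"] > n_half["left_lateral"]

    @pytest.mark.parametrize("posture", ["right_lateral", "left_lateral"])
    def test_lateral_centroid_opposes_maximum(self, posture):
        # moment balance: centroid column on the opposite side of the
        # grid midline from the maximum-weight column
        t = sd.make_template(posture)
        cols = np.arange(8)[None, :]
        for w in (t.resp_weights, t.bcg_weights):
            argmax_col = np.unravel_index(np.argmax(w), w.shape)[1]
            centroid = (w * cols).sum() / w.sum()
            assert np.sign(centroid - 3.5) == -np.sign(argmax_col - 3.5)

    def test_lateral_templates_mirror(self):
        r = sd.make_template("right_lateral")
        l = sd.make_template("left_lateral")
        np.testing.assert_allclose(l.resp_weights, r.resp_weights[:, ::-1])

    def test_subject_template_valid(self):
        rng = np.random.default_rng(0)
        t = sd.subject_template("supine", rng)
        assert t.resp_weights.shape == (4, 8)
        assert t.resp_weights.max() == pytest.approx(1.0)


class TestSynthMinute:
    def test_clean_minute_shape_and_flags(self, clean_minute):
        assert clean_minute.voltages.shape == (32, 6000)
        assert not clean_minute.movement
        assert not clean_minute.per_channel_movement.any()

    def test_respiratory_peak_at_fres(self, default_profile, supine_template):
        # >= 95% of clean minutes peak within one DFT bin of fres
        hits = 0
        n = 60
        freqs = np.fft.rfftfreq(6000, 0.01)
        band = (freqs >= 0.1) & (freqs <= 0.8)
        for seed in range(n):
            m = sd.synth_minute(default_profile, supine_template, False, seed)
            spec = np.abs(np.fft.rfft(m.voltages.mean(axis=0)))
            f_peak = freqs[band][np.argmax(spec[band])]
            if abs(f_peak - default_profile.fres) <= 1 / 60 + 1e-9:
                hits += 1
        assert hits / n >= 0.95

    def test_zero_modulation_gives_pure_carrier(self, supine_template):
        profile = sd.SubjectProfile(mbcg=1e-9, noise_sd=0.0,
                                    freq_jitter_sd=0.0, amp_jitter_sd=0.0,
                                    resp_amp=0.0)
        m = sd.synth_minute(profile, supine_template, False, 5)
        x = m.voltages[np.argmax(supine_template.bcg_weights.ravel())]
        freqs = np.fft.rfftfreq(6000, 0.01)
        spec = np.abs(np.fft.rfft(x))
        assert freqs[np.argmax(spec)] == pytest.approx(5 * profile.fhea,
                                                       abs=1 / 60)

    def test_movement_contaminates_at_least_seven_channels(
            self, contaminated_minute):
        assert contaminated_minute.per_channel_movement.sum() >= 7
        assert contaminated_minute.movement

    def test_same_seed_reproduces(self, default_profile, supine_template):
        a = sd.synth_minute(default_profile, supine_template, True, 9)
        b = sd.synth_minute(default_profile, supine_template, True, 9)
        np.testing.assert_array_equal(a.voltages, b.voltages)


class TestDataset:
    def test_manifest_row_count(self, tmp_path):
        man = sd.synth_dataset(2, 60, 0, tmp_path / "d", waveforms=False)
        assert len(man) == 120
        assert set(man.columns) >= {"subject_id", "minute_index", "posture",
                                    "movement", "file"}

    def test_determinism_byte_identical(self, tmp_path):
        sd.synth_dataset(2, 60, 7, tmp_path / "a", waveforms=False)
        sd.synth_dataset(2, 60, 7, tmp_path / "b", waveforms=False)
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == \
            (tmp_path / "b" / "manifest.csv").read_bytes()

    def test_movement_fraction_matches_configured_rate(self, tmp_path):
        man = sd.synth_dataset(22, 390, 1, tmp_path / "d", waveforms=False,
                               movement_rate=0.11)
        frac = man["movement"].mean()
        assert frac == pytest.approx(0.11, abs=0.02)

    def test_waveform_container_roundtrip(self, tmp_path):
        out = tmp_path / "d"
        man = sd.synth_dataset(2, 60, 3, out, waveforms=True)
        z = np.load(out / "s00.npz")
        assert z["voltages"].shape == (60, 32, 6000)
        assert z["movement"].shape == (60,)
        sub = man[man.subject_id == "s00"]
        np.testing.assert_array_equal(z["movement"].astype(int),
                                      sub["movement"].to_numpy())
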