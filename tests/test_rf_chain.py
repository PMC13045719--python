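"""Signal-chain stages: muting, TGC, filtering, envelope, log compression,
upsampling and the 7-matrix contract."""

import numpy as np
import pytest

from us2ct.rf_chain import (
    STAGES,
    StageMatrix,
    default_mute_time,
    envelope_detect,
    frequency_filter,
    log_compress,
    remove_input_signal,
    run_chain,
    time_gain_compensation,
    upsample_lateral,
)
from us2ct.us_sim import ProbeConfig, desk_probe, scan
from tests.conftest import make_phantom


def _stage(stage, data, probe=None, dt=None):
    probe = probe or ProbeConfig(n_lines=data.shape[0], n_time_samples=data.shape[1])
    return StageMatrix(stage=stage, data=data, probe=probe, c_bar=1540.0,
                       dt=dt or 57.1364e-6 / probe.n_time_samples)


def test_stage_enum_guard():
    with pytest.raises(ValueError):
        _stage("beamforming", np.zeros((4, 8)))


class TestInputSignalRemoval:
    def test_zero_mute_is_identity(self):
        rf = _stage("raw_scan_lines", np.random.default_rng(0).normal(size=(4, 64)))
        out = remove_input_signal(rf, mute_time=0.0)
        assert np.array_equal(out.data, rf.data)
        assert out.stage == "input_signal_removal"

    def test_zero_input_stays_zero(self):
        rf = _stage("raw_scan_lines", np.zeros((4, 64)))
        assert np.all(remove_input_signal(rf).data == 0.0)

    def test_default_mute_zeroes_expected_columns(self):
        probe = ProbeConfig(n_lines=4, n_time_samples=256)
        rf = _stage("raw_scan_lines", np.ones((4, 256)), probe=probe)
        out = remove_input_signal(rf)
        n_mute = int(np.ceil(default_mute_time(probe) / rf.dt))
        assert np.all(out.data[:, :n_mute] == 0.0)
        assert np.all(out.data[:, n_mute:] == 1.0)

    def test_wrong_stage_rejected(self):
        env = _stage("envelope", np.ones((4, 8)))
        with pytest.raises(ValueError):
            remove_input_signal(env)


class TestTimeGainCompensation:
    def test_zero_attenuation_is_identity(self):
        probe = ProbeConfig(n_lines=4, n_time_samples=64, attenuation_coeff=0.0)
        rf = _stage("input_signal_removal", np.random.default_rng(1).normal(size=(4, 64)), probe)
        out = time_gain_compensation(rf)
        assert np.allclose(out.data, rf.data)

    def test_gain_is_one_at_zero_depth(self):
        rf = _stage("input_signal_removal", np.ones((2, 32)))
        out = time_gain_compensation(rf)
        assert out.data[0, 0] == pytest.approx(1.0)
        assert np.all(out.data[:, 1:] > out.data[:, :-1])  # strictly growing gain

    def test_depth_profile_flattened_on_uniform_phantom(self):
        ph = make_phantom("ct_invisible", [], seed=8, grid_spacing=0.2)
        rf = scan(ph, desk_probe(), np.random.default_rng(4))
        stages = run_chain(rf)
        env = stages[4].data
        n_keep = int(round(2 * 38e-3 / rf.c_bar / stages[4].dt))
        band = env[:, env.shape[1] // 8 : n_keep]
        quarters = np.array_split(np.arange(band.shape[1]), 4)
        deep = np.median(band[:, quarters[-1]])
        shallow = np.median(band[:, quarters[0]])
        assert 0.5 <= deep / shallow <= 2.0


class TestFrequencyFilter:
    def _tone(self, freq_hz, probe):
        dt = 57.1364e-6 / probe.n_time_samples
        t = np.arange(probe.n_time_samples) * dt
        return np.tile(np.sin(2 * np.pi * freq_hz * t), (probe.n_lines, 1))

    def test_centre_tone_preserved_within_1db(self):
        probe = ProbeConfig(n_lines=2, n_time_samples=2934)
        rf = _stage("time_gain_compensation", self._tone(6e6, probe), probe)
        out = frequency_filter(rf)
        mid = slice(500, 2400)
        gain = np.abs(out.data[0, mid]).max() / np.abs(rf.data[0, mid]).max()
        assert abs(20 * np.log10(gain)) < 1.0

    def test_out_of_band_tone_suppressed_40db(self):
        probe = ProbeConfig(n_lines=2, n_time_samples=2934)
        rf = _stage("time_gain_compensation", self._tone(0.5e6, probe), probe)
        out = frequency_filter(rf)
        mid = slice(500, 2400)
        gain = np.abs(out.data[0, mid]).max() / np.abs(rf.data[0, mid]).max()
        assert 20 * np.log10(gain) <= -40.0

    def test_zero_in_zero_out(self):
        rf = _stage("time_gain_compensation", np.zeros((2, 512)))
        assert np.allclose(frequency_filter(rf).data, 0.0)


class TestEnvelope:
    def test_sinusoid_envelope_is_amplitude(self):
        probe = ProbeConfig(n_lines=1, n_time_samples=2934)
        dt = 57.1364e-6 / 2934
        t = np.arange(2934) * dt
        # integer number of cycles over the record so the analytic signal
        # is leakage-free
        freq = round(6e6 * 2934 * dt) / (2934 * dt)
        rf = _stage("frequency_filter", 3.7 * np.sin(2 * np.pi * freq * t)[None, :], probe)
        env = envelope_detect(rf)
        assert np.allclose(env.data[0, 200:-200], 3.7, rtol=1e-3)

    def test_nonnegative_and_zero_preserving(self):
        rf = _stage("frequency_filter", np.zeros((2, 64)))
        env = envelope_detect(rf)
        assert np.all(env.data == 0.0)
        rf2 = _stage("frequency_filter", np.random.default_rng(2).normal(size=(2, 64)))
        assert envelope_detect(rf2).data.min() >= 0.0


class TestLogCompression:
    def test_reference_points(self):
        data = np.array([[1.0, 10.0 ** (-60.0 / 20.0), 10.0 ** (-80.0 / 20.0), 0.1]])
        env = _stage("envelope", data)
        out = log_compress(env, dynamic_range_dB=60.0)
        assert out.data[0, 0] == pytest.approx(1.0)        # global max → 1
        assert out.data[0, 1] == pytest.approx(0.0)        # exactly at floor
        assert out.data[0, 2] == pytest.approx(0.0)        # below floor clips
        assert out.data[0, 3] == pytest.approx((60.0 - 20.0) / 60.0, abs=1e-9)

    def test_output_always_in_unit_interval(self):
        rng = np.random.default_rng(3)
        env = _stage("envelope", np.abs(rng.lognormal(size=(8, 128))))
        out = log_compress(env, 40.0)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_all_zero_envelope_rejected(self):
        env = _stage("envelope", np.zeros((2, 16)))
        with pytest.raises(ValueError):
            log_compress(env)


class TestUpsampling:
    def test_constant_image_unchanged(self):
        img = _stage("log_compression", np.full((8, 16), 0.25))
        out = upsample_lateral(img)
        assert np.allclose(out.data, 0.25)
        assert out.data.shape == (16, 16)

    def test_midpoint_interpolation(self):
        img = _stage("log_compression", np.array([[0.0, 0.0], [1.0, 1.0]]))
        out = upsample_lateral(img)
        assert np.allclose(out.data[1], 0.5)   # between lines 0 and 1
        assert np.array_equal(out.data[0], img.data[0])
        assert np.array_equal(out.data[2], img.data[1])


def test_run_chain_emits_seven_matrices_with_paper_shapes():
    """Six matrices of (128, 2934) plus the (256, 2934) B-mode at the
    full-scale probe configuration."""
    ph = make_phantom("ct_invisible", None, seed=12, grid_spacing=0.4)
    rf = scan(ph, ProbeConfig(), np.random.default_rng(0))
    stages = run_chain(rf)
    assert len(stages) == 7
    assert [s.stage for s in stages] == list(STAGES)
    assert np.array_equal(stages[0].data, rf.data)
    shapes = [s.data.shape for s in stages]
    assert shapes[:6] == [(128, 2934)] * 6
    assert shapes[6] == (256, 2934)


def test_chain_is_deterministic(scanned_stages, lesion_phantom_visible, probe):
    rf = scan(lesion_phantom_visible, probe, np.random.default_rng(5))
    again = run_chain(rf)
    for a, b in zip(scanned_stages, again):
        assert np.array_equal(a.data, b.data)


def test_bmode_contrast_ordering(scanned_stages, lesion_phantom_visible, probe):
    """Mean B-mode intensity: hyperechoic ROI > background > anechoic ROI."""
    from us2ct.pairs import aligned_masks, stage_to_image
    from skimage.transform import resize

    ph = lesion_phantom_visible
    bmode = stage_to_image(scanned_stages[-1], ph.config)
    bmode = resize(bmode, (64, 64), order=1, preserve_range=True)
    masks = aligned_masks(ph, probe, 64)
    hyper = bmode[masks["hyperechoic"]].mean()
    anech = bmode[masks["anechoic"]].mean()
    bg = bmode[masks["background"]].mean()
    assert hyper > bg > anech
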