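"""Seven-stage ultrasound signal-processing chain.

Starting from the raw scan lines the chain applies, in fixed order: input
signal removal (muting the transmit feedthrough), time gain compensation,
band-pass frequency filtering, envelope detection, log compression and
lateral upsampling; the final stage is the B-mode image.  Every stage
consumes the previous stage's output, and the chain emits one matrix per
stage (7 in total: six of shape (n_lines, n_time) and the upsampled B-mode
of shape (2·n_lines, n_time)).

The chain is fully deterministic: all randomness lives in the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from us2ct.us_sim import ProbeConfig, RFMatrix

STAGES = (
    "raw_scan_lines",
    "input_signal_removal",
    "time_gain_compensation",
    "frequency_filter",
    "envelope",
    "log_compression",
    "upsampling",
)


@dataclass
class StageMatrix:
    stage: str
    data: np.ndarray
    probe: ProbeConfig
    c_bar: float
    dt: float
    phantom_id: str = ""
    flavour: str = ""

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


def _as_stage(src, stage: str, data: np.ndarray) -> StageMatrix:
    return StageMatrix(
        stage=stage,
        data=data,
        probe=src.probe,
        c_bar=src.c_bar,
        dt=src.dt,
        phantom_id=src.phantom_id,
        flavour=src.flavour,
    )


def _require_stage(m, expected: str) -> None:
    if m.stage != expected:
        raise ValueError(f"expected stage {expected!r}, got {m.stage!r}")


def default_mute_time(probe: ProbeConfig) -> float:
    """Mute window in seconds: tone-burst duration plus a 1 µs guard."""
    return probe.tone_burst_cycles / (probe.centre_frequency * 1e6) + 1e-6


def remove_input_signal(rf, mute_time: float | None = None) -> StageMatrix:
    """Zero all samples earlier than ``mute_time`` (transmit feedthrough)."""
    _require_stage(rf, "raw_scan_lines")
    if mute_time is None:
        mute_time = default_mute_time(rf.probe)
    n_mute = min(int(np.ceil(mute_time / rf.dt)), rf.data.shape[1])
    out = rf.data.copy()
    out[:, :n_mute] = 0.0
    return _as_stage(rf, "input_signal_removal", out)


def time_gain_compensation(rf, probe: ProbeConfig | None = None) -> StageMatrix:
    """Depth-dependent gain cancelling the modelled two-way attenuation.

    Sample at time t sits at depth z = c̄·t/2; the simulator attenuates its
    amplitude by α·f^γ dB/cm over the 2z round trip, so the gain is
    g(t) = 10^(α·f^γ · 2·z_cm / 20), with g(0) = 1 and identity when α = 0.
    """
    _require_stage(rf, "input_signal_removal")
    probe = probe or rf.probe
    t = np.arange(rf.data.shape[1]) * rf.dt
    z_cm = rf.c_bar * t / 2.0 * 100.0
    alpha_db = probe.attenuation_coeff * probe.centre_frequency**probe.attenuation_exponent
    gain = 10.0 ** (alpha_db * 2.0 * z_cm / 20.0)
    return _as_stage(rf, "time_gain_compensation", rf.data * gain[None, :])


def frequency_filter(
    rf, probe: ProbeConfig | None = None, fractional_bandwidth: float = 1.0, order: int = 4
) -> StageMatrix:
    """Zero-phase band-pass around the centre frequency.

    Passband f0 · (1 ± fractional_bandwidth/2); a forward-backward
    Butterworth keeps zero phase and doubles the stopband attenuation.
    """
    _require_stage(rf, "time_gain_compensation")
    probe = probe or rf.probe
    fs = 1.0 / rf.dt
    f0 = probe.centre_frequency * 1e6
    lo = f0 * (1.0 - fractional_bandwidth / 2.0)
    hi = min(f0 * (1.0 + fractional_bandwidth / 2.0), 0.95 * fs / 2.0)
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return _as_stage(rf, "frequency_filter", sosfiltfilt(sos, rf.data, axis=1))


def envelope_detect(rf) -> StageMatrix:
    """Per-line analytic-signal magnitude (non-negative)."""
    _require_stage(rf, "frequency_filter")
    return _as_stage(rf, "envelope", np.abs(hilbert(rf.data, axis=1)))


def log_compress(env, dynamic_range_dB: float = 60.0) -> StageMatrix:
    """Map the envelope to [0, 1] over ``dynamic_range_dB`` of log scale.

    20·log10(env/max) clipped to [−DR, 0] and rescaled so the global
    maximum maps to 1 and the clip floor to 0.
    """
    _require_stage(env, "envelope")
    if dynamic_range_dB <= 0:
        raise ValueError("dynamic range must be positive")
    peak = env.data.max()
    if peak <= 0:
        raise ValueError("all-zero envelope has no finite log compression")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env.data / peak)
    db = np.clip(db, -dynamic_range_dB, 0.0)
    return _as_stage(env, "log_compression", (db + dynamic_range_dB) / dynamic_range_dB)


def upsample_lateral(img) -> StageMatrix:
    """Double the line count by linear interpolation between adjacent lines.

    Even output rows copy the original lines; odd rows are midpoints (the
    last row duplicates the final line).  The time axis is unchanged.
    """
    _require_stage(img, "log_compression")
    x = img.data
    n = x.shape[0]
    out = np.empty((2 * n, x.shape[1]), dtype=x.dtype)
    out[0::2] = x
    out[1:-1:2] = 0.5 * (x[:-1] + x[1:])
    out[-1] = x[-1]
    return _as_stage(img, "upsampling", out)


def run_chain(rf: RFMatrix, dynamic_range_dB: float = 60.0) -> list[StageMatrix]:
    """Run the full chain; returns exactly 7 matrices in stage order."""
    raw = _as_stage(rf, "raw_scan_lines", rf.data)
    s1 = remove_input_signal(raw)
    s2 = time_gain_compensation(s1)
    s3 = frequency_filter(s2)
    s4 = envelope_detect(s3)
    s5 = log_compress(s4, dynamic_range_dB)
    s6 = upsample_lateral(s5)
    return [raw, s1, s2, s3, s4, s5, s6]
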