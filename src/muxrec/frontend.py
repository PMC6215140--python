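"""Behavioral time-domain model of the multiplexed acquisition chain.

Signal path per slot (one electrode visit at the aggregate rate fs):

1. the multiplexer selects the electrode; the capacitive-feedback LNA
   (closed-loop gain CS/CF = 10) settles toward the new electrode
   voltage, minus the coarse offset-DAC correction, with a single-pole
   exponential residual during the conversion window Tconv;
2. the integration capacitor is reset, then the transconductor GM
   integrates the LNA output (minus the fine offset-DAC correction)
   onto CIN_adc for the window Ts, implementing windowed integration
   sampling with voltage gain GM*Ts/CIN_adc (designed at 100);
3. the 9-bit SAR ADC quantizes the integrated value over +/-0.9 V.

The overall passband gain is therefore 10 x 100 = 1000 (60 dB).  LNA
noise is injected as one equivalent Gaussian per acquired sample with
variance density^2 * NEB_wis = density^2/(2 Ts), which is exactly the
sample-level variance the sinc response admits for a white density.
Signals are represented single-ended-equivalent; common-mode behavior
is out of scope.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .electrode import K_BOLTZMANN
from .neb import MuxTiming
from .scene import NeuralScene, render_electrode_voltage


@dataclass(frozen=True)
class FrontEndConfig:
    """Electrical parameters of the acquisition chain."""

    CS: float = 5e-12            # LNA input capacitance, F
    CF: float = 0.5e-12          # LNA feedback capacitance, F
    CP: float = 0.0              # OTA parasitic input capacitance, F
    lna_bandwidth: float = 7.5e6     # closed-loop settling bandwidth, Hz
    lna_noise_density: float = 8.7e-9  # input-referred, V/rtHz
    n_slope: float = 1.5         # subthreshold slope factor
    UT: float = 0.02585          # thermal voltage, V
    GM: float | None = None      # transconductance, S (derived if None)
    wis_gain_design: float = 100.0   # target GM*Ts/CIN_adc of the WIS stage
    CIN_adc: float = 600e-15     # SAR CDAC total capacitance, F
    adc_bits: int = 9
    adc_fullscale: float = 0.9   # differential full scale, +/- V
    # coarse offset DAC (in the LNA/OTA): 4 bits spanning +/-65 mV
    # input-referred; implemented physically as a 4 uA-LSB current
    # imbalance on 50 uA branches
    coarse_bits: int = 4
    coarse_range: float = 65e-3
    coarse_bias_current: float = 50e-6
    coarse_lsb_current: float = 4e-6
    coarse_physical_scale: float = 1.0
    # fine offset DAC (input pair of GM): 5 bits, +/-57 mV referred to
    # the GM input (i.e. the LNA output)
    fine_bits: int = 5
    fine_range: float = 57e-3
    # multiplexer switch on-resistance, ohms
    mux_r_on: float = 160.0
    temperature: float = 300.0

    @property
    def lna_gain(self) -> float:
        return self.CS / self.CF

    def gm_value(self, Ts: float = 1.5e-6) -> float:
        """Transconductance for the active timing.

        An explicitly configured GM is used as-is; otherwise GM is sized
        as ``wis_gain_design * CIN_adc / Ts`` so the WIS stage realizes
        its design gain (100, i.e. ~40 uS at Ts = 1.5 us) for whatever
        integration window the timing provides.
        """
        if self.GM is not None:
            return self.GM
        return self.wis_gain_design * self.CIN_adc / Ts

    def wis_gain(self, Ts: float) -> float:
        return self.gm_value(Ts) * Ts / self.CIN_adc

    def passband_gain(self, Ts: float) -> float:
        return self.lna_gain * self.wis_gain(Ts)

    @property
    def adc_lsb(self) -> float:
        return 2.0 * self.adc_fullscale / 2 ** self.adc_bits

    @property
    def adc_mid(self) -> int:
        return 2 ** (self.adc_bits - 1)

    @property
    def coarse_lsb(self) -> float:
        """Input-referred volts per coarse code step (offset-binary map)."""
        return 2.0 * self.coarse_range / (2 ** self.coarse_bits - 1)

    @property
    def fine_lsb(self) -> float:
        """GM-input-referred volts per fine code step."""
        return 2.0 * self.fine_range / (2 ** self.fine_bits - 1)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(
            {k: (None if v is None else float(v) if isinstance(v, (int, float)) else v)
             for k, v in asdict(self).items()},
            sort_keys=True,
        )
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def coarse_dac_offset(code: int, config: FrontEndConfig, mode: str = "calibrated"):
    """Input-referred correction voltage for a coarse DAC code (0..15).

    ``calibrated`` (default): offset-binary map ``(code - 7.5) * lsb``
    spanning exactly +/-coarse_range; codes 7 and 8 bracket zero.
    ``physical``: the weak-inversion current-imbalance map -- the code
    steers ``(code - 7.5) * coarse_lsb_current`` into/out of each 50 uA
    branch and the input-referred offset follows
    ``(CF+CS+CP)/CS * n UT ln(ID1b/ID1a)``.  With the default currents
    this spans noticeably less than the calibrated +/-65 mV (about
    6.8 mV per LSB step); ``coarse_physical_scale`` rescales it when a
    larger physical range is to be emulated.
    """
    code = np.asarray(code)
    if np.any((code < 0) | (code > 2 ** config.coarse_bits - 1)):
        raise ValueError(f"coarse code out of range 0..{2**config.coarse_bits - 1}")
    centered = code - (2 ** config.coarse_bits - 1) / 2.0
    if mode == "calibrated":
        v = centered * config.coarse_lsb
    elif mode == "physical":
        di = centered * config.coarse_lsb_current
        id1a = config.coarse_bias_current - di
        id1b = config.coarse_bias_current + di
        v = config.coarse_physical_scale * coarse_dac_voltage_from_currents(
            id1a, id1b, config
        )
    else:
        raise ValueError(f"unknown coarse DAC mode {mode!r}")
    return float(v) if np.isscalar(code) or code.ndim == 0 else v


def coarse_dac_voltage_from_currents(id1a, id1b, config: FrontEndConfig):
    """Input-referred offset compensated by a differential-pair current
    imbalance: ``(CF+CS+CP)/CS * n UT ln(ID1b/ID1a)``."""
    prefactor = (config.CF + config.CS + config.CP) / config.CS
    return prefactor * config.n_slope * config.UT * np.log(
        np.asarray(id1b, float) / np.asarray(id1a, float)
    )


def fine_dac_offset(code: int, config: FrontEndConfig):
    """GM-input-referred correction for a fine DAC code (0..31).

    Offset-binary map ``(code - 15.5) * lsb`` spanning exactly
    +/-fine_range; codes 15 and 16 bracket zero (with 32 codes a map
    that is symmetric about zero cannot also contain an exact zero).
    """
    code = np.asarray(code)
    if np.any((code < 0) | (code > 2 ** config.fine_bits - 1)):
        raise ValueError(f"fine code out of range 0..{2**config.fine_bits - 1}")
    centered = code - (2 ** config.fine_bits - 1) / 2.0
    v = centered * config.fine_lsb
    return float(v) if np.isscalar(code) or code.ndim == 0 else v


def fine_dac_voltage_from_widths(w1a, w1b, config: FrontEndConfig):
    """Offset referred to the GM input for an input-pair width ratio:
    ``n UT ln(W1a/W1b)`` (weak inversion)."""
    return config.n_slope * config.UT * np.log(
        np.asarray(w1a, float) / np.asarray(w1b, float)
    )


def lna_step_response(v_target, v_start, t, config: FrontEndConfig):
    """First-order settling toward v_target from v_start after time t.

    ``v(t) = v_target - (v_target - v_start) exp(-2 pi f_bw t)``; the
    fractional residual after t is ``exp(-2 pi f_bw t)``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    decay = np.exp(-2.0 * math.pi * config.lna_bandwidth * t)
    return v_target - (v_target - np.asarray(v_start)) * decay


def adc_quantize(v_diff, config: FrontEndConfig):
    """Uniform mid-tread 9-bit quantizer over [-FS, +FS].

    Returns ``(codes, saturated)``: code = round(v/LSB) + 2^(bits-1),
    clamped to the code range with the saturation mask flagging clamps.
    v = 0 maps to the mid code, +FS to the top code, -FS to code 0.
    """
    v = np.asarray(v_diff, dtype=float)
    raw = np.round(v / config.adc_lsb).astype(np.int64) + config.adc_mid
    top = 2 ** config.adc_bits - 1
    saturated = (raw < 0) | (raw > top)
    codes = np.clip(raw, 0, top)
    if np.isscalar(v_diff) or v.ndim == 0:
        return int(codes), bool(saturated)
    return codes.astype(np.uint16), saturated


@dataclass
class SampleStream:
    """Interleaved ADC codes plus everything needed to interpret them."""

    codes: np.ndarray                 # uint16, slot order
    timing: MuxTiming
    channel_map: np.ndarray           # slot-in-frame -> electrode
    config: FrontEndConfig
    calibration: object = None        # CalibrationState or None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint16)
        if self.codes.size % self.timing.M != 0:
            raise ValueError("stream length must be a whole number of frames")
        top = 2 ** self.config.adc_bits - 1
        if self.codes.size and self.codes.max() > top:
            raise ValueError("codes exceed the ADC range")

    @property
    def n_frames(self) -> int:
        return self.codes.size // self.timing.M

    def to_dataframe(self) -> pd.DataFrame:
        slots = np.arange(self.codes.size)
        return pd.DataFrame({
            "slot": slots,
            "electrode": self.channel_map[slots % self.timing.M],
            "code": self.codes,
        })

    def save(self, path) -> None:
        """Raw little-endian uint16 codes + a structured-text sidecar."""
        path = str(path)
        self.codes.astype("<u2").tofile(path)
        sidecar = {
            "M": int(self.timing.M),
            "fch_hz": float(self.timing.fch),
            "fs_hz": float(self.timing.fs),
            "tconv_s": float(self.timing.Tconv),
            "eps_dtol": float(self.timing.eps_dtol),
            "channel_map": [int(e) for e in self.channel_map],
            "adc_bits": int(self.config.adc_bits),
            "config_hash": self.config.config_hash(),
            "metadata": {k: (v if isinstance(v, (int, float, str, bool)) else str(v))
                         for k, v in self.metadata.items()},
        }
        with open(path + ".yaml", "w") as fh:
            yaml.safe_dump(sidecar, fh, sort_keys=True)

    @classmethod
    def load(cls, path, config: FrontEndConfig | None = None) -> "SampleStream":
        path = str(path)
        with open(path + ".yaml") as fh:
            sidecar = yaml.safe_load(fh)
        codes = np.fromfile(path, dtype="<u2")
        timing = MuxTiming(
            M=sidecar["M"], fch=sidecar["fch_hz"],
            Tconv=sidecar["tconv_s"], eps_dtol=sidecar["eps_dtol"],
        )
        return cls(
            codes=codes, timing=timing,
            channel_map=np.asarray(sidecar["channel_map"]),
            config=config or FrontEndConfig(),
            metadata=sidecar.get("metadata", {}),
        )


def switched_input_impedance(fch: float, CS: float) -> float:
    """Switched-capacitor input impedance ``1/(fch CS)`` an electrode sees
    when the CS capacitance is periodically connected to it at fch."""
    if fch <= 0 or CS <= 0:
        raise ValueError("fch and CS must be positive")
    return 1.0 / (fch * CS)


def mux_switch_noise(R_on: float, neb: float, T: float = 300.0) -> float:
    """RMS thermal noise of the multiplexer switch: ``sqrt(4 k T R_on NEB)``."""
    if R_on < 0 or neb < 0 or T <= 0:
        raise ValueError("R_on and neb must be >= 0 and T > 0")
    return math.sqrt(4.0 * K_BOLTZMANN * T * R_on * neb)


def simulate_acquisition(
    scene: NeuralScene,
    timing: MuxTiming,
    config: FrontEndConfig,
    calibration=None,
    duration: float = 0.1,
    seed: int = 0,
    oversample: int = 10,
    include=("offset", "spikes", "background", "thermal"),
    lna_noise: bool = True,
    mux_noise: bool = True,
) -> SampleStream:
    """Run the full chain on a scene and return the interleaved codes.

    Per slot the electrode waveform (rendered at ``oversample * fs``) is:
    settled through the LNA during Tconv (exponential residual carried
    over from the previous slot's output), averaged over the Ts window
    (windowed integration via sub-slot numerical averaging), corrected
    by the coarse (input-referred) and fine (GM-input-referred) DAC
    codes, scaled by the 60 dB passband gain, perturbed by the
    sample-level LNA and multiplexer noise equivalents, and quantized.
    Saturation events are counted in the metadata, never silent.
    """
    if timing.Tconv > 0 and timing.Tconv < 110e-9:
        raise ValueError("Tconv >= 110 ns is required for ADC conversion")
    if timing.M > scene.n_electrodes:
        raise ValueError("M exceeds the number of electrodes in the scene")
    M = timing.M
    rate = oversample * timing.fs
    n_slot = oversample
    n_conv = int(round(timing.Tconv * rate))
    if n_conv >= n_slot:
        raise ValueError("Tconv leaves no integration window at this oversample")
    n_ts = n_slot - n_conv
    ts_eff = n_ts / rate
    if timing.Tconv > 0 and abs(ts_eff - timing.Ts) > 0.05 * timing.Ts:
        raise ValueError(
            f"oversample {oversample} cannot represent Tconv={timing.Tconv:.3g} s "
            f"(effective Ts {ts_eff:.3g} vs requested {timing.Ts:.3g})"
        )

    n_frames = int(math.floor(duration * timing.fch))
    if n_frames < 1:
        raise ValueError("duration shorter than one frame")
    n_grid = n_frames * M * n_slot

    from .calibration import CalibrationState  # local import, no cycle at load

    if calibration is None:
        calibration = CalibrationState.ideal(M)
    # codes may be the half-LSB ideal midpoints (floats), which map to
    # exactly zero correction
    coarse_corr = np.array([
        coarse_dac_offset(float(c), config) for c in calibration.coarse_codes[:M]
    ])
    fine_corr = np.array([
        fine_dac_offset(float(c), config) for c in calibration.fine_codes[:M]
    ])

    lna_gain = config.lna_gain
    wis_gain = config.wis_gain(ts_eff)
    a = 2.0 * math.pi * config.lna_bandwidth
    decay_conv = math.exp(-a * (n_conv / rate))
    # mean of the residual exponential over the integration window
    res_mean_factor = (1.0 - math.exp(-a * ts_eff)) / (a * ts_eff)

    mean_w = np.empty((M, n_frames))
    w_start = np.empty((M, n_frames))
    w_end = np.empty((M, n_frames))
    for e in range(M):
        w = render_electrode_voltage(scene, e, duration, rate, include=include)
        samples = w.samples[:n_grid]
        # grid samples for this electrode's slots: frame f, slot index f*M+e
        starts = (np.arange(n_frames) * M + e) * n_slot
        win = starts[:, None] + np.arange(n_conv, n_slot)[None, :]
        mean_w[e] = samples[win].mean(axis=1)
        w_start[e] = samples[starts]
        w_end[e] = samples[starts + n_slot - 1]

    # LNA output targets (coarse correction applied at the input)
    vota_mean = lna_gain * (mean_w - coarse_corr[:, None])
    vota_start = lna_gain * (w_start - coarse_corr[:, None])
    vota_end = lna_gain * (w_end - coarse_corr[:, None])

    # previous slot's settled LNA output, slot order
    vota_end_flat = vota_end.T.reshape(-1)        # slot-ordered
    vota_start_flat = vota_start.T.reshape(-1)
    prev_end = np.concatenate(([0.0], vota_end_flat[:-1]))
    residual0 = (prev_end - vota_start_flat) * decay_conv
    residual_mean = residual0 * res_mean_factor

    vota_avg = vota_mean.T.reshape(-1) + residual_mean
    fine_flat = np.tile(fine_corr, n_frames)
    v_adc = wis_gain * (vota_avg - fine_flat)

    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xF0])
    if lna_noise and config.lna_noise_density > 0:
        sigma_in = config.lna_noise_density * math.sqrt(1.0 / (2.0 * ts_eff))
        v_adc = v_adc + rng.standard_normal(v_adc.size) * (
            sigma_in * lna_gain * wis_gain
        )
    if mux_noise and config.mux_r_on > 0:
        sigma_mux = mux_switch_noise(
            config.mux_r_on, 1.0 / (2.0 * ts_eff), config.temperature
        )
        v_adc = v_adc + rng.standard_normal(v_adc.size) * (
            sigma_mux * lna_gain * wis_gain
        )

    codes, saturated = adc_quantize(v_adc, config)
    return SampleStream(
        codes=codes,
        timing=timing,
        channel_map=np.arange(M),
        config=config,
        calibration=calibration,
        metadata={
            "seed": int(seed),
            "duration_s": float(n_frames / timing.fch),
            "oversample": int(oversample),
            "ts_effective_s": float(ts_eff),
            "passband_gain": float(lna_gain * wis_gain),
            "n_saturated": int(np.sum(saturated)),
            "config_hash": config.config_hash(),
        },
    )
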