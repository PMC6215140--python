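"""Mixed-signal offset calibration: binary search over the DAC codes.

Electrode DC offsets (tens of mV) would saturate the 60 dB chain, so
each electrode gets a coarse (4-bit, input-referred) and a fine (5-bit,
GM-input-referred) correction code, found by a SAR-style binary search
that only observes averaged ADC output codes: the coarse stage drives
the demultiplexed mean code toward mid-scale MSB-first, then the fine
stage refines the residual.  Offsets change slowly, so the codes are
recalculated on a slow schedule (1 Hz by default) and held in between.

Rounding detail: a sign-only comparison against mid-code would leave up
to one full coarse LSB of residual -- more than the fine DAC can absorb.
The search therefore biases each stage's comparison by half of its own
step (the coarse stage by parking the fine DAC near half a coarse LSB,
the fine stage by shifting the digital mid-code threshold), so each
stage lands on the *nearest* code with no extra trials: exactly
4 + 5 trial settings per electrode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frontend import (
    FrontEndConfig,
    adc_quantize,
    coarse_dac_offset,
    fine_dac_offset,
    mux_switch_noise,
)
from .neb import MuxTiming


@dataclass
class CalibrationState:
    """Per-electrode DAC codes with residual estimates and flags."""

    coarse_codes: np.ndarray
    fine_codes: np.ndarray
    residual_estimate: np.ndarray   # input-referred volts
    converged: np.ndarray
    saturated: np.ndarray
    n_trials: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.coarse_codes = np.atleast_1d(np.asarray(self.coarse_codes))
        self.fine_codes = np.atleast_1d(np.asarray(self.fine_codes))
        self.residual_estimate = np.atleast_1d(
            np.asarray(self.residual_estimate, float))
        self.converged = np.atleast_1d(np.asarray(self.converged, bool))
        self.saturated = np.atleast_1d(np.asarray(self.saturated, bool))
        if self.n_trials is None:
            self.n_trials = np.zeros_like(self.coarse_codes, dtype=int)
        if not np.all(np.isfinite(self.residual_estimate)):
            raise ValueError("residual estimates must be finite")

    @classmethod
    def ideal(cls, n_electrodes: int) -> "CalibrationState":
        """Zero-correction reference state.

        The offset-binary DAC maps have no exact-zero code, so the ideal
        state uses the half-LSB midpoint codes (7.5 / 15.5), which map
        to exactly zero correction.  Useful as the no-offset baseline
        for gain and noise characterization.
        """
        return cls(
            coarse_codes=np.full(n_electrodes, 7.5),
            fine_codes=np.full(n_electrodes, 15.5),
            residual_estimate=np.zeros(n_electrodes),
            converged=np.ones(n_electrodes, bool),
            saturated=np.zeros(n_electrodes, bool),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "electrode": np.arange(self.coarse_codes.size),
            "coarse_code": self.coarse_codes,
            "fine_code": self.fine_codes,
            "residual_v": self.residual_estimate,
            "converged": self.converged,
            "saturated": self.saturated,
            "n_trials": self.n_trials,
        })

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class PolarityError(RuntimeError):
    """The acquire response rises with increasing correction: mis-wired
    feedback polarity (or a non-monotone DAC)."""


def calibrate_electrode(acquire, config: FrontEndConfig, Ts: float = 1.5e-6):
    """Binary-search the coarse and fine codes for one electrode.

    ``acquire(coarse_code, fine_code)`` must return the averaged
    demultiplexed ADC code for a trial DAC setting.  Returns a
    single-electrode :class:`CalibrationState`.

    The final input-referred residual is at most half a fine-DAC step
    (~0.18 mV electrode-referred at the default 60 dB gain split)
    whenever the true offset lies within the correctable range;
    otherwise the codes rail and the ``saturated`` flag is set.
    """
    gain = config.passband_gain(Ts)
    lna_gain = config.lna_gain
    mid = config.adc_mid
    top = 2 ** config.adc_bits - 1
    code_to_volts = config.adc_lsb / gain   # ADC code -> input-referred V

    n_calls = 0
    observed = []  # (total input-referred correction, mean code)

    def trial(c, f):
        nonlocal n_calls
        n_calls += 1
        m = float(acquire(int(c), int(f)))
        corr = coarse_dac_offset(int(c), config) + fine_dac_offset(int(f), config) / lna_gain
        observed.append((corr, m))
        return m

    # --- coarse stage: park the fine DAC near -coarse_lsb/2 so the sign
    # comparison implements nearest-code rounding even while the ADC
    # clamps (a digital threshold alone cannot reach half a coarse LSB,
    # which is ~1200 ADC codes, past the clamp); the fine DAC's own
    # quantization of that half-LSB point is absorbed into a small
    # digital threshold correction so the rounding boundary is exact
    f_bias_target = -lna_gain * config.coarse_lsb / 2.0
    f_bias = int(round((2 ** config.fine_bits - 1) / 2.0
                       + f_bias_target / config.fine_lsb))
    f_bias = int(np.clip(f_bias, 0, 2 ** config.fine_bits - 1))
    d_codes = (-config.coarse_lsb / 2.0
               - fine_dac_offset(f_bias, config) / lna_gain) / code_to_volts
    coarse = 0
    for bit in tuple(2 ** b for b in range(config.coarse_bits - 1, -1, -1)):
        m = trial(coarse + bit, f_bias)
        if m >= mid + d_codes:
            coarse += bit

    # --- fine stage: shift the digital threshold by half a fine step
    half_step_codes = (config.fine_lsb / lna_gain / 2.0) * gain / config.adc_lsb
    fine = 0
    m_last = None
    kept_last = False
    for bit in tuple(2 ** b for b in range(config.fine_bits - 1, -1, -1)):
        m_last = trial(coarse, fine + bit)
        kept_last = m_last >= mid - half_step_codes
        if kept_last:
            fine += bit

    # residual estimate from the last measurement, corrected for the
    # difference between the last trial's fine code and the final one
    last_trial_fine = fine if kept_last else fine + 1
    resid = (m_last - mid) * code_to_volts + (
        fine_dac_offset(last_trial_fine, config) - fine_dac_offset(fine, config)
    ) / lna_gain

    # polarity sanity check on unclamped observations
    unclamped = [(c, m) for c, m in observed if 0 < m < top]
    if len(unclamped) >= 2:
        corr_arr = np.array([c for c, _ in unclamped])
        m_arr = np.array([m for _, m in unclamped])
        if np.ptp(corr_arr) > 0:
            slope = np.polyfit(corr_arr, m_arr, 1)[0]
            if slope > 0:
                raise PolarityError(
                    "mean ADC code increases with the applied correction; "
                    "check the feedback polarity"
                )

    fine_lsb_in = config.fine_lsb / lna_gain
    at_rail = coarse in (0, 2 ** config.coarse_bits - 1) or fine in (
        0, 2 ** config.fine_bits - 1)
    saturated = bool(abs(resid) > fine_lsb_in and at_rail)
    return CalibrationState(
        coarse_codes=np.array([coarse]),
        fine_codes=np.array([fine]),
        residual_estimate=np.array([resid]),
        converged=np.array([not saturated]),
        saturated=np.array([saturated]),
        n_trials=np.array([n_calls]),
    )


def make_acquire(
    v_offset: float,
    timing: MuxTiming,
    config: FrontEndConfig,
    n_avg: int = 64,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    extra_noise_rms: float = 0.0,
):
    """Build an ``acquire(coarse, fine)`` callable around the sample model.

    Each call simulates ``n_avg`` acquired samples of a DC electrode at
    ``v_offset`` with the trial DAC codes applied, with the sample-level
    LNA and multiplexer noise equivalents (plus any extra input-referred
    noise, e.g. biological background), and returns the mean ADC code.
    Averaging suppresses the noise so the search decisions stay reliable.
    """
    rng = rng or np.random.default_rng()
    Ts = timing.Ts
    gain = config.passband_gain(Ts)
    wis_gain = config.wis_gain(Ts)

    sigma_in = 0.0
    if noise:
        sigma_in = math.sqrt(
            (config.lna_noise_density ** 2) / (2.0 * Ts)
            + mux_switch_noise(config.mux_r_on, 1.0 / (2.0 * Ts),
                               config.temperature) ** 2
            + extra_noise_rms ** 2
        )

    def acquire(coarse_code: int, fine_code: int) -> float:
        vc = coarse_dac_offset(int(coarse_code), config)
        vf = fine_dac_offset(int(fine_code), config)
        v_in = v_offset - vc
        if sigma_in > 0:
            v_in = v_in + rng.standard_normal(n_avg) * sigma_in
        v_adc = wis_gain * (config.lna_gain * v_in - vf)
        codes, _ = adc_quantize(np.broadcast_to(v_adc, (n_avg,)).copy(), config)
        return float(np.mean(codes))

    return acquire


def calibrate_scene(
    scene,
    timing: MuxTiming,
    config: FrontEndConfig,
    n_avg: int = 64,
    seed: int = 0,
    noise: bool = True,
) -> CalibrationState:
    """Calibrate every multiplexed electrode of a scene."""
    states = []
    for e in range(timing.M):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xCA, e])
        acq = make_acquire(
            float(scene.dc_offsets[e]), timing, config, n_avg=n_avg, rng=rng,
            noise=noise, extra_noise_rms=scene.background_noise_rms if noise else 0.0,
        )
        states.append(calibrate_electrode(acq, config, Ts=timing.Ts))
    return CalibrationState(
        coarse_codes=np.concatenate([s.coarse_codes for s in states]),
        fine_codes=np.concatenate([s.fine_codes for s in states]),
        residual_estimate=np.concatenate([s.residual_estimate for s in states]),
        converged=np.concatenate([s.converged for s in states]),
        saturated=np.concatenate([s.saturated for s in states]),
        n_trials=np.concatenate([s.n_trials for s in states]),
    )


def schedule_recalibration(stream_time: float, period: float = 1.0) -> np.ndarray:
    """Calibration epochs: t = 0 and every ``period`` up to ``stream_time``.

    Codes are held constant between epochs.  A 4 s run at the default
    1 s period yields epochs at t = 0, 1, 2, 3, 4.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if stream_time < 0:
        raise ValueError("stream_time must be >= 0")
    n = int(math.floor(stream_time / period + 1e-9))
    return np.arange(n + 1) * period
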