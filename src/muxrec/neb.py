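"""Noise-equivalent-bandwidth theory for multiplexed acquisition.

The noise equivalent bandwidth (NEB) of a magnitude response H(f) with
unit DC gain is the width of the brick-wall filter passing the same
noise power::

    NEB = integral_0^inf |H(f)|^2 df

Two sampling disciplines are compared for a chain that time-multiplexes
M electrodes at an aggregate rate fs = M * fch:

* *Instantaneous voltage sampling* samples the settled amplifier output
  at the end of each slot.  Settling to a fractional error eps within a
  window Ts requires a single-pole bandwidth
  ``f_bw = -ln(eps) / (2 pi Ts)``, so
  ``NEB_vs = pi f_bw / 2 = -M fch ln(eps) / 4``: it grows with M and
  with the demanded settling accuracy.

* *Windowed integration sampling* (WIS) integrates the signal over the
  window Ts before sampling, which imposes a sinc magnitude response
  with ``NEB_wis = 1/(2 Ts)`` -- independent of any settling tolerance.

Noise at frequencies above fch/2 aliases into the per-channel samples,
so the variance of one acquired sample is the input PSD weighted by the
squared sampling response, integrated over all frequency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .electrode import ElectrodeModel, NoisePSD, thermal_noise_psd


@dataclass(frozen=True)
class MuxTiming:
    """Multiplexing timing: M electrodes at per-channel rate fch.

    ``fs = M * fch`` is the aggregate slot rate.  ``Tconv`` is the
    conversion/settling overhead reserved at the start of each slot
    (idealized theory mode uses ``Tconv = 0`` so that ``Ts = 1/fs``;
    simulation mode uses ``Ts = 1/fs - Tconv``).
    """

    M: int
    fch: float
    Tconv: float = 0.0
    eps_dtol: float = 1e-3

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.fch <= 0:
            raise ValueError("fch must be positive")
        if not (0.0 < self.eps_dtol < 1.0):
            raise ValueError("eps_dtol must lie in (0, 1)")
        if self.Tconv < 0 or self.Tconv >= self.slot:
            if self.Tconv != 0.0:
                raise ValueError("Tconv must lie in [0, 1/fs)")

    @property
    def fs(self) -> float:
        return self.M * self.fch

    @property
    def slot(self) -> float:
        return 1.0 / self.fs

    @property
    def Ts(self) -> float:
        """Integration window: the slot minus the conversion overhead."""
        return self.slot - self.Tconv


@dataclass
class FrequencyResponse:
    """Magnitude response |H(f)| on an ascending frequency grid."""

    frequencies: np.ndarray
    gain: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        if self.frequencies.size != self.gain.size or self.frequencies.size < 2:
            raise ValueError("frequencies and gain must have equal length >= 2")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly ascending")


def neb_numeric(response: FrequencyResponse) -> float:
    """NEB of a tabulated response by trapezoidal integration of |H|^2.

    The gain is first normalized to unity at the lowest tabulated
    frequency (DC proxy).  The response must extend far enough that the
    tail contributes negligibly; the top decade contributing more than
    0.5% of the integral triggers a warning.
    """
    g0 = response.gain[0]
    if g0 == 0:
        raise ValueError("zero DC gain: response cannot be normalized")
    g2 = (response.gain / g0) ** 2
    f = response.frequencies
    total = np.trapezoid(g2, f)
    # flat-continuation tail estimate: the endpoint |H|^2 (peak over the
    # top 2% of the band, to be robust to oscillatory responses)
    # continued over one more bandwidth
    tail_mask = f >= 0.98 * f[-1]
    tail_est = float(np.max(g2[tail_mask]) * f[-1])
    if tail_est > 0.005 * total:
        warnings.warn(
            f"integrand tail (~{tail_est / total:.1%} of the NEB integral) is "
            "not negligible; extend the frequency support"
        )
    return float(total)


def settling_bandwidth(eps_dtol: float, Ts: float) -> float:
    """Single-pole bandwidth for fractional settling error eps within Ts.

    ``f_bw = -ln(eps) / (2 pi Ts)``: the residual of a first-order step
    response after Ts equals ``exp(-2 pi f_bw Ts) = eps``.
    """
    if not (0.0 < eps_dtol < 1.0):
        raise ValueError("eps_dtol must lie in (0, 1)")
    if Ts <= 0:
        raise ValueError("Ts must be positive")
    return -math.log(eps_dtol) / (2.0 * math.pi * Ts)


def neb_voltage_sampling(timing: MuxTiming) -> float:
    """NEB of instantaneous voltage sampling: ``-M fch ln(eps)/4``.

    Equals ``pi/2`` times the settling bandwidth for ``Ts = 1/fs``
    (idealized mode, no conversion overhead).
    """
    return -timing.M * timing.fch * math.log(timing.eps_dtol) / 4.0


def neb_wis(Ts: float) -> float:
    """NEB of windowed integration sampling: ``1/(2 Ts)``."""
    if Ts <= 0:
        raise ValueError("Ts must be positive")
    return 1.0 / (2.0 * Ts)


def wis_magnitude_response(f, Ts: float):
    """|sinc(f Ts)| = |sin(pi f Ts)/(pi f Ts)|, unit gain at DC.

    Zeros fall at integer multiples of 1/Ts, which is what suppresses
    high-frequency noise before it aliases into the channel samples.
    """
    if Ts <= 0:
        raise ValueError("Ts must be positive")
    return np.abs(np.sinc(np.asarray(f, dtype=float) * Ts))


def neb_ratios(timing: MuxTiming) -> dict:
    """NEB of both sampling modes relative to a traditional channel.

    The traditional (non-multiplexed) reference is a single-pole
    recording channel with its pole at the AP bandwidth fch/3 (the
    per-channel rate is taken as 3x the AP bandwidth), hence
    ``NEB_trad = pi (fch/3) / 2``.  Returns::

        vs_over_trad  = -M ln(eps) 3/(2 pi)
        wis_over_trad = M 3/pi
        vs_over_wis   = -ln(eps)/2   (independent of M and fch)
    """
    neb_trad = math.pi * (timing.fch / 3.0) / 2.0
    vs = neb_voltage_sampling(timing)
    wis = neb_wis(1.0 / timing.fs)  # idealized Ts = 1/fs
    return {
        "vs_over_trad": vs / neb_trad,
        "wis_over_trad": wis / neb_trad,
        "vs_over_wis": -math.log(timing.eps_dtol) / 2.0,
    }


@dataclass(frozen=True)
class WisMode:
    """Windowed-integration sampling response: sinc with window Ts."""

    Ts: float

    def gain_squared(self, f):
        return wis_magnitude_response(f, self.Ts) ** 2

    @property
    def neb(self) -> float:
        return neb_wis(self.Ts)

    def tail_integral(self, psd_tail: float, f_from: float) -> float:
        # mean of sin^2 is 1/2: integral_F^inf S/(2 (pi f Ts)^2) df
        return psd_tail / (2.0 * (math.pi * self.Ts) ** 2 * f_from)


@dataclass(frozen=True)
class VoltageSamplingMode:
    """Instantaneous voltage sampling: single pole at the settling bandwidth.

    The alias-weighting response is the same single pole from which the
    closed-form NEB is derived: ``|H|^2 = 1/(1 + (f/f_bw)^2)`` with
    ``f_bw = -ln(eps)/(2 pi Ts)``.
    """

    Ts: float
    eps_dtol: float = 1e-3
    f_bw: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "f_bw", settling_bandwidth(self.eps_dtol, self.Ts))

    def gain_squared(self, f):
        f = np.asarray(f, dtype=float)
        return 1.0 / (1.0 + (f / self.f_bw) ** 2)

    @property
    def neb(self) -> float:
        return math.pi * self.f_bw / 2.0

    def tail_integral(self, psd_tail: float, f_from: float) -> float:
        # integral_F^inf S (f_bw/f)^2 df = S f_bw^2 / F
        return psd_tail * self.f_bw ** 2 / f_from


def aliased_sample_variance(psd: NoisePSD, mode) -> float:
    """Variance of one acquired sample: ``integral psd(f) |H(f)|^2 df``.

    All input noise, whatever its frequency, lands in the samples after
    aliasing; the sampling response merely weights it.  For a flat PSD
    S0 the result is ``S0 * NEB`` of the mode.

    The tabulated PSD must extend far enough that the (flat-continuation)
    tail estimate stays below 0.5% of the integral, otherwise an error
    names the required support.  The tail estimate is added to the
    returned value.
    """
    fr, s = psd.frequencies, psd.psd
    f_lo = fr[0] if fr[0] > 0 else (fr[1] if fr.size > 1 else 0.0)
    f_hi = fr[-1]
    # Dense grid: resolve the sinc lobes (>= 32 points per 1/Ts period).
    if isinstance(mode, WisMode):
        n = int(np.ceil(32.0 * mode.Ts * f_hi)) + 1
    else:
        n = 20001
    n = int(np.clip(max(n, fr.size), 2, 4_000_000))
    dense = np.linspace(0.0 if fr[0] == 0 else f_lo, f_hi, n)
    grid = np.union1d(dense, fr)
    s_grid = np.interp(grid, fr, s)
    integrand = s_grid * mode.gain_squared(grid)
    total = float(np.trapezoid(integrand, grid))
    tail = float(mode.tail_integral(s[-1], f_hi))
    if tail > 0.005 * (total + tail):
        f_req = f_hi * tail / (0.005 * (total + tail))
        raise ValueError(
            f"PSD support ends at {f_hi:.3g} Hz but the aliased tail is "
            f"{tail / (total + tail):.2%} of the sample variance; extend the "
            f"PSD to roughly {f_req:.3g} Hz"
        )
    return total + tail


def tin_vs_m(
    model: ElectrodeModel,
    fch: float,
    M_values,
    eps_dtol: float = 1e-3,
    Tconv: float = 0.0,
    include_cin: bool = False,
) -> pd.DataFrame:
    """Total integrated electrode thermal noise versus multiplexing factor.

    For each M the electrode thermal PSD (``4 k T Re[Z]``) is weighted by
    the voltage-sampling and WIS responses and integrated, giving the rms
    thermal noise one sample carries.  WIS sits below voltage sampling at
    every M, and both curves grow with M as the per-slot window shrinks.

    ``Tconv = 0`` is the idealized theory mode (Ts = 1/fs); a positive
    Tconv reproduces the simulation timing (Ts = 1/fs - Tconv).
    """
    rows = []
    for M in M_values:
        timing = MuxTiming(M=int(M), fch=fch, Tconv=Tconv, eps_dtol=eps_dtol)
        Ts = timing.Ts
        wis = WisMode(Ts)
        vs = VoltageSamplingMode(Ts, eps_dtol)
        # PSD support: far enough that both modes' tails are < 0.5%.
        f_hi = max(400.0 / Ts, 200.0 * vs.f_bw)
        freqs = np.unique(np.concatenate([
            np.logspace(0, np.log10(f_hi), 4000),
            np.linspace(1.0, f_hi, 200_000),
        ]))
        psd = NoisePSD(freqs, thermal_noise_psd(model, freqs, include_cin=include_cin))
        rows.append({
            "M": int(M),
            "neb_vs_hz": vs.neb,
            "neb_wis_hz": wis.neb,
            "tin_vs_vrms": math.sqrt(aliased_sample_variance(psd, vs)),
            "tin_wis_vrms": math.sqrt(aliased_sample_variance(psd, wis)),
        })
    return pd.DataFrame(rows)
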