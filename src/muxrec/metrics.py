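"""Analysis of acquired sample streams.

Covers the post-processing used to validate the acquisition chain:
demultiplexing the interleaved codes into per-electrode series referred
back to the electrode (volts), digital band-pass filtering for AP
detection, threshold-crossing spike detection with time-amplitude
("hoop") acceptance windows, the peak-to-peak-over-noise SNR of sorted
mean waveforms, noise-floor estimation with events excised, grounded-
input input-referred noise with Welch spectra, the noise efficiency
factor, FFT-based THD, and histogram-method ADC DNL/INL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .electrode import K_BOLTZMANN
from .frontend import SampleStream


def demultiplex(stream: SampleStream, downsample: int = 1):
    """De-interleave a stream into per-electrode series at fch.

    Codes are referred back to the electrode in volts via
    ``(code - mid) * LSB / passband_gain``.  Optional integer-factor
    downsampling simply throws away samples.  Returns
    ``(volts, rate)`` with ``volts`` shaped (M, n_samples).
    """
    if downsample < 1 or int(downsample) != downsample:
        raise ValueError("downsample must be a positive integer")
    M = stream.timing.M
    if stream.codes.size < M:
        raise ValueError("stream shorter than one frame")
    cmap = np.asarray(stream.channel_map)
    if cmap.size != M or sorted(cmap.tolist()) != list(range(M)):
        raise ValueError("channel map must be a permutation of 0..M-1")
    gain = stream.metadata.get(
        "passband_gain", stream.config.passband_gain(stream.timing.Ts)
    )
    frames = stream.codes.reshape(-1, M).astype(float)
    volts = np.empty_like(frames.T)
    for slot, electrode in enumerate(cmap):
        volts[electrode] = frames[:, slot]
    volts = (volts - stream.config.adc_mid) * stream.config.adc_lsb / gain
    volts = volts[:, ::downsample]
    return volts, stream.timing.fch / downsample


def bandpass(series, fs: float, lo: float = 800.0, hi: float = 4000.0):
    """Zero-phase 4th-order Butterworth band-pass (applied forward-backward).

    The default 0.8-4 kHz band isolates action-potential energy; DC and
    offsets are fully rejected.
    """
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"require 0 < lo < hi < fs/2, got ({lo}, {hi}) at fs={fs}")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, float), axis=-1)


@dataclass
class SortedEvents:
    """Threshold-crossing events that passed the hoop windows."""

    crossing_times: np.ndarray      # s
    snippets: np.ndarray            # (n_events, n_samples), V
    mean_waveform: np.ndarray       # pointwise mean of snippets, V
    deviations: np.ndarray          # snippets - mean
    sd_eps: float                   # std over all deviation entries
    threshold: float                # V
    hoop_windows: tuple
    window: tuple                   # (pre_s, post_s)
    sample_rate: float


def detect_and_sort(
    series,
    fs: float,
    threshold: float,
    hoops=(),
    refractory: float = 1.0e-3,
    window: tuple = (0.4e-3, 1.0e-3),
) -> SortedEvents:
    """Detect threshold crossings and sort them with hoop windows.

    A negative threshold detects negative-going crossings (the usual
    convention for extracellular APs, which lead with a negative phase);
    a positive threshold detects positive-going ones.  Crossings within
    the refractory lockout of a previous event are ignored.  A snippet
    (window[0] before to window[1] after the crossing) is kept only if,
    for every hoop ``(dt_s, v_lo, v_hi)``, its value at ``crossing +
    dt_s`` lies inside [v_lo, v_hi].  No events is an empty result, not
    an error.
    """
    if threshold == 0:
        raise ValueError("threshold must be nonzero")
    x = np.asarray(series, float)
    if threshold < 0:
        crossed = (x[1:] <= threshold) & (x[:-1] > threshold)
    else:
        crossed = (x[1:] >= threshold) & (x[:-1] < threshold)
    idx = np.flatnonzero(crossed) + 1

    lockout = max(int(round(refractory * fs)), 1)
    kept = []
    last = -lockout - 1
    for i in idx:
        if i - last > lockout:
            kept.append(i)
            last = i
    n_pre = int(round(window[0] * fs))
    n_post = int(round(window[1] * fs))
    n_len = n_pre + n_post + 1

    snippets, times = [], []
    for i in kept:
        if i - n_pre < 0 or i + n_post >= x.size:
            continue
        snip = x[i - n_pre: i + n_post + 1]
        ok = True
        for dt, v_lo, v_hi in hoops:
            j = n_pre + int(round(dt * fs))
            if j < 0 or j >= n_len or not (v_lo <= snip[j] <= v_hi):
                ok = False
                break
        if ok:
            snippets.append(snip)
            times.append(i / fs)

    if snippets:
        snippets = np.vstack(snippets)
        mean_wf = snippets.mean(axis=0)
        dev = snippets - mean_wf
        sd_eps = float(dev.std())
    else:
        snippets = np.empty((0, n_len))
        mean_wf = np.zeros(n_len)
        dev = np.empty((0, n_len))
        sd_eps = 0.0
    return SortedEvents(
        crossing_times=np.asarray(times),
        snippets=snippets,
        mean_waveform=mean_wf,
        deviations=dev,
        sd_eps=sd_eps,
        threshold=float(threshold),
        hoop_windows=tuple(hoops),
        window=window,
        sample_rate=fs,
    )


def snr_waveforms(events: SortedEvents) -> float:
    """Peak-to-peak of the mean waveform over the deviation SD.

    ``SNR = (max(W) - min(W)) / SD_eps`` where W is the mean sorted
    waveform and SD_eps the standard deviation over all entries of the
    snippet-minus-mean matrix.  Dimensionless, invariant to joint gain
    scaling.  With identical snippets (SD_eps = 0) the SNR is flagged
    infinite.
    """
    if events.snippets.shape[0] < 2:
        raise ValueError("need >= 2 events to estimate SNR")
    ptp = float(events.mean_waveform.max() - events.mean_waveform.min())
    if events.sd_eps == 0:
        return math.inf
    return ptp / events.sd_eps


def noise_floor(series, fs: float, events: SortedEvents | None = None,
                window: tuple | None = None) -> float:
    """RMS of the series with the detected event windows excised."""
    x = np.asarray(series, float)
    keep = np.ones(x.size, bool)
    if events is not None and events.crossing_times.size:
        win = window or events.window
        n_pre = int(round(win[0] * fs))
        n_post = int(round(win[1] * fs))
        for t in events.crossing_times:
            i = int(round(t * fs))
            keep[max(i - n_pre, 0): i + n_post + 1] = False
    if not keep.any():
        raise ValueError("event excision removed the entire series")
    return float(np.sqrt(np.mean(x[keep] ** 2)))


def input_referred_noise(stream: SampleStream, nperseg: int = 4096):
    """Input-referred rms noise and Welch spectra of a grounded-input run.

    Per-channel means are removed (they carry residual offset, not
    noise), the rms is taken over all channels, and Welch spectra (Hann,
    50% overlap) are returned both for the interleaved stream at fs and
    for the demultiplexed channels at fch (averaged across channels).
    """
    volts, fch = demultiplex(stream)
    centered = volts - volts.mean(axis=1, keepdims=True)
    v_rms = float(np.sqrt(np.mean(centered ** 2)))

    gain = stream.metadata.get(
        "passband_gain", stream.config.passband_gain(stream.timing.Ts)
    )
    interleaved = (stream.codes.astype(float) - stream.config.adc_mid) \
        * stream.config.adc_lsb / gain
    interleaved -= interleaved.mean()
    fs = stream.timing.fs
    f_hi, p_hi = signal.welch(
        interleaved, fs=fs, nperseg=min(nperseg, interleaved.size))
    f_lo, p_lo = signal.welch(
        centered, fs=fch, nperseg=min(nperseg, centered.shape[1]), axis=-1)
    return v_rms, {"fs": (f_hi, p_hi), "fch": (f_lo, p_lo.mean(axis=0))}


def nef(v_rms_in: float, supply_current: float, bandwidth: float,
        UT: float = 0.02585, T: float = 300.0) -> float:
    """Noise efficiency factor of an amplifier.

    ``NEF = V_rms,in * sqrt(2 I / (pi UT 4 k T BW))`` -- the input noise
    relative to a single ideal bipolar transistor burning the same
    current over the same bandwidth.
    """
    if min(v_rms_in, supply_current, bandwidth, UT, T) <= 0:
        raise ValueError("all NEF inputs must be positive")
    return v_rms_in * math.sqrt(
        2.0 * supply_current / (math.pi * UT * 4.0 * K_BOLTZMANN * T * bandwidth)
    )


def thd_fft(series, fs: float, f0: float, n_harmonics: int = 5) -> float:
    """Total harmonic distortion of a tone at f0 from the FFT.

    Hann-windowed spectrum; each component's amplitude is the square
    root of the power summed over +/-2 bins around its peak.  Returns
    ``sqrt(sum of harmonic powers 2..n) / fundamental`` as a fraction.
    """
    x = np.asarray(series, float)
    n = x.size
    if f0 <= 0 or f0 < 4.0 * fs / n:
        raise ValueError("f0 not resolvable in this record length")
    x = x - x.mean()
    w = np.hanning(n)
    spec = np.abs(np.fft.rfft(x * w)) ** 2
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    df = fs / n

    def comp_power(fk):
        k = int(round(fk / df))
        if k >= freqs.size:
            return 0.0
        k = k - 2 + int(np.argmax(spec[max(k - 2, 0): k + 3]))
        lo, hi = max(k - 2, 0), min(k + 3, spec.size)
        return float(spec[lo:hi].sum())

    p1 = comp_power(f0)
    if p1 <= 0:
        raise ValueError("no fundamental found at f0")
    p_h = sum(comp_power(k * f0) for k in range(2, n_harmonics + 1)
              if k * f0 < fs / 2)
    return math.sqrt(p_h / p1)


def adc_histogram_linearity(codes, bits: int):
    """Histogram-method DNL and INL from a full-scale sine record.

    The code-density histogram is normalized by the arcsine probability
    density of an ideal sine (amplitude and offset fitted to the
    cumulative histogram); DNL per code is the normalized bin width
    minus 1 and INL is its cumulative sum under the endpoint-fit
    convention.  The first and last codes absorb clipping and are
    excluded.  Codes never exercised are reported as missing.

    Returns ``(dnl, inl, missing_codes)`` with NaN DNL at the end codes
    and at missing codes.
    """
    codes = np.asarray(codes)
    n_codes = 2 ** bits
    h = np.bincount(codes.astype(int), minlength=n_codes).astype(float)
    n_total = h.sum()
    if n_total < 100 * n_codes:
        raise ValueError("need >= 100 samples per code on average")

    cum = np.cumsum(h) / n_total
    transitions = np.arange(n_codes - 1) + 0.5  # code-unit transition levels

    def model_cdf(params, t):
        c, a = params
        return 0.5 + np.arcsin(np.clip((t - c) / a, -1.0, 1.0)) / np.pi

    c0 = float(np.mean(codes))
    a0 = float(np.std(codes) * math.sqrt(2.0))
    fit = optimize.least_squares(
        lambda p: model_cdf(p, transitions) - cum[:-1],
        x0=[c0, max(a0, 1.0)],
    )
    c_fit, a_fit = fit.x

    p_ideal = np.diff(model_cdf((c_fit, a_fit),
                                np.concatenate(([-np.inf], transitions, [np.inf]))
                                .clip(c_fit - a_fit, c_fit + a_fit)))
    # normalize over interior codes only (end bins absorb clipping)
    interior = np.arange(1, n_codes - 1)
    scale = h[interior].sum() / p_ideal[interior].sum()
    dnl = np.full(n_codes, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        dnl[interior] = h[interior] / (scale * p_ideal[interior]) - 1.0
    missing = interior[h[interior] == 0]
    dnl[missing] = np.nan

    inl = np.full(n_codes, np.nan)
    run = np.cumsum(np.nan_to_num(dnl[interior]))
    # endpoint fit: remove the straight line through the first and last
    # interior cumulative values
    line = run[0] + (run[-1] - run[0]) * np.linspace(0, 1, run.size)
    inl[interior] = run - line
    return dnl, inl, missing
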