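"""Synthetic multi-electrode scenes and the multiplexed input waveform.

A scene is the ground truth a simulated front end sees: per-electrode
DC offsets (tens of millivolts -- the differential polarization
potential between each electrode and the reference), sparse action
potential trains (sub-millivolt biphasic transients), band-limited
"biological" background noise in the AP band, and electrode thermal
noise whose spectrum follows the Randles-model prediction.

When M electrodes are time-division multiplexed onto one acquisition
circuit, the input hops between electrode potentials every slot: the
waveform is dominated by step transitions between DC offsets, with the
neural signal riding on top at a scale 1-2 orders of magnitude smaller.
That step-like structure is why simple AC coupling cannot be used and
offsets must be cancelled by feedback DACs instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .electrode import ElectrodeModel, MICROWIRE_LIKE, thermal_noise_psd
from .neb import MuxTiming


@dataclass
class SpikeTemplate:
    """Biphasic (negative-leading) cosine-windowed action potential shape.

    ``amplitude`` is the magnitude of the dominant (negative) peak in
    volts; extracellular APs are < 1 mV.  ``duration`` is the total
    support of the waveform.
    """

    amplitude: float = 300e-6
    duration: float = 1.0e-3
    second_phase_ratio: float = 0.45  # positive rebound relative to the trough

    def waveform(self, rate: float) -> np.ndarray:
        n = max(int(round(self.duration * rate)), 8)
        t = np.arange(n) / n  # normalized 0..1
        # negative trough in the first 40%, positive rebound after
        trough = -np.sin(np.pi * np.clip(t / 0.4, 0.0, 1.0)) ** 2
        rebound = (self.second_phase_ratio
                   * np.sin(np.pi * np.clip((t - 0.4) / 0.6, 0.0, 1.0)) ** 2)
        w = trough + rebound
        return self.amplitude * w / np.max(np.abs(w))


@dataclass
class SceneConfig:
    """Generation parameters for a synthetic scene.

    Defaults: offsets uniform in +/-50 mV (the upper end of the 1-50 mV
    scale typical of metal microelectrodes against a shared reference),
    Poisson spike trains at 20 Hz with a 300 uV biphasic template, 8 uV
    rms biological background confined to 0.3-7.5 kHz, and electrode
    thermal noise from a microwire-like Randles model.
    """

    n_electrodes: int = 16
    offset_range: tuple = (-50e-3, 50e-3)
    spike_rate: float = 20.0
    templates: tuple = (SpikeTemplate(),)
    background_noise_rms: float = 8e-6
    background_band: tuple = (300.0, 7500.0)
    electrode_model: ElectrodeModel | None = MICROWIRE_LIKE
    duration: float = 1.0  # horizon over which spike trains are drawn, s

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise ValueError("n_electrodes must be >= 1")
        if self.offset_range[0] >= self.offset_range[1]:
            raise ValueError("offset_range must be (lo, hi) with lo < hi")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        if self.background_noise_rms < 0:
            raise ValueError("background_noise_rms must be >= 0")


@dataclass
class NeuralScene:
    """Ground truth for a multi-electrode recording scene."""

    n_electrodes: int
    dc_offsets: np.ndarray             # V, one per electrode
    spike_trains: list                 # per electrode: sorted event times (s)
    template_ids: np.ndarray           # per electrode: index into templates
    templates: tuple
    background_noise_rms: float
    background_band: tuple
    electrode_model: ElectrodeModel | None
    seed: int

    def ground_truth_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "n_electrodes": int(self.n_electrodes),
            "dc_offsets_v": [float(x) for x in self.dc_offsets],
            "template_ids": [int(i) for i in self.template_ids],
            "spike_times_s": {
                int(e): [float(t) for t in tr]
                for e, tr in enumerate(self.spike_trains)
            },
        }

    def write_ground_truth(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.ground_truth_dict(), fh, sort_keys=True)


@dataclass
class ContinuousWaveform:
    """Uniformly sampled voltage trace."""

    sample_rate: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sample_rate


def _rng(seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def generate_scene(config: SceneConfig, seed: int) -> NeuralScene:
    """Draw a reproducible scene: offsets, spike trains, template choice.

    Offsets are uniform in the configured range; spike times are
    homogeneous Poisson over the configured duration.  The same seed
    always produces the same scene.
    """
    rng = _rng(seed, 0)
    offsets = rng.uniform(*config.offset_range, size=config.n_electrodes)
    template_ids = rng.integers(0, len(config.templates), size=config.n_electrodes)
    trains = []
    for e in range(config.n_electrodes):
        n_ev = rng.poisson(config.spike_rate * config.duration)
        trains.append(np.sort(rng.uniform(0.0, config.duration, size=n_ev)))
    return NeuralScene(
        n_electrodes=config.n_electrodes,
        dc_offsets=offsets,
        spike_trains=trains,
        template_ids=template_ids,
        templates=tuple(config.templates),
        background_noise_rms=config.background_noise_rms,
        background_band=config.background_band,
        electrode_model=config.electrode_model,
        seed=int(seed),
    )


def _shaped_noise(rng, n, rate, psd_fn) -> np.ndarray:
    """White Gaussian noise spectrally shaped to the one-sided PSD psd_fn(f)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    # unit-variance white noise has one-sided PSD 2/rate
    target = psd_fn(f)
    spec *= np.sqrt(target * rate / 2.0)
    return np.fft.irfft(spec, n=n)


def render_electrode_voltage(
    scene: NeuralScene,
    electrode_index: int,
    duration: float,
    rate: float,
    include=("offset", "spikes", "background", "thermal"),
) -> ContinuousWaveform:
    """Render one electrode's continuous voltage at the given rate.

    The trace is the sum of the DC offset, spike templates inserted at
    the ground-truth event times, Gaussian background noise band-limited
    to the configured AP band, and a thermal-noise realization whose PSD
    follows ``4 k T Re[Z]`` of the electrode model.  Each component uses
    an independent seeded substream, so any subset reproduces exactly.
    """
    n = int(round(duration * rate))
    v = np.zeros(n)
    e = int(electrode_index)
    if e < 0 or e >= scene.n_electrodes:
        raise IndexError(f"electrode {e} out of range")

    if "offset" in include:
        v += scene.dc_offsets[e]

    if "spikes" in include and len(scene.spike_trains[e]) > 0:
        tmpl = scene.templates[scene.template_ids[e]].waveform(rate)
        for t_ev in scene.spike_trains[e]:
            i0 = int(round(t_ev * rate))
            if i0 >= n:
                continue
            i1 = min(i0 + tmpl.size, n)
            v[i0:i1] += tmpl[: i1 - i0]

    if "background" in include and scene.background_noise_rms > 0:
        lo, hi = scene.background_band
        hi = min(hi, 0.499 * rate)
        s0 = scene.background_noise_rms ** 2 / (hi - lo)
        rng = _rng(scene.seed, e, 1)
        v += _shaped_noise(
            rng, n, rate, lambda f: np.where((f >= lo) & (f <= hi), s0, 0.0)
        )

    if "thermal" in include and scene.electrode_model is not None:
        model = scene.electrode_model
        rng = _rng(scene.seed, e, 2)

        def psd(f):
            out = np.zeros_like(f)
            pos = f > 0
            out[pos] = thermal_noise_psd(model, f[pos])
            if np.any(~pos):
                out[~pos] = thermal_noise_psd(model, np.full((~pos).sum(), 1e-3))
            return out

        v += _shaped_noise(rng, n, rate, psd)

    return ContinuousWaveform(sample_rate=rate, samples=v)


def multiplexed_input(
    scene: NeuralScene,
    timing: MuxTiming,
    duration: float,
    rate: float,
    include=("offset", "spikes", "background", "thermal"),
):
    """Render the rapidly multiplexed input seen by the acquisition circuit.

    Electrodes 0..M-1 are visited round-robin at the aggregate rate fs;
    within each slot the waveform follows that electrode's own voltage
    trajectory, so slot boundaries show steps dominated by the DC offset
    differences.  Returns the waveform plus the slot -> electrode
    schedule for one frame.
    """
    ratio = rate / timing.fs
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError("rate must be a positive integer multiple of fs")
    if timing.M > scene.n_electrodes:
        raise ValueError(
            f"M={timing.M} exceeds the scene's {scene.n_electrodes} electrodes"
        )
    per_slot = int(round(ratio))
    n = int(round(duration * rate))
    out = np.empty(n)
    schedule = np.arange(timing.M)
    for e in range(timing.M):
        w = render_electrode_voltage(scene, e, duration, rate, include=include)
        idx = np.arange(n)
        slot_of = (idx // per_slot) % timing.M
        sel = slot_of == e
        out[sel] = w.samples[sel]
    return ContinuousWaveform(sample_rate=rate, samples=out), schedule
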