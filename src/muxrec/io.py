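"""Run configuration, defaulting, and reproducibility plumbing.

A run config is a structured-text (YAML) document with optional
sections ``electrode``, ``scene``, ``timing``, ``frontend``,
``calibration`` and ``analysis``; anything omitted takes the package
defaults.  Every run serializes its fully resolved configuration and
master seed alongside its outputs, and output sidecars carry the
config hash, so the same config + seed reproduces byte-identical
artifacts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import yaml

from .electrode import ElectrodeModel, MICROWIRE_LIKE, SILICON_ARRAY_LIKE
from .frontend import FrontEndConfig
from .neb import MuxTiming
from .scene import SceneConfig, SpikeTemplate

_NAMED_ELECTRODES = {
    "microwire": MICROWIRE_LIKE,
    "silicon_array": SILICON_ARRAY_LIKE,
}


def build_electrode_model(section) -> ElectrodeModel:
    """Electrode section: either a named preset string or explicit fields."""
    if section is None:
        return MICROWIRE_LIKE
    if isinstance(section, str):
        try:
            return _NAMED_ELECTRODES[section]
        except KeyError:
            raise ValueError(
                f"unknown electrode preset {section!r}; "
                f"choose from {sorted(_NAMED_ELECTRODES)}"
            ) from None
    base = _NAMED_ELECTRODES.get(section.pop("preset", "microwire"), MICROWIRE_LIKE)
    return base.with_(**{k: float(v) for k, v in section.items()})


def build_timing(section) -> MuxTiming:
    section = dict(section or {})
    return MuxTiming(
        M=int(section.get("M", 20)),
        fch=float(section.get("fch", 30e3)),
        Tconv=float(section.get("Tconv", 0.0)),
        eps_dtol=float(section.get("eps_dtol", 1e-3)),
    )


def build_frontend(section) -> FrontEndConfig:
    section = dict(section or {})
    return FrontEndConfig(**{k: (None if v is None else v)
                             for k, v in section.items()})


def build_scene_config(section, electrode: ElectrodeModel) -> SceneConfig:
    section = dict(section or {})
    tmpl = section.pop("template", None)
    templates = (SpikeTemplate(**tmpl),) if tmpl else (SpikeTemplate(),)
    kwargs = {k: v for k, v in section.items()}
    if "offset_range" in kwargs:
        kwargs["offset_range"] = tuple(float(x) for x in kwargs["offset_range"])
    if "background_band" in kwargs:
        kwargs["background_band"] = tuple(float(x) for x in kwargs["background_band"])
    return SceneConfig(templates=templates, electrode_model=electrode, **kwargs)


@dataclass
class RunConfig:
    """Fully resolved configuration for a reproducible run."""

    electrode: ElectrodeModel = field(default_factory=lambda: MICROWIRE_LIKE)
    scene: SceneConfig = field(default_factory=SceneConfig)
    timing: MuxTiming = field(default_factory=lambda: MuxTiming(M=20, fch=30e3))
    frontend: FrontEndConfig = field(default_factory=FrontEndConfig)
    calibration: dict = field(default_factory=lambda: {"n_avg": 64, "period_s": 1.0})
    analysis: dict = field(default_factory=lambda: {
        "band_hz": [800.0, 4000.0],
        "threshold_rms_multiple": 4.0,
        "refractory_s": 1.0e-3,
        "window_s": [0.4e-3, 1.0e-3],
    })
    seed: int = 0
    raw: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc, seed=seed)

    @classmethod
    def from_dict(cls, doc: dict, seed: int | None = None) -> "RunConfig":
        electrode = build_electrode_model(doc.get("electrode"))
        rc = cls(
            electrode=electrode,
            scene=build_scene_config(doc.get("scene"), electrode),
            timing=build_timing(doc.get("timing")),
            frontend=build_frontend(doc.get("frontend")),
            seed=int(doc.get("seed", 0)) if seed is None else int(seed),
            raw=doc,
        )
        rc.calibration.update(doc.get("calibration") or {})
        rc.analysis.update(doc.get("analysis") or {})
        return rc

    def resolved_dict(self) -> dict:
        return {
            "seed": self.seed,
            "electrode": {
                "Rs": self.electrode.Rs, "Rp": self.electrode.Rp,
                "Y0": self.electrode.Y0, "alpha": self.electrode.alpha,
                "Cin": self.electrode.Cin,
                "temperature": self.electrode.temperature,
            },
            "timing": {
                "M": self.timing.M, "fch": self.timing.fch,
                "Tconv": self.timing.Tconv, "eps_dtol": self.timing.eps_dtol,
            },
            "scene": {
                "n_electrodes": self.scene.n_electrodes,
                "offset_range": list(self.scene.offset_range),
                "spike_rate": self.scene.spike_rate,
                "background_noise_rms": self.scene.background_noise_rms,
                "background_band": list(self.scene.background_band),
                "duration": self.scene.duration,
            },
            "frontend_hash": self.frontend.config_hash(),
            "calibration": self.calibration,
            "analysis": self.analysis,
        }

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.resolved_dict(), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def write_resolved(self, path) -> None:
        doc = self.resolved_dict()
        doc["config_hash"] = self.config_hash()
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)
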