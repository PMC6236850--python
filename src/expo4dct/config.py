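"""Experiment configuration: validated YAML in, reproducible runs out.

A config file has sections ``scanner``, ``grid``, ``phantom``, ``waveform``,
``weighting``, ``reconstruction`` and ``metrics``; every field maps onto a
constructor argument of the corresponding domain type, so validation is
delegated to the types' own invariants.  A run's config echo plus its seed
reproduces the run bit-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .geometry import ScannerGeometry
from .phantom import GridSpec, PhantomObject
from .reconstruction import MU_WATER
from .weighting import DEFAULT_STEEPNESS

__all__ = ["ExperimentConfig", "load_config", "default_config_dict"]

_SCHEME_ALIASES = {"cosine2": "cosine_squared", "cos2": "cosine_squared"}


@dataclass
class ExperimentConfig:
    scanner: ScannerGeometry = field(default_factory=ScannerGeometry)
    grid: GridSpec = field(default_factory=GridSpec)
    objects: list[PhantomObject] = field(default_factory=list)
    waveform_kind: str = "sinusoidal"
    breathing_rate_bpm: float = 12.0
    amplitude: float = 30.0
    sample_rate: float = 200.0
    irregularity: float = 0.0
    duration: float | None = None  # None: derived from the gating budget
    scheme: str = "expo"
    ef: float = DEFAULT_STEEPNESS
    n_phases: int = 10
    noise_sigma: float = 0.0
    mu_water: float = MU_WATER
    rois: list[dict] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "scanner": asdict(self.scanner),
            "grid": asdict(self.grid),
            "phantom": {"objects": [asdict(o) for o in self.objects]},
            "waveform": {
                "kind": self.waveform_kind,
                "breathing_rate_bpm": self.breathing_rate_bpm,
                "amplitude": self.amplitude,
                "sample_rate": self.sample_rate,
                "irregularity": self.irregularity,
                "duration": self.duration,
            },
            "weighting": {"scheme": self.scheme, "ef": self.ef},
            "reconstruction": {
                "n_phases": self.n_phases,
                "noise_sigma": self.noise_sigma,
                "mu_water": self.mu_water,
            },
            "metrics": {"rois": self.rois},
            "seed": self.seed,
        }

    def echo(self, path: str | Path) -> None:
        """Write the config echo that reproduces this run."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _require(mapping: dict, section: str, known: set[str]) -> None:
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"config section {section!r}: unknown field(s) {sorted(unknown)}")


def from_dict(cfg: dict) -> ExperimentConfig:
    scanner = ScannerGeometry(**cfg.get("scanner", {}))
    grid = GridSpec(**cfg.get("grid", {}))
    phantom = cfg.get("phantom", {})
    objects = [
        PhantomObject(
            shape=o["shape"],
            center=tuple(o["center"]),
            size=tuple(o["size"]) if isinstance(o["size"], (list, tuple)) else o["size"],
            attenuation=o["attenuation"],
            motion_axis=o.get("motion_axis", "none"),
            excursion=o.get("excursion", 0.0),
            label=o.get("label", ""),
        )
        for o in phantom.get("objects", [])
    ]
    wf = dict(cfg.get("waveform", {}))
    _require(wf, "waveform", {"kind", "breathing_rate_bpm", "amplitude", "sample_rate", "irregularity", "duration"})
    wt = dict(cfg.get("weighting", {}))
    _require(wt, "weighting", {"scheme", "ef"})
    scheme = wt.get("scheme", "expo")
    scheme = _SCHEME_ALIASES.get(scheme, scheme)
    rec = dict(cfg.get("reconstruction", {}))
    _require(rec, "reconstruction", {"n_phases", "noise_sigma", "mu_water"})
    met = dict(cfg.get("metrics", {}))
    _require(met, "metrics", {"rois"})
    return ExperimentConfig(
        scanner=scanner,
        grid=grid,
        objects=objects,
        waveform_kind=wf.get("kind", "sinusoidal"),
        breathing_rate_bpm=wf.get("breathing_rate_bpm", 12.0),
        amplitude=wf.get("amplitude", 30.0),
        sample_rate=wf.get("sample_rate", 200.0),
        irregularity=wf.get("irregularity", 0.0),
        duration=wf.get("duration"),
        scheme=scheme,
        ef=wt.get("ef", DEFAULT_STEEPNESS),
        n_phases=rec.get("n_phases", 10),
        noise_sigma=rec.get("noise_sigma", 0.0),
        mu_water=rec.get("mu_water", MU_WATER),
        rois=met.get("rois", []),
        seed=cfg.get("seed", 0),
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML experiment config."""
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    return from_dict(cfg)


def default_config_dict() -> dict:
    """A complete example config (the S-I sinusoid suite phantom)."""
    from .phantom import standard_phantom_suite

    spec = standard_phantom_suite("si_sinusoid_grid")
    cfg = ExperimentConfig(objects=list(spec.objects))
    return cfg.to_dict()
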