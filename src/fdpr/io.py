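"""File formats and run configuration.

Intensity stacks are stored as multi-page TIFF (float32 or 16-bit) or a
directory of PNG frames, always with a JSON metadata sidecar carrying the
acquisition parameters (wavelength, pixel pitch, illumination descriptors).
Run configurations are JSON (YAML accepted) with all physical units in um
and radians.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import (
    ComplexField,
    ConstraintSpec,
    FeatureExtractorSpec,
    LossSpec,
    ObservationSet,
    SolverConfig,
)
from . import constraints as C

logger = logging.getLogger("fdpr")

__all__ = ["RunConfig", "read_stack", "write_stack", "build_constraints",
           "ConfigError", "DataError"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Unreadable or inconsistent input data (CLI exit code 3)."""


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def write_stack(obs: ObservationSet, path: str | Path) -> Path:
    """Write frames as a float32 multi-page TIFF plus a JSON sidecar.

    ``write_stack`` then :func:`read_stack` round-trips frames bitwise for
    float32 data.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, obs.frames.astype(np.float32))
    sidecar = {
        "illum": [list(np.atleast_1d(i).astype(float)) for i in obs.illum],
        "meta": {k: (float(v) if isinstance(v, (int, float, np.floating))
                     else v) for k, v in obs.meta.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))
    return path


def read_stack(path: str | Path) -> ObservationSet:
    """Read a TIFF stack or a directory of PNG frames into an ObservationSet.

    16-bit integer data are scaled to [0, 1] (the scale is recorded in the
    returned metadata).  A missing sidecar yields defaults plus a warning.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input stack {path} does not exist")
    if path.is_dir():
        import imageio.v3 as iio
        files = sorted(path.glob("*.png"))
        if not files:
            raise DataError(f"no PNG frames found in {path}")
        frames = []
        for i, f in enumerate(files):
            try:
                frames.append(np.asarray(iio.imread(f), dtype=float))
            except Exception as exc:  # pragma: no cover
                raise DataError(f"unreadable frame {i} ({f.name}): {exc}")
        frames = np.stack(frames)
        sidecar_path = path / "stack.json"
    else:
        try:
            frames = np.asarray(tifffile.imread(path))
        except Exception as exc:
            raise DataError(f"unreadable TIFF {path}: {exc}")
        if frames.ndim == 2:
            frames = frames[None]
        sidecar_path = path.with_suffix(path.suffix + ".json")

    meta = {"wavelength_um": 0.532, "pixel_pitch_um": 1.0}
    illum = None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        meta.update(sidecar.get("meta", {}))
        illum = sidecar.get("illum")
    else:
        warnings.warn(f"missing sidecar {sidecar_path.name}; "
                      "default metadata applied")
        logger.warning("missing sidecar for %s; defaults applied", path)

    if np.issubdtype(frames.dtype, np.integer):
        scale = float(np.iinfo(frames.dtype).max)
        frames = frames.astype(float) / scale
        meta["intensity_scale"] = scale
    frames = frames.astype(float)
    if illum is None:
        illum = [(0.0, 0.0)] * frames.shape[0]
    return ObservationSet(frames, [tuple(i) if np.ndim(i) else float(i)
                                   for i in illum], meta)


# ---------------------------------------------------------------------------
# constraints registry
# ---------------------------------------------------------------------------

def build_constraints(specs: list[dict]) -> list[ConstraintSpec]:
    """Instantiate constraints from config dicts: name + parameter map."""
    out = []
    for d in specs:
        name = d.get("name")
        params = d.get("params", {})
        weight = float(d.get("weight", 0.1))
        target = d.get("target", "object")
        component = d.get("component", "phase")
        if name == "amplitude_threshold":
            lo, hi = params.get("lo", 0.0), params.get("hi", 1.0)
            fn = lambda x, lo=lo, hi=hi: C.amplitude_threshold(x, lo, hi)
        elif name == "tv":
            w = params.get("weight", 0.05)
            it = int(params.get("iterations", 20))
            fn = C.complex_constraint(
                lambda f, w=w, it=it: C.tv_denoise(f, w, it), component)
        elif name == "guided_filter":
            gp = C.GuidedFilterParams(
                radius_px=int(params.get("radius_px", 8)),
                eps=float(params.get("eps", 0.04)))
            fn = C.complex_constraint(
                lambda f, gp=gp: C.guided_filter(f, gp), component)
        else:
            raise ConfigError(f"unknown constraint {name!r}")
        out.append(ConstraintSpec(constraint=fn, weight=weight,
                                  target=target, name=name))
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a reconstruction run."""

    modality: str
    input_stack: str
    output_dir: str
    system: dict = dc_field(default_factory=dict)
    extractor: dict = dc_field(default_factory=dict)
    loss: dict = dc_field(default_factory=dict)
    constraints: list = dc_field(default_factory=list)
    solver: dict = dc_field(default_factory=dict)
    baseline: str | None = None

    def __post_init__(self):
        if self.modality not in ("fpm", "coded", "holography"):
            raise ConfigError(f"invalid modality {self.modality!r}")
        required = {"fpm": ("objective_na", "downsample_factor"),
                    "coded": ("sample_to_mask_um", "mask_to_sensor_um"),
                    "holography": ("distance_um",)}[self.modality]
        missing = [k for k in required if k not in self.system]
        if missing:
            raise ConfigError(f"modality {self.modality!r} requires system "
                              f"parameters {missing}")

    def to_dict(self) -> dict:
        return {"modality": self.modality, "input_stack": self.input_stack,
                "output_dir": self.output_dir, "system": self.system,
                "extractor": self.extractor, "loss": self.loss,
                "constraints": self.constraints, "solver": self.solver,
                "baseline": self.baseline}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: d[k] for k in ("modality", "input_stack", "output_dir",
                                   "system", "extractor", "loss",
                                   "constraints", "solver", "baseline")
                 if k in d}
        try:
            return cls(**known)
        except TypeError as exc:
            raise ConfigError(str(exc))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file {path} does not exist")
        text = path.read_text()
        data = (yaml.safe_load(text) if path.suffix in (".yml", ".yaml")
                else json.loads(text))
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def feature_spec(self) -> FeatureExtractorSpec:
        try:
            return FeatureExtractorSpec(**self.extractor)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad extractor spec: {exc}")

    def loss_spec(self) -> LossSpec:
        try:
            return LossSpec(**self.loss)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad loss spec: {exc}")

    def solver_config(self) -> SolverConfig:
        try:
            return SolverConfig(**self.solver)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad solver config: {exc}")


def save_field(field_: ComplexField, directory: Path, stem: str) -> None:
    """Save amplitude and phase of a complex field as float32 TIFFs."""
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{stem}_amplitude.tif",
                     np.abs(field_.values).astype(np.float32))
    tifffile.imwrite(directory / f"{stem}_phase.tif",
                     np.angle(field_.values).astype(np.float32))
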