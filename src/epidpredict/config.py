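"""Run configuration, pipeline orchestration and run manifests.

A run is fully described by a :class:`RunConfig` (YAML-loadable) plus
the input file paths; every stage writes a manifest recording inputs,
the configuration hash, the package version and the seeds so a run can
be reproduced from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .grid import ImageGrid
from .gamma import GammaCriteria, GammaResult, compare_report, gamma_map


class ConfigError(ValueError):
    """A configuration field failed validation; the message names it."""


@dataclass
class RunConfig:
    """Pipeline settings; the defaults reproduce the standard protocol
    (SDD 150 cm, control-point up-sampling factor 5, global gamma
    3%/2 mm with a 10% low-dose threshold)."""

    binning: int = 2
    sdd: float = 150.0
    sad: float = 100.0
    upsample_factor: int = 5
    leaf_transmission: float = 0.0
    kernel_support_k1: float | None = None  # cm; None = auto (4 sigma)
    kernel_support_k2: float | None = None  # cm; None = auto (5 / min b)
    lookup_clamping: str = "clamp"  # the only supported policy
    gamma_dose_pct: float = 3.0
    gamma_dta_mm: float = 2.0
    gamma_threshold_pct: float = 10.0
    seed: int = 0
    output_dir: str = "runs"

    def validate(self) -> None:
        checks = [
            ("binning", self.binning >= 1),
            ("sdd", self.sdd > self.sad > 0),
            ("upsample_factor", self.upsample_factor >= 1),
            ("leaf_transmission", 0.0 <= self.leaf_transmission < 1.0),
            ("lookup_clamping", self.lookup_clamping == "clamp"),
            ("gamma_dose_pct", self.gamma_dose_pct > 0),
            ("gamma_dta_mm", self.gamma_dta_mm > 0),
            ("gamma_threshold_pct", self.gamma_threshold_pct > 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(f"invalid value for config field '{name}'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def grid(self) -> ImageGrid:
        return ImageGrid.binned(self.binning, sdd=self.sdd)

    def gamma_criteria(self) -> GammaCriteria:
        return GammaCriteria(
            dose_pct=self.gamma_dose_pct,
            dta_mm=self.gamma_dta_mm,
            low_threshold_pct=self.gamma_threshold_pct,
        )

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(out_dir: str | Path, command: str, config: RunConfig, inputs: dict) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "inputs": {k: str(v) for k, v in inputs.items()},
        "package_version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return path


# ---------------------------------------------------------------------------
# image I/O helpers for pipeline artifacts

def save_image(image, path: str | Path) -> None:
    """Portal image as .npy grid + JSON sidecar, or 16-bit TIFF."""
    from .forward import PortalImage

    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        v = image.values
        scale = 65535.0 / v.max() if v.max() > 0 else 1.0
        tifffile.imwrite(path, (v * scale).astype(np.uint16))
        meta = {"scale": scale}
    else:
        np.save(path.with_suffix(".npy"), image.values)
        meta = {}
    sidecar = {
        "kind": image.kind,
        "nx": image.grid.nx,
        "ny": image.grid.ny,
        "pitch": image.grid.pitch,
        "sdd": image.grid.sdd,
        "integrated_mu": image.integrated_mu,
        **meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))


def load_image(path: str | Path):
    from .forward import PortalImage

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    values = np.load(path.with_suffix(".npy"))
    grid = ImageGrid(
        nx=sidecar["nx"], ny=sidecar["ny"], pitch=sidecar["pitch"], sdd=sidecar["sdd"]
    )
    return PortalImage(
        values=values, grid=grid, kind=sidecar["kind"],
        integrated_mu=sidecar.get("integrated_mu", 0.0),
    )


def compare_images(reference, evaluated, config: RunConfig, out_dir: str | Path) -> GammaResult:
    """Gamma-compare two portal images and write the report artifacts."""
    result = gamma_map(reference, evaluated, config.gamma_criteria())
    compare_report(result, out_dir)
    return result
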