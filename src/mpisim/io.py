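"""File formats and run manifests.

Sinograms travel in an HDF5 container (``/harmonics/h2`` ... ``/harmonics/h9``
complex64 planes, ``/axes/shift_mT``, ``/axes/angle_deg``, and a ``/meta``
group holding the config YAML snapshot, seed, and flag bitmasks).
Reconstructed images and phantoms are 32-bit float TIFFs with a JSON sidecar
carrying FOV/pitch/method metadata; dilution series get a CSV manifest.
Every CLI run emits a JSON RunManifest from which deterministic stages can
be reproduced bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .acquisition import Sinogram
from .phantoms import DilutionSeries, PhantomImage
from .recon import ReconImage
from .scanner_model import ScannerConfig

__all__ = [
    "save_sinogram", "load_sinogram",
    "save_image", "load_image",
    "save_phantom", "save_phantom_h5",
    "save_dilution_manifest",
    "RunManifest",
    "array_hash",
]


def array_hash(arr: np.ndarray) -> str:
    """Stable content hash of an array (dtype + shape + bytes)."""
    h = hashlib.sha256()
    h.update(str(arr.dtype).encode())
    h.update(str(arr.shape).encode())
    h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


# -- sinograms -------------------------------------------------------------

def save_sinogram(sinogram: Sinogram, path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("harmonics")
        for i, h in enumerate(sinogram.harmonic_numbers):
            grp.create_dataset(f"h{h}", data=sinogram.data[i].astype(np.complex64))
        axes = f.create_group("axes")
        axes.create_dataset("shift_mT", data=sinogram.shift_axis)
        axes.create_dataset("angle_deg", data=sinogram.angle_axis)
        meta = f.create_group("meta")
        meta.attrs["config_yaml"] = sinogram.provenance.get("config", "")
        meta.attrs["seed"] = int(sinogram.provenance.get("seed", -1))
        meta.create_dataset("interpolated",
                            data=sinogram.interpolated.astype(np.uint8))
        if "outlier_mask" in sinogram.provenance:
            meta.create_dataset(
                "outlier_mask",
                data=sinogram.provenance["outlier_mask"].astype(np.uint8))


def load_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as f:
        numbers = sorted(int(k[1:]) for k in f["harmonics"])
        data = np.stack([f["harmonics"][f"h{h}"][()] for h in numbers]
                        ).astype(complex)
        shift = f["axes/shift_mT"][()]
        angle = f["axes/angle_deg"][()]
        interp = f["meta/interpolated"][()].astype(bool)
        prov = {"config": f["meta"].attrs.get("config_yaml", ""),
                "seed": int(f["meta"].attrs.get("seed", -1))}
        if "outlier_mask" in f["meta"]:
            prov["outlier_mask"] = f["meta/outlier_mask"][()].astype(bool)
    return Sinogram(data=data, shift_axis=shift, angle_axis=angle,
                    interpolated=interp, provenance=prov,
                    harmonic_numbers=np.array(numbers))


# -- images ----------------------------------------------------------------

def save_image(image: ReconImage, path) -> None:
    """32-bit float TIFF plus a JSON sidecar with geometry and provenance."""
    path = Path(path)
    tifffile.imwrite(path, image.values.astype(np.float32))
    sidecar = {
        "fov_mm": image.fov,
        "pixel_pitch_mm": image.pixel_pitch,
        "method": image.method,
        "provenance": _jsonable(image.provenance),
        "values_hash": array_hash(image.values),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def load_image(path) -> ReconImage:
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ReconImage(values=values, fov=meta["fov_mm"],
                      pixel_pitch=meta["pixel_pitch_mm"],
                      method=meta["method"],
                      provenance=meta.get("provenance", {}))


def save_phantom(phantom: PhantomImage, path) -> None:
    """Phantom as float TIFF + JSON sidecar (pitch, origin, depth)."""
    path = Path(path)
    tifffile.imwrite(path, phantom.concentration_grid.astype(np.float32))
    sidecar = {"pixel_pitch_mm": phantom.pixel_pitch,
               "origin": list(phantom.origin),
               "depth_mm": phantom.depth,
               "analytic_mass_ug": phantom.analytic_mass_ug}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def save_phantom_h5(phantom: PhantomImage, path) -> None:
    """Phantom as an HDF5 dataset with pitch/origin/depth attributes."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset(
            "concentration_mg_per_mL",
            data=phantom.concentration_grid.astype(np.float32))
        ds.attrs["pixel_pitch_mm"] = phantom.pixel_pitch
        ds.attrs["origin"] = phantom.origin
        ds.attrs["depth_mm"] = phantom.depth


def save_dilution_manifest(series: DilutionSeries, path) -> pd.DataFrame:
    """CSV manifest of a dilution series: sample id, concentration, mass."""
    df = pd.DataFrame({
        "sample_id": np.arange(len(series.phantoms)),
        "concentration_mg_per_mL": series.concentrations,
        "mass_ug": series.masses_ug,
    })
    df.to_csv(path, index=False)
    return df


# -- manifests -------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return {"__array_hash__": array_hash(obj)}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to reproduce it.

    ``outputs`` maps output names to content hashes; rerunning a manifest
    and comparing hashes verifies bit-exact reproduction of deterministic
    stages.
    """

    command: str
    config_yaml: str
    seed: int
    phantom_spec: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(_jsonable(dataclasses.asdict(self)), indent=2))

    @classmethod
    def load(cls, path) -> "RunManifest":
        doc = json.loads(Path(path).read_text())
        return cls(**doc)

    @property
    def config(self) -> ScannerConfig:
        return ScannerConfig.from_yaml(self.config_yaml)
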