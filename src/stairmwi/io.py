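"""NIfTI volume and YAML configuration I/O.

Volumes are written as NIfTI-1 with the affine as the single source of
geometric truth (canonical RAS, voxel sizes on the diagonal for phantom
output).  Configuration files round-trip the sequence protocols, the
quantification constants and the phantom spec; unknown keys are rejected
so silent typos cannot change a run.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from stairmwi.errors import ConfigError, StairError
from stairmwi.params import QuantConstants, SequenceParams
from stairmwi.phantom import ImageVolume, PhantomSpec

__all__ = [
    "read_volume",
    "write_volume",
    "load_config",
    "dump_config",
]


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write an ImageVolume as NIfTI-1 (.nii or .nii.gz)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    img.header.set_zooms(vol.voxel_mm)
    if vol.meta.get("sequence"):
        img.header["descrip"] = str(vol.meta["sequence"])[:79].encode()
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI-1 volume into an ImageVolume."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise StairError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise StairError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(
        data=data,
        voxel_mm=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine, dtype=float),
        meta={"source": str(path),
              "sequence": img.header["descrip"].tobytes().decode(
                  errors="ignore").rstrip("\x00")},
    )


def _from_mapping(cls, mapping: dict, context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {context}; "
            f"expected a subset of {sorted(fields)}"
        )
    kwargs = dict(mapping)
    for key in ("shape", "voxel_mm", "lesion_radius_vox"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path: str | Path) -> dict:
    """Load a run configuration from YAML.

    Recognised top-level sections: ``stair`` and ``pd`` (sequence
    protocols), ``constants`` (quantification constants), ``phantom``
    (phantom spec), ``seed``, ``out_dir``.  Returns a dict with the
    corresponding dataclass instances.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {"stair", "pd", "constants", "phantom", "afp_pulse",
             "seed", "out_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown section(s) {sorted(unknown)}")
    out: dict = {}
    if "stair" in raw:
        out["stair"] = _from_mapping(SequenceParams, raw["stair"], "stair")
    if "pd" in raw:
        out["pd"] = _from_mapping(SequenceParams, raw["pd"], "pd")
    if "constants" in raw:
        out["constants"] = _from_mapping(
            QuantConstants, raw["constants"], "constants")
    if "phantom" in raw:
        out["phantom"] = _from_mapping(PhantomSpec, raw["phantom"], "phantom")
    if "afp_pulse" in raw:
        out["afp_pulse"] = dict(raw["afp_pulse"])
    if "seed" in raw:
        out["seed"] = int(raw["seed"])
    if "out_dir" in raw:
        out["out_dir"] = str(raw["out_dir"])
    return out


def default_config() -> dict:
    """The package's shipped defaults (protocols, constants, phantom)."""
    return load_config(Path(__file__).parent / "data" / "defaults.yaml")


def dump_config(config: dict, path: str | Path) -> Path:
    """Serialize a run configuration (dataclasses allowed) to YAML."""
    path = Path(path)
    plain: dict = {}
    for key, val in config.items():
        if dataclasses.is_dataclass(val) and not isinstance(val, type):
            d = dataclasses.asdict(val)
            plain[key] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in d.items()
            }
        else:
            plain[key] = val
    path.write_text(yaml.safe_dump(plain, sort_keys=False))
    return path
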