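"""File I/O and run configuration.

Image data travel as NIfTI (the neuroimaging standard): one 4-D file per
encoding direction for the complex series — stored as paired real/imaginary
(or magnitude/wrapped-phase) volumes, since NIfTI complex support is patchy
across tools — uint8 NIfTI for masks, and a 4-D file with components on the
third axis for displacement fields.  A JSON sidecar records the acquisition
timing and layout; PPG beat times and plane-fit audits are plain CSV.

Array axis convention: in-memory arrays are (row y, column x) with frame and
encoding axes in front; NIfTI files store (x, y, z=1, t).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .encoding import EncodingScheme
from .dispstats import DisplacementField
from .metrics import PPGTrace
from .phantom import PhantomConfig
from .pipeline import ComplexSeries

__all__ = [
    "RunConfig",
    "write_series",
    "read_series",
    "write_mask",
    "read_mask",
    "write_displacement",
    "read_displacement",
    "write_ppg",
    "read_ppg",
    "write_plane_audit",
]

SIDECAR_NAME = "series.json"
LAYOUTS = ("real_imag", "mag_phase")


def _affine(voxel_mm: float) -> np.ndarray:
    return np.diag([voxel_mm, voxel_mm, 1.0, 1.0])


def _to_nifti_array(frames_yx: np.ndarray) -> np.ndarray:
    """(n_frames, ny, nx) -> NIfTI (x, y, 1, t)."""
    return np.transpose(frames_yx, (2, 1, 0))[:, :, None, :]


def _from_nifti_array(vol: np.ndarray) -> np.ndarray:
    """NIfTI (x, y, 1, t) -> (n_frames, ny, nx)."""
    return np.transpose(vol[:, :, 0, :], (2, 1, 0))


def write_series(
    directory, series: ComplexSeries, layout: str = "real_imag"
) -> Path:
    """Write one 4-D NIfTI pair per encoding direction plus a JSON sidecar."""
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(series.voxel_mm)
    for e in range(series.n_encodings):
        frames = series.data[e]
        if layout == "real_imag":
            parts = {"real": frames.real, "imag": frames.imag}
        else:
            parts = {"mag": np.abs(frames), "phase": np.angle(frames)}
        for name, arr in parts.items():
            img = nib.Nifti1Image(
                _to_nifti_array(arr).astype(np.float64), aff
            )
            nib.save(img, directory / f"enc{e:02d}_{name}.nii.gz")
    sidecar = {
        "n_encodings": series.n_encodings,
        "n_frames": series.n_frames,
        "layout": layout,
        "voxel_mm": series.voxel_mm,
        "rr_ms": series.rr_ms,
        "coverage_fraction": series.coverage_fraction,
        "frame_times_ms": [float(t) for t in series.frame_times_ms],
    }
    (directory / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    return directory


def read_series(directory, n_encodings: int | None = None) -> ComplexSeries:
    """Assemble a :class:`ComplexSeries` from a directory written by
    :func:`write_series`.  Validates the encoding count against the sidecar
    (and against ``n_encodings`` if given) and the array shapes."""
    directory = Path(directory)
    sidecar_path = directory / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar timing file {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    layout = sidecar["layout"]
    n_enc = sidecar["n_encodings"]
    if n_encodings is not None and n_enc != n_encodings:
        raise ValueError(
            f"sidecar has {n_enc} encodings, expected {n_encodings}"
        )
    suffixes = ("real", "imag") if layout == "real_imag" else ("mag", "phase")
    data = []
    for e in range(n_enc):
        parts = []
        for name in suffixes:
            path = directory / f"enc{e:02d}_{name}.nii.gz"
            if not path.exists():
                raise FileNotFoundError(
                    f"encoding file missing: {path} "
                    f"({n_enc} encodings expected)"
                )
            parts.append(_from_nifti_array(np.asarray(nib.load(path).dataobj)))
        if layout == "real_imag":
            data.append(parts[0] + 1j * parts[1])
        else:
            data.append(parts[0] * np.exp(1j * parts[1]))
    arr = np.stack(data, axis=0)
    if arr.shape[1] != sidecar["n_frames"]:
        raise ValueError("frame count does not match sidecar")
    return ComplexSeries(
        data=arr,
        voxel_mm=sidecar["voxel_mm"],
        rr_ms=sidecar["rr_ms"],
        coverage_fraction=sidecar["coverage_fraction"],
    )


def write_mask(path, mask: np.ndarray, voxel_mm: float = 4.0) -> Path:
    path = Path(path)
    arr = np.asarray(mask, dtype=np.uint8).T[:, :, None]
    nib.save(nib.Nifti1Image(arr, np.diag([voxel_mm, voxel_mm, 1.0, 1.0])), path)
    return path


def read_mask(path) -> np.ndarray:
    vol = np.asarray(nib.load(path).dataobj)
    return vol[:, :, 0].T.astype(bool)


def write_displacement(path, field: DisplacementField) -> Path:
    """Displacement NIfTI (x, y, component, frame) + JSON sidecar."""
    path = Path(path)
    # (n_frames, 3, ny, nx) -> (x, y, comp, frame)
    arr = np.transpose(field.data, (3, 2, 1, 0))
    nib.save(nib.Nifti1Image(arr, _affine(field.voxel_mm)), path)
    sidecar = {
        "axes": "x,y,component,frame",
        "components": list(field.axis_labels),
        "frame_times_ms": [float(t) for t in field.frame_times_ms],
        "voxel_mm": field.voxel_mm,
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2)
    )
    return path


def read_displacement(path, masks=None) -> DisplacementField:
    path = Path(path)
    sidecar = json.loads(
        path.with_suffix("").with_suffix(".json").read_text()
    )
    arr = np.asarray(nib.load(path).dataobj)
    data = np.transpose(arr, (3, 2, 1, 0))
    return DisplacementField(
        data=data,
        frame_times_ms=np.asarray(sidecar["frame_times_ms"]),
        masks=masks,
        voxel_mm=sidecar["voxel_mm"],
        axis_labels=tuple(sidecar["components"]),
    )


def write_ppg(path, trace: PPGTrace) -> Path:
    path = Path(path)
    pd.DataFrame({"beat_time_ms": trace.beat_times_ms}).to_csv(
        path, index=False
    )
    return path


def read_ppg(path) -> PPGTrace:
    df = pd.read_csv(path)
    return PPGTrace(beat_times_ms=df["beat_time_ms"].to_numpy(dtype=float))


def write_plane_audit(path, fits: list[dict]) -> Path:
    """Per-image plane-fit audit: frame, encoding, coefficients, objective."""
    path = Path(path)
    pd.DataFrame(fits).to_csv(path, index=False)
    return path


_PHANTOM_FIELDS = {f.name for f in dataclasses.fields(PhantomConfig)}


def _phantom_from_dict(d: dict) -> PhantomConfig:
    unknown = set(d) - _PHANTOM_FIELDS
    if unknown:
        raise ValueError(f"unknown phantom config keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("grid_size", "peak_displacement_mm"):
        if key in d:
            d[key] = tuple(d[key])
    return PhantomConfig(**d)


@dataclasses.dataclass
class RunConfig:
    """Serializable run configuration: paths, scheme, phantom, mode, seed.

    Round-trips losslessly through YAML; unknown keys are rejected so typos
    fail loudly instead of being silently ignored.
    """

    seed: int = 0
    pipeline: str = "standard"
    scheme: EncodingScheme = dataclasses.field(default_factory=EncodingScheme)
    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    paths: dict = dataclasses.field(default_factory=dict)
    metric_flags: dict = dataclasses.field(default_factory=dict)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        phantom = dataclasses.asdict(self.phantom)
        phantom["grid_size"] = list(self.phantom.grid_size)
        phantom["peak_displacement_mm"] = list(self.phantom.peak_displacement_mm)
        if phantom.get("background_phase") is not None:
            phantom["background_phase"] = np.asarray(
                phantom["background_phase"]
            ).tolist()
        return {
            "seed": self.seed,
            "pipeline": self.pipeline,
            "scheme": self.scheme.to_dict(),
            "phantom": phantom,
            "paths": dict(self.paths),
            "metric_flags": dict(self.metric_flags),
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "scheme" in d:
            d["scheme"] = EncodingScheme.from_dict(d["scheme"])
        if "phantom" in d:
            ph = dict(d["phantom"])
            if ph.get("background_phase") is not None:
                ph["background_phase"] = np.asarray(ph["background_phase"])
            d["phantom"] = _phantom_from_dict(ph)
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
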