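"""Hyperspectral cubes, semantic masks, label legends, and their file formats.

A cube is an H x W x C nonnegative reflectance array with a strictly
increasing wavelength axis (nm) and subject/camera provenance. Two on-disk
containers are supported:

* ENVI: ``.hdr`` text header + ``.raw`` binary, fixed to band-sequential
  (BSQ) float32, wavelength units nm. A single canonical dialect avoids
  silent unit or interleave drift.
* HDF5: datasets ``/data`` and ``/wavelengths``, attributes ``subject_id``
  and ``camera_id``.

Masks are 8-bit PNGs with a JSON legend sidecar (same path + ``.json``), so
they stay viewable in ordinary image tools. Pixel coordinates are 0-based,
row-major, origin top-left; label id 0 is reserved for the background class
(blue cloth in the surgical datasets this models).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from PIL import Image

from .errors import FormatError, ValidationError

__all__ = [
    "HsiCube", "SemanticMask", "LabelLegend",
    "read_cube", "write_cube", "read_mask", "write_mask", "one_hot",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class LabelLegend:
    """Ordered mapping of label ids to class names."""

    entries: dict[int, str]
    background_id: int = 0

    def __post_init__(self):
        ids = list(self.entries)
        if len(ids) != len(set(ids)):
            raise ValidationError("legend ids must be unique")
        if any(int(i) < 0 for i in ids):
            raise ValidationError("legend ids must be nonnegative")
        if self.background_id not in self.entries:
            raise ValidationError(
                f"background id {self.background_id} missing from legend"
            )
        self.entries = {int(k): str(v) for k, v in self.entries.items()}

    @property
    def ids(self) -> list[int]:
        return list(self.entries)

    def __contains__(self, label: int) -> bool:
        return int(label) in self.entries


@dataclass
class HsiCube:
    """H x W x C reflectance image with wavelength axis and provenance."""

    data: np.ndarray
    wavelengths: np.ndarray
    subject_id: str = ""
    camera_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError(f"cube must be H x W x C, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("cube contains non-finite values")
        if np.any(self.data < 0):
            raise ValidationError("cube contains negative reflectance values")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValidationError(
                f"wavelength axis length {len(self.wavelengths)} != band count "
                f"{self.data.shape[2]}"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class SemanticMask:
    """H x W integer label image plus legend.

    ``fill_label`` marks augmentation voids; it must stay outside the legend
    (see :mod:`hsisynth.masks_augment`).
    """

    labels: np.ndarray
    legend: LabelLegend
    fill_label: int | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("mask labels must be integers")
        self.labels = self.labels.astype(np.int64)
        self.validate()

    def validate(self) -> None:
        if self.labels.ndim != 2:
            raise ValidationError(f"mask must be H x W, got shape {self.labels.shape}")
        if self.labels.min(initial=0) < 0:
            raise ValidationError("mask labels must be nonnegative")
        allowed = set(self.legend.ids)
        if self.fill_label is not None:
            if self.fill_label in self.legend:
                raise ValidationError("fill_label must not collide with a legend id")
            allowed.add(int(self.fill_label))
        present = set(np.unique(self.labels).tolist())
        unknown = present - allowed
        if unknown:
            raise ValidationError(f"mask contains ids absent from legend: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def check_paired(cube: HsiCube, mask: SemanticMask) -> None:
    """Cube and mask must share (H, W) exactly."""
    if cube.data.shape[:2] != mask.labels.shape:
        raise ValidationError(
            f"cube spatial shape {cube.data.shape[:2]} != mask shape {mask.labels.shape}"
        )


# --------------------------------------------------------------------------
# one-hot encoding
# --------------------------------------------------------------------------

def one_hot(mask: SemanticMask | np.ndarray, n_classes: int) -> np.ndarray:
    """Encode an H x W label image as an H x W x K binary stack."""
    labels = mask.labels if isinstance(mask, SemanticMask) else np.asarray(mask)
    if labels.max(initial=0) >= n_classes:
        raise ValidationError(
            f"label {labels.max()} out of range for n_classes={n_classes}"
        )
    return np.eye(n_classes, dtype=np.float32)[labels]


# --------------------------------------------------------------------------
# ENVI (.hdr + .raw, BSQ, float32)
# --------------------------------------------------------------------------

_ENVI_DTYPE = 4  # float32 in the ENVI data-type enumeration


def _envi_paths(path: Path) -> tuple[Path, Path]:
    path = Path(path)
    if path.suffix == ".hdr":
        return path, path.with_suffix(".raw")
    if path.suffix == ".raw":
        return path.with_suffix(".hdr"), path
    return path.with_suffix(".hdr"), path.with_suffix(".raw")


def _write_envi(cube: HsiCube, path: Path) -> None:
    hdr_path, raw_path = _envi_paths(path)
    h, w, c = cube.data.shape
    wl = ", ".join(f"{v:.6g}" for v in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {c}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_DTYPE}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"subject id = {cube.subject_id}\n"
        f"camera id = {cube.camera_id}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(hdr)
    # BSQ: band-sequential layout, (C, H, W) on disk
    raw_path.write_bytes(
        np.ascontiguousarray(cube.data.transpose(2, 0, 1), dtype="<f4").tobytes()
    )


def _parse_envi_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    body = text
    if body.lstrip().lower().startswith("envi"):
        body = body.lstrip()[4:]
    # brace-delimited values may span lines; normalise them first
    pos = 0
    out = []
    while pos < len(body):
        brace = body.find("{", pos)
        if brace == -1:
            out.append(body[pos:])
            break
        end = body.find("}", brace)
        if end == -1:
            raise FormatError("unterminated '{' in ENVI header")
        out.append(body[pos:brace])
        out.append("{" + body[brace + 1 : end].replace("\n", " ") + "}")
        pos = end + 1
    for line in "".join(out).splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _read_envi(path: Path) -> HsiCube:
    hdr_path, raw_path = _envi_paths(path)
    if not hdr_path.exists():
        raise FormatError(f"missing ENVI header: {hdr_path}")
    if not raw_path.exists():
        raise FormatError(f"missing ENVI binary: {raw_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        c = int(fields["bands"])
    except KeyError as e:  # pragma: no cover - defensive
        raise FormatError(f"ENVI header missing field {e}") from e
    if int(fields.get("data type", _ENVI_DTYPE)) != _ENVI_DTYPE:
        raise FormatError("only float32 ENVI data (data type = 4) is supported")
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise FormatError("only BSQ interleave is supported")
    wl_text = fields.get("wavelength", "")
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise FormatError("ENVI header lacks a wavelength block")
    wavelengths = np.array(
        [float(v) for v in wl_text[1:-1].split(",") if v.strip()], dtype=np.float64
    )
    if len(wavelengths) != c:
        raise FormatError(
            f"ENVI header lists {len(wavelengths)} wavelengths for {c} bands"
        )
    raw = np.frombuffer(raw_path.read_bytes(), dtype="<f4")
    if raw.size != h * w * c:
        raise FormatError(
            f"ENVI binary holds {raw.size} values, header promises {h * w * c}"
        )
    data = raw.reshape(c, h, w).transpose(1, 2, 0)
    return HsiCube(
        data=data,
        wavelengths=wavelengths,
        subject_id=fields.get("subject id", ""),
        camera_id=fields.get("camera id", ""),
    )


# --------------------------------------------------------------------------
# HDF5
# --------------------------------------------------------------------------

def _write_hdf5(cube: HsiCube, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=cube.data.astype(np.float32))
        f.create_dataset("wavelengths", data=cube.wavelengths)
        f.attrs["subject_id"] = cube.subject_id
        f.attrs["camera_id"] = cube.camera_id


def _read_hdf5(path: Path) -> HsiCube:
    with h5py.File(path, "r") as f:
        if "data" not in f or "wavelengths" not in f:
            raise FormatError(f"{path} lacks /data or /wavelengths")
        return HsiCube(
            data=f["data"][()],
            wavelengths=f["wavelengths"][()],
            subject_id=str(f.attrs.get("subject_id", "")),
            camera_id=str(f.attrs.get("camera_id", "")),
        )


# --------------------------------------------------------------------------
# public I/O surface
# --------------------------------------------------------------------------

_HDF5_SUFFIXES = {".h5", ".hdf5", ".he5"}


def write_cube(cube: HsiCube, path, format: str | None = None) -> None:
    """Write a cube as ENVI (default) or HDF5, inferred from the suffix."""
    cube.validate()
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in _HDF5_SUFFIXES else "envi"
    if format == "envi":
        _write_envi(cube, path)
    elif format == "hdf5":
        _write_hdf5(cube, path)
    else:
        raise ValueError(f"unknown cube format: {format!r}")


def read_cube(path) -> HsiCube:
    """Read a cube written by :func:`write_cube` (ENVI or HDF5)."""
    path = Path(path)
    if path.suffix in _HDF5_SUFFIXES or (path.exists() and h5py.is_hdf5(path)):
        return _read_hdf5(path)
    return _read_envi(path)


def _legend_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_mask(mask: SemanticMask, path) -> None:
    """Write a mask as an 8-bit PNG plus JSON legend sidecar."""
    mask.validate()
    path = Path(path)
    if mask.labels.max(initial=0) > 255:
        raise ValidationError("mask ids exceed the 8-bit PNG range")
    Image.fromarray(mask.labels.astype(np.uint8), mode="L").save(path, format="PNG")
    sidecar = {
        "entries": {str(k): v for k, v in mask.legend.entries.items()},
        "background_id": mask.legend.background_id,
        "fill_label": mask.fill_label,
    }
    _legend_path(path).write_text(json.dumps(sidecar, indent=1))


def read_mask(path) -> SemanticMask:
    """Read a mask PNG + legend sidecar; unknown labels raise ValidationError."""
    path = Path(path)
    sidecar_path = _legend_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing legend sidecar: {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
        legend = LabelLegend(
            entries={int(k): v for k, v in sidecar["entries"].items()},
            background_id=int(sidecar["background_id"]),
        )
    except (KeyError, ValueError, json.JSONDecodeError) as e:
        raise FormatError(f"malformed legend sidecar {sidecar_path}: {e}") from e
    labels = np.asarray(Image.open(path), dtype=np.int64)
    fill = sidecar.get("fill_label")
    return SemanticMask(labels=labels, legend=legend,
                        fill_label=None if fill is None else int(fill))
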