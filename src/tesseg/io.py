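"""Volume, label-field, landmark and graph I/O.

Supported volume formats: NRRD (raw or gzip encoding), MHD/RAW pairs, and
multipage TIFF.  Arrays are stored ``(z, y, x)`` in memory with x fastest on
disk; NRRD/MHD headers therefore list sizes as ``nx ny nz``.  The pipeline
assumes isotropic voxels (as for resampled scans); anisotropic spacing in a
header is rejected.  Integer volumes round-trip bit-identically.

Landmark CSVs have columns ``x,y,z`` in 0-based voxel coordinates;
conversion to the internal ``(z, y, x)`` order happens here.
"""

from __future__ import annotations

import gzip
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VolumeImage",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
]

_NRRD_TYPES = {
    "uint8": np.uint8, "uchar": np.uint8,
    "uint16": np.uint16, "unsigned short": np.uint16,
    "int16": np.int16, "short": np.int16,
    "uint32": np.uint32, "unsigned int": np.uint32,
    "int32": np.int32, "int": np.int32,
    "float": np.float32, "double": np.float64,
}
_NRRD_NAMES = {
    np.dtype(np.uint8): "uint8", np.dtype(np.uint16): "uint16",
    np.dtype(np.int16): "int16", np.dtype(np.uint32): "uint32",
    np.dtype(np.int32): "int32", np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
}

_MHD_TYPES = {
    "MET_UCHAR": np.uint8, "MET_USHORT": np.uint16, "MET_SHORT": np.int16,
    "MET_UINT": np.uint32, "MET_INT": np.int32,
    "MET_FLOAT": np.float32, "MET_DOUBLE": np.float64,
}
_MHD_NAMES = {np.dtype(v): k for k, v in _MHD_TYPES.items()}


@dataclass
class VolumeImage:
    """A 3D scalar field on a regular grid with physical voxel size.

    ``data`` is indexed ``(z, y, x)``; ``voxel_size_um`` is the isotropic
    edge length of a voxel in micrometers.
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VolumeImage data must be 3D")
        if min(self.data.shape) < 1:
            raise ValueError("every dimension must be >= 1")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _check_isotropic(spacings) -> float:
    s = np.asarray(spacings, dtype=np.float64)
    if not np.allclose(s, s[0], rtol=1e-6):
        raise ValueError(
            f"anisotropic voxel spacing {tuple(s)} not supported; resample "
            "to isotropic voxels first"
        )
    return float(s[0])


# ---------------------------------------------------------------------------
# NRRD (minimal: the subset this package writes)
# ---------------------------------------------------------------------------


def _read_nrrd(path: Path) -> VolumeImage:
    with open(path, "rb") as f:
        magic = f.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = f.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, _, val = text.partition(":")
            fields[key.strip().lower()] = val.lstrip("=").strip()
        payload = f.read()
    try:
        sizes = [int(s) for s in fields["sizes"].split()]
        dtype = np.dtype(_NRRD_TYPES[fields["type"]])
        encoding = fields.get("encoding", "raw")
    except KeyError as exc:
        raise ValueError(f"{path}: corrupt or unsupported NRRD header") from exc
    if len(sizes) != 3:
        raise ValueError(f"{path}: expected a 3D NRRD, got sizes {sizes}")
    if fields.get("endian", "little") != "little":
        raise ValueError(f"{path}: big-endian NRRD not supported")
    if encoding in ("gzip", "gz"):
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    if "spacings" in fields:
        voxel = _check_isotropic([float(s) for s in fields["spacings"].split()])
    else:
        raise ValueError(f"{path}: NRRD header lacks spacings")
    nx, ny, nz = sizes  # fastest axis first in NRRD
    arr = np.frombuffer(payload, dtype=dtype, count=nx * ny * nz)
    return VolumeImage(arr.reshape(nz, ny, nx).copy(), voxel)


def _write_nrrd(vol: VolumeImage, path: Path, compress: bool = False) -> None:
    dtype = np.dtype(vol.data.dtype)
    if dtype not in _NRRD_NAMES:
        raise ValueError(f"unsupported dtype for NRRD: {dtype}")
    nz, ny, nx = vol.data.shape
    v = vol.voxel_size_um
    header = (
        "NRRD0004\n"
        "# written by tesseg\n"
        f"type: {_NRRD_NAMES[dtype]}\n"
        "dimension: 3\n"
        f"sizes: {nx} {ny} {nz}\n"
        f"spacings: {v:.10g} {v:.10g} {v:.10g}\n"
        "endian: little\n"
        f"encoding: {'gzip' if compress else 'raw'}\n"
        "\n"
    )
    raw = np.ascontiguousarray(vol.data).tobytes()
    if compress:
        raw = gzip.compress(raw, 6)
    with open(path, "wb") as f:
        f.write(header.encode("ascii"))
        f.write(raw)


# ---------------------------------------------------------------------------
# MHD/RAW
# ---------------------------------------------------------------------------


def _read_mhd(path: Path) -> VolumeImage:
    fields: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            k, _, v = line.partition("=")
            fields[k.strip()] = v.strip()
    try:
        ndims = int(fields["NDims"])
        sizes = [int(s) for s in fields["DimSize"].split()]
        dtype = np.dtype(_MHD_TYPES[fields["ElementType"]])
        datafile = fields["ElementDataFile"]
    except KeyError as exc:
        raise ValueError(f"{path}: corrupt or unsupported MHD header") from exc
    if ndims != 3 or len(sizes) != 3:
        raise ValueError(f"{path}: expected a 3D MHD")
    voxel = _check_isotropic(
        [float(s) for s in fields.get("ElementSpacing", "1 1 1").split()]
    )
    raw_path = path.parent / datafile
    arr = np.fromfile(raw_path, dtype=dtype, count=int(np.prod(sizes)))
    nx, ny, nz = sizes
    return VolumeImage(arr.reshape(nz, ny, nx).copy(), voxel)


def _write_mhd(vol: VolumeImage, path: Path) -> None:
    dtype = np.dtype(vol.data.dtype)
    if dtype not in _MHD_NAMES:
        raise ValueError(f"unsupported dtype for MHD: {dtype}")
    nz, ny, nx = vol.data.shape
    raw_name = path.with_suffix(".raw").name
    v = vol.voxel_size_um
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        f"DimSize = {nx} {ny} {nz}\n"
        f"ElementSpacing = {v:.10g} {v:.10g} {v:.10g}\n"
        f"ElementType = {_MHD_NAMES[dtype]}\n"
        f"ElementDataFile = {raw_name}\n"
    )
    path.write_text(header)
    np.ascontiguousarray(vol.data).tofile(path.parent / raw_name)


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------


def _read_tiff(path: Path, voxel_size_um: float | None) -> VolumeImage:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    if arr.ndim == 2:
        arr = arr[None]
    voxel = voxel_size_um
    if voxel is None and desc:
        try:
            meta = json.loads(desc)
            voxel = float(meta["voxel_size_um"])
        except (ValueError, KeyError, TypeError):
            voxel = None
    if voxel is None:
        raise ValueError(
            f"{path}: TIFF carries no voxel size metadata; pass voxel_size_um"
        )
    return VolumeImage(arr, voxel)


def _write_tiff(vol: VolumeImage, path: Path) -> None:
    tifffile.imwrite(
        path,
        vol.data,
        photometric="minisblack",
        description=json.dumps({"voxel_size_um": vol.voxel_size_um}),
    )


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def read_volume(path, voxel_size_um: float | None = None) -> VolumeImage:
    """Read a volume; format chosen by extension (.nrrd, .mhd, .tif/.tiff).

    ``voxel_size_um`` overrides / supplies the voxel size when the header
    lacks one (required for plain TIFF stacks).
    """
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".nrrd":
        vol = _read_nrrd(p)
    elif suffix == ".mhd":
        vol = _read_mhd(p)
    elif suffix in (".tif", ".tiff"):
        return _read_tiff(p, voxel_size_um)
    else:
        raise ValueError(f"unknown volume format: {suffix!r}")
    if voxel_size_um is not None:
        vol.voxel_size_um = float(voxel_size_um)
    return vol


def write_volume(vol: VolumeImage, path, compress: bool = False) -> None:
    """Write a volume; format chosen by extension (.nrrd, .mhd, .tif/.tiff)."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".nrrd":
        _write_nrrd(vol, p, compress=compress)
    elif suffix == ".mhd":
        _write_mhd(vol, p)
    elif suffix in (".tif", ".tiff"):
        _write_tiff(vol, p)
    else:
        raise ValueError(f"unknown volume format: {suffix!r}")


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------


def read_landmarks(path) -> np.ndarray:
    """Read a landmark CSV (columns x,y,z, 0-based voxel coordinates).

    Returns an (N, 3) float array in internal ``(z, y, x)`` order.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        return df[[cols["z"], cols["y"], cols["x"]]].to_numpy(dtype=np.float64)
    except KeyError as exc:
        raise ValueError(f"{path}: landmark CSV needs x,y,z columns") from exc


def write_landmarks(points: np.ndarray, path, names=None) -> None:
    """Write landmarks given in internal ``(z, y, x)`` order as x,y,z CSV."""
    pts = np.asarray(points, dtype=np.float64)
    df = pd.DataFrame(
        {"x": pts[:, 2], "y": pts[:, 1], "z": pts[:, 0]}
    )
    if names is not None:
        df["name"] = list(names)
    df.to_csv(path, index=False)


def array_checksum(arr: np.ndarray) -> str:
    """Stable checksum of an array's bytes (used for pipeline resume)."""
    a = np.ascontiguousarray(arr)
    return f"{zlib.crc32(a.tobytes()) & 0xFFFFFFFF:08x}-{a.shape}-{a.dtype}"
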