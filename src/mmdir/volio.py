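"""Volume I/O: MetaImage (.mha/.mhd) and NIfTI (.nii/.nii.gz).

MetaImage support is a small self-contained reader/writer (uncompressed,
identity direction, scalar element types) so the package has no dependency
on a full ITK stack. NIfTI goes through nibabel.

Array axis order is (x, y, z); MetaImage raw data is x-fastest, which maps
to Fortran order of our arrays.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import LabelMask, Volume

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask"]

_MET_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_UINT": np.uint32,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_NP_TO_MET = {np.dtype(v): k for k, v in _MET_TYPES.items()}


def _parse_mhd_header(text: str) -> dict[str, str]:
    hdr = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        hdr[key.strip()] = val.strip()
    return hdr


def _read_meta(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    raw_bytes = path.read_bytes()
    # header is ASCII key = value lines terminated by the ElementDataFile line
    end = raw_bytes.find(b"ElementDataFile")
    if end < 0:
        raise ValueError(f"{path}: missing ElementDataFile key")
    nl = raw_bytes.find(b"\n", end)
    header_text = raw_bytes[: nl + 1].decode("ascii")
    hdr = _parse_mhd_header(header_text)

    if int(hdr.get("NDims", "3")) != 3:
        raise ValueError(f"{path}: only 3D images supported")
    if hdr.get("CompressedData", "False").lower() == "true":
        raise ValueError(f"{path}: compressed MetaImage not supported")
    if hdr.get("BinaryDataByteOrderMSB", "False").lower() == "true":
        raise ValueError(f"{path}: big-endian MetaImage not supported")
    dtype = _MET_TYPES.get(hdr.get("ElementType", "MET_FLOAT"))
    if dtype is None:
        raise ValueError(f"{path}: unsupported ElementType {hdr.get('ElementType')}")
    dims = tuple(int(v) for v in hdr["DimSize"].split())
    spacing = tuple(float(v) for v in hdr.get("ElementSpacing", "1 1 1").split())
    origin = tuple(float(v) for v in hdr.get("Offset", hdr.get("Position", "0 0 0")).split())
    tm = hdr.get("TransformMatrix")
    if tm is not None:
        mat = np.array([float(v) for v in tm.split()]).reshape(3, 3)
        if not np.allclose(mat, np.eye(3)):
            raise ValueError(f"{path}: oblique direction matrices not supported")

    datafile = hdr["ElementDataFile"]
    if datafile == "LOCAL":
        buf = raw_bytes[nl + 1 :]
    else:
        buf = (path.parent / datafile).read_bytes()
    n = int(np.prod(dims))
    arr = np.frombuffer(buf, dtype=dtype, count=n)
    # raw order is x fastest -> reshape as (z, y, x) then transpose
    data = arr.reshape(dims[::-1]).transpose(2, 1, 0)
    return np.ascontiguousarray(data), spacing, origin


def _write_meta(path: Path, data: np.ndarray, spacing, origin, dtype=None) -> None:
    dtype = np.dtype(dtype or np.float64)
    met = _NP_TO_MET.get(dtype)
    if met is None:
        raise ValueError(f"cannot write dtype {dtype} as MetaImage")
    arr = np.asarray(data).astype(dtype)
    local = path.suffix.lower() == ".mha"
    datafile = "LOCAL" if local else path.with_suffix(".raw").name
    header = "\n".join(
        [
            "ObjectType = Image",
            "NDims = 3",
            "BinaryData = True",
            "BinaryDataByteOrderMSB = False",
            "CompressedData = False",
            "TransformMatrix = 1 0 0 0 1 0 0 0 1",
            f"Offset = {origin[0]!r} {origin[1]!r} {origin[2]!r}",
            "CenterOfRotation = 0 0 0",
            f"ElementSpacing = {spacing[0]!r} {spacing[1]!r} {spacing[2]!r}",
            f"DimSize = {arr.shape[0]} {arr.shape[1]} {arr.shape[2]}",
            f"ElementType = {met}",
            f"ElementDataFile = {datafile}",
        ]
    )
    raw = arr.transpose(2, 1, 0).tobytes()  # x fastest
    if local:
        path.write_bytes(header.encode("ascii") + b"\n" + raw)
    else:
        path.write_text(header + "\n")
        path.with_suffix(".raw").write_bytes(raw)


def _nifti_affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path) -> Volume:
    """Read a scalar 3D volume; rejects non-finite data."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".mha", ".mhd")):
        data, spacing, origin = _read_meta(path)
        return Volume(data, spacing, origin)
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
        aff = img.affine
        lin = aff[:3, :3]
        if not np.allclose(lin, np.diag(np.diag(lin))):
            raise ValueError(f"{path}: oblique direction cosines not supported")
        spacing = tuple(float(abs(lin[i, i])) for i in range(3))
        origin = tuple(float(v) for v in aff[:3, 3])
        return Volume(data, spacing, origin)
    raise ValueError(f"unsupported volume format: {path}")


def write_volume(volume: Volume, path: str | Path, dtype=None) -> None:
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".mha", ".mhd")):
        _write_meta(path, volume.data, volume.spacing, volume.origin, dtype)
        return
    if name.endswith((".nii", ".nii.gz")):
        arr = volume.data.astype(np.dtype(dtype) if dtype else np.float64)
        img = nib.Nifti1Image(arr, _nifti_affine(volume.spacing, volume.origin))
        img.header.set_zooms(volume.spacing)
        nib.save(img, str(path))
        return
    raise ValueError(f"unsupported volume format: {path}")


def read_mask(path: str | Path, like: Volume | None = None) -> LabelMask:
    v = read_volume(path)
    mask = LabelMask((v.data > 0.5), v.spacing, v.origin)
    if like is not None:
        mask.check_matches(like)
    return mask


def write_mask(mask: LabelMask, path: str | Path) -> None:
    vol = Volume(mask.data.astype(np.float64), mask.spacing, mask.origin)
    write_volume(vol, path, dtype=np.uint8)
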