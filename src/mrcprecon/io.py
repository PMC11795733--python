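"""K-space volume container, HDF5 I/O, slice decomposition, and normalization.

Two HDF5 dialects are supported:

``simple-h5``
    A documented flat layout used for fixtures and interchange: datasets
    ``kspace`` (complex, ``[coil, slice, pe, ro]``) and ``mask`` (uint8,
    ``[pe]``), attributes ``n_acs``, ``accel``, ``norm_factor``.

``ismrmrd-h5``
    A minimal ISMRMRD-style raw layout written and read by this package: a
    ``dataset`` group holding an XML header (encoded matrix size, parallel
    imaging factor, ACS count) and a compound ``data`` table with one record
    per acquired readout line, each carrying its encode-step counters.  It
    mirrors how Cartesian 3-D raw data is organized in the ISMRMRD standard
    but implements only the subset this package needs.

A 3-D acquisition fully sampled along the slice (partition) direction is
converted to independent 2-D problems by an inverse Fourier transform along
slices (`slice_decompose`); `normalize_volume` then applies one scalar factor
per volume chosen so the maximum magnitude of the zero-filled
root-sum-of-squares reconstruction equals 1, giving consistent data scaling
across volumes (and hence transferable regularization weights).
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import h5py
import nibabel as nib
import numpy as np

from .fourier import fftnc, ifft2c, ifftnc
from .masks import SamplingMask

__all__ = [
    "KSpaceVolume",
    "read_kspace",
    "write_kspace",
    "slice_decompose",
    "slice_recompose",
    "normalize_volume",
    "save_magnitude_nifti",
]


class ParseError(ValueError):
    """Raised when an input file is malformed; names the offending field."""


@dataclass
class KSpaceVolume:
    """Raw multicoil 3-D Cartesian k-space plus sampling annotation.

    ``samples`` is ordered ``[coil, slice, pe, ro]``; unsampled PE lines are
    exactly zero across all coils and slices.
    """

    samples: np.ndarray
    mask: SamplingMask
    norm_factor: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 4:
            raise ValueError("samples must be [coil, slice, pe, ro]")
        if self.samples.shape[2] != self.mask.n_pe:
            raise ValueError("mask length and PE dimension differ")
        if self.norm_factor <= 0:
            raise ValueError("norm_factor must be positive")

    @property
    def n_coils(self) -> int:
        return self.samples.shape[0]

    @property
    def n_slices(self) -> int:
        return self.samples.shape[1]


# --------------------------------------------------------------------------
# simple-h5 dialect
# --------------------------------------------------------------------------


def _write_simple(path, vol: KSpaceVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=vol.samples.astype(np.complex64))
        mask_arr = vol.mask.bool_array().astype(np.uint8)
        f.create_dataset("mask", data=mask_arr)
        f.attrs["n_acs"] = vol.mask.n_acs
        f.attrs["accel"] = vol.mask.accel
        f.attrs["acs_start"] = vol.mask.acs_start
        f.attrs["norm_factor"] = vol.norm_factor
        f.attrs["meta"] = json.dumps(vol.meta)


def _read_simple(path) -> KSpaceVolume:
    with h5py.File(path, "r") as f:
        if "kspace" not in f:
            raise ParseError("missing dataset 'kspace'")
        if "mask" not in f:
            raise ParseError("missing dataset 'mask'")
        samples = f["kspace"][()]
        mask_arr = f["mask"][()].astype(bool)
        n_acs = int(f.attrs.get("n_acs", 0))
        accel = int(f.attrs.get("accel", 1))
        acs_start = int(f.attrs.get("acs_start", mask_arr.size // 2 - n_acs // 2))
        norm_factor = float(f.attrs.get("norm_factor", 1.0))
        meta = json.loads(f.attrs.get("meta", "{}"))
    if samples.ndim != 4 or samples.shape[0] < 1:
        raise ParseError("dataset 'kspace' must be non-empty [coil, slice, pe, ro]")
    mask = SamplingMask(
        mask_arr.size, np.flatnonzero(mask_arr), acs_start, acs_start + n_acs, accel
    )
    return KSpaceVolume(samples, mask, norm_factor, meta)


# --------------------------------------------------------------------------
# ISMRMRD-style dialect
# --------------------------------------------------------------------------

_IDX_DTYPE = np.dtype(
    [("kspace_encode_step_1", "<u2"), ("kspace_encode_step_2", "<u2"), ("slice", "<u2")]
)


def _head_dtype() -> np.dtype:
    return np.dtype(
        [
            ("version", "<u2"),
            ("flags", "<u8"),
            ("scan_counter", "<u4"),
            ("active_channels", "<u2"),
            ("number_of_samples", "<u2"),
            ("idx", _IDX_DTYPE),
        ]
    )


def _xml_header(vol: KSpaceVolume) -> str:
    nc, ns, npe, nro = vol.samples.shape
    return (
        "<ismrmrdHeader>"
        "<encoding><encodedSpace><matrixSize>"
        f"<x>{nro}</x><y>{npe}</y><z>{ns}</z>"
        "</matrixSize></encodedSpace>"
        "<parallelImaging><accelerationFactor>"
        f"<kspace_encoding_step_1>{vol.mask.accel}</kspace_encoding_step_1>"
        "<kspace_encoding_step_2>1</kspace_encoding_step_2>"
        "</accelerationFactor></parallelImaging>"
        "</encoding>"
        "<userParameters>"
        f"<userParameterLong><name>n_acs</name><value>{vol.mask.n_acs}</value></userParameterLong>"
        f"<userParameterLong><name>acs_start</name><value>{vol.mask.acs_start}</value></userParameterLong>"
        f"<userParameterLong><name>coils</name><value>{nc}</value></userParameterLong>"
        "</userParameters>"
        "</ismrmrdHeader>"
    )


def _write_ismrmrd(path, vol: KSpaceVolume) -> None:
    nc, ns, npe, nro = vol.samples.shape
    sampled = vol.mask.sampled
    n_acq = ns * sampled.size
    rec_dtype = np.dtype(
        [("head", _head_dtype()), ("data", "<f4", (2 * nc * nro,))]
    )
    records = np.zeros(n_acq, dtype=rec_dtype)
    i = 0
    for s in range(ns):
        for pe in sampled:
            head = records[i]["head"]
            head["version"] = 1
            head["scan_counter"] = i + 1
            head["active_channels"] = nc
            head["number_of_samples"] = nro
            head["idx"]["kspace_encode_step_1"] = pe
            head["idx"]["kspace_encode_step_2"] = s
            line = vol.samples[:, s, pe, :].astype(np.complex64)
            records[i]["data"] = (
                np.stack([line.real, line.imag], axis=-1).reshape(-1)
            )
            i += 1
    with h5py.File(path, "w") as f:
        grp = f.create_group("dataset")
        grp.create_dataset("xml", data=np.bytes_(_xml_header(vol)))
        grp.create_dataset("data", data=records)
        grp.attrs["norm_factor"] = vol.norm_factor


def _parse_xml_long(root: ET.Element, name: str) -> int | None:
    for p in root.iter("userParameterLong"):
        if p.findtext("name") == name:
            return int(p.findtext("value"))
    return None


def _read_ismrmrd(path) -> KSpaceVolume:
    with h5py.File(path, "r") as f:
        if "dataset" not in f:
            raise ParseError("missing group 'dataset'")
        grp = f["dataset"]
        if "xml" not in grp:
            raise ParseError("missing dataset 'dataset/xml'")
        if "data" not in grp:
            raise ParseError("missing dataset 'dataset/data'")
        xml = grp["xml"][()]
        records = grp["data"][()]
        norm_factor = float(grp.attrs.get("norm_factor", 1.0))
    if isinstance(xml, bytes):
        xml = xml.decode()
    root = ET.fromstring(xml)
    msize = root.find("./encoding/encodedSpace/matrixSize")
    if msize is None:
        raise ParseError("XML header lacks encoding/encodedSpace/matrixSize")
    nro = int(msize.findtext("x"))
    npe = int(msize.findtext("y"))
    ns = int(msize.findtext("z"))
    accel_txt = root.findtext(
        "./encoding/parallelImaging/accelerationFactor/kspace_encoding_step_1"
    )
    accel = int(accel_txt) if accel_txt else 1
    n_acs = _parse_xml_long(root, "n_acs") or 0
    acs_start = _parse_xml_long(root, "acs_start")
    if records.size == 0:
        raise ParseError("dataset 'dataset/data' holds no acquisitions")
    nc = int(records["head"]["active_channels"][0])
    if nc < 1:
        raise ParseError("header field active_channels is zero")
    samples = np.zeros((nc, ns, npe, nro), dtype=np.complex64)
    seen_pe: set[int] = set()
    for rec in records:
        head = rec["head"]
        pe = int(head["idx"]["kspace_encode_step_1"])
        s = int(head["idx"]["kspace_encode_step_2"])
        nsamp = int(head["number_of_samples"])
        if nsamp != nro:
            raise ParseError("acquisition number_of_samples disagrees with header")
        line = rec["data"].reshape(nc, nro, 2)
        samples[:, s, pe, :] = line[..., 0] + 1j * line[..., 1]
        seen_pe.add(pe)
    sampled = np.array(sorted(seen_pe))
    if acs_start is None:
        acs_start = npe // 2 - n_acs // 2
    mask = SamplingMask(npe, sampled, acs_start, acs_start + n_acs, accel)
    return KSpaceVolume(samples, mask, norm_factor)


def read_kspace(path, dialect: str = "simple-h5") -> KSpaceVolume:
    """Read a k-space volume; ``dialect`` is ``simple-h5`` or ``ismrmrd-h5``."""
    if dialect == "simple-h5":
        return _read_simple(path)
    if dialect == "ismrmrd-h5":
        return _read_ismrmrd(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_kspace(path, vol: KSpaceVolume, dialect: str = "simple-h5") -> None:
    """Write a k-space volume in the requested dialect."""
    if dialect == "simple-h5":
        _write_simple(path, vol)
    elif dialect == "ismrmrd-h5":
        _write_ismrmrd(path, vol)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# --------------------------------------------------------------------------
# Slice decomposition and normalization
# --------------------------------------------------------------------------


def slice_decompose(vol: KSpaceVolume) -> np.ndarray:
    """3-D -> 2-D: inverse FFT along the fully sampled slice direction.

    Returns an array ``[slice, coil, pe, ro]`` of independent 2-D multicoil
    k-space slices; `slice_recompose` inverts the operation to machine
    precision (the transform is orthonormal).
    """
    hybrid = ifftnc(vol.samples, axis=1)
    return np.ascontiguousarray(np.moveaxis(hybrid, 1, 0))


def slice_recompose(slices: np.ndarray) -> np.ndarray:
    """Forward FFT along slices: inverse of `slice_decompose`."""
    return fftnc(np.moveaxis(np.asarray(slices), 0, 1), axis=1)


def zero_filled_rss(slices: np.ndarray) -> np.ndarray:
    """Zero-filled root-sum-of-squares magnitude stack ``[slice, ny, nx]``."""
    imgs = ifft2c(np.asarray(slices))
    return np.sqrt((np.abs(imgs) ** 2).sum(axis=1))


def normalize_volume(slices: np.ndarray) -> tuple[np.ndarray, float]:
    """Volume-wise normalization of a 2-D slice stack ``[slice, coil, pe, ro]``.

    One scalar factor per volume, chosen so the maximum magnitude of the
    zero-filled RSS reconstruction over the whole stack equals 1.  Returns
    ``(slices / factor, factor)``; the map is idempotent and homogeneous.
    """
    slices = np.asarray(slices)
    factor = float(zero_filled_rss(slices).max())
    if factor == 0:
        raise ValueError("cannot normalize an all-zero volume")
    return slices / factor, factor


def save_magnitude_nifti(path, volume: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Save a magnitude volume ``[slice, ny, nx]`` as NIfTI."""
    mag = np.abs(np.asarray(volume)).astype(np.float32)
    affine = np.diag([*voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.moveaxis(mag, 0, -1), affine), str(path))
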