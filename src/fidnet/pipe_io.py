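"""Minimal NMRPipe single-file format support.

An NMRPipe file is a 512-float32 header followed by float32 data.  Only
the header words the pipelines need are interpreted (sizes, sweep widths,
observe frequencies, domain and quadrature flags, transpose state); the
full header is carried through opaquely so a round trip preserves it.

Data layout for a 2D plane (direct x indirect): one row per indirect
component, each row holding the direct-dimension values (real row then
imaginary row per complex indirect point when the indirect dimension is
complex; real and imaginary direct halves concatenated when the direct
dimension is complex).  3D data is handled as a series of 2D plane files.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .pipeline import Axis, SpectrumPlane

__all__ = ["PipeSpectrum", "FormatError", "make_spectrum",
           "read_nmrpipe", "write_nmrpipe",
           "spectrum_from_plane", "plane_from_spectrum",
           "read_plane_series", "write_plane_series"]

HEADER_WORDS = 512

# header word offsets (fdatap.h numbering)
FDMAGIC = 0
FDFLTFORMAT = 1
FDFLTORDER = 2
FDDIMCOUNT = 9
FDF1QUADFLAG = 55
FDF2QUADFLAG = 56
FDF2CAR = 66
FDF1CAR = 67
FDF2FTSIZE = 96
FDF1FTSIZE = 98
FDSIZE = 99
FDF2SW = 100
FDQUADFLAG = 106
FDF2OBS = 119
FDF1OBS = 218
FDSPECNUM = 219
FDF2FTFLAG = 220
FDTRANSPOSED = 221
FDF1FTFLAG = 222
FDF1SW = 229

FLTORDER_VALUE = np.float32(2.345)
FLTFORMAT_VALUE = struct.unpack("<f", struct.pack("<I", 0xEEEEEEEE))[0]


class FormatError(Exception):
    """Malformed NMRPipe file; the message carries a byte-offset diagnostic."""


@dataclass
class PipeSpectrum:
    """Data grid plus its NMRPipe header.

    ``data`` is complex (direct, indirect); purely real dimensions carry a
    zero imaginary part and are flagged via the quad flags in the header.
    """

    data: np.ndarray
    header: np.ndarray  # float32[512]
    source_path: str | None = None

    @property
    def n_direct(self) -> int:
        return int(self.header[FDSIZE])

    @property
    def n_indirect(self) -> int:
        n = int(self.header[FDSPECNUM])
        return n // 2 if self.indirect_complex else n

    @property
    def direct_complex(self) -> bool:
        return self.header[FDF2QUADFLAG] == 0.0

    @property
    def indirect_complex(self) -> bool:
        return self.header[FDF1QUADFLAG] == 0.0

    @property
    def sw_direct(self) -> float:
        return float(self.header[FDF2SW])

    @property
    def sw_indirect(self) -> float:
        return float(self.header[FDF1SW])


def _empty_header() -> np.ndarray:
    h = np.zeros(HEADER_WORDS, dtype=np.float32)
    h[FDMAGIC] = 0.0
    h[FDFLTFORMAT] = FLTFORMAT_VALUE
    h[FDFLTORDER] = FLTORDER_VALUE
    h[FDDIMCOUNT] = 2.0
    return h


def make_spectrum(
    data: np.ndarray,
    sw_direct: float,
    sw_indirect: float,
    direct_domain: str = "freq",
    indirect_domain: str = "time",
    direct_complex: bool = False,
    indirect_complex: bool = True,
) -> PipeSpectrum:
    """Wrap a complex (direct, indirect) grid into a headered spectrum."""
    h = _empty_header()
    n_direct, n_indirect = data.shape
    h[FDSIZE] = n_direct
    h[FDSPECNUM] = n_indirect * (2 if indirect_complex else 1)
    h[FDF2SW] = sw_direct
    h[FDF1SW] = sw_indirect
    h[FDF2QUADFLAG] = 0.0 if direct_complex else 1.0
    h[FDF1QUADFLAG] = 0.0 if indirect_complex else 1.0
    h[FDQUADFLAG] = 1.0 if (not direct_complex and not indirect_complex) else 0.0
    h[FDF2FTFLAG] = 1.0 if direct_domain == "freq" else 0.0
    h[FDF1FTFLAG] = 1.0 if indirect_domain == "freq" else 0.0
    h[FDTRANSPOSED] = 0.0
    return PipeSpectrum(np.ascontiguousarray(data.astype(complex)), h)


def read_nmrpipe(path) -> PipeSpectrum:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < HEADER_WORDS * 4:
        raise FormatError(
            f"{path}: truncated header ({len(raw)} bytes < {HEADER_WORDS * 4})"
        )
    header = np.frombuffer(raw[: HEADER_WORDS * 4], dtype="<f4").copy()
    if abs(float(header[FDFLTORDER]) - 2.345) > 1e-4:
        swapped = np.frombuffer(raw[: HEADER_WORDS * 4], dtype=">f4").copy()
        if abs(float(swapped[FDFLTORDER]) - 2.345) > 1e-4:
            raise FormatError(
                f"{path}: bad float-order check word at byte offset {FDFLTORDER * 4}"
            )
        header = swapped.astype("<f4")
        payload = np.frombuffer(raw[HEADER_WORDS * 4:], dtype=">f4").astype("<f4")
    else:
        payload = np.frombuffer(raw[HEADER_WORDS * 4:], dtype="<f4")
    if header[FDMAGIC] != 0.0:
        raise FormatError(f"{path}: bad magic at byte offset 0")
    spec = PipeSpectrum(np.empty(0), header, source_path=str(path))
    n_direct, n_indirect = spec.n_direct, spec.n_indirect
    row_floats = n_direct * (2 if spec.direct_complex else 1)
    n_rows = n_indirect * (2 if spec.indirect_complex else 1)
    expected = row_floats * n_rows
    if payload.size != expected:
        raise FormatError(
            f"{path}: expected {expected} data floats after byte offset "
            f"{HEADER_WORDS * 4}, found {payload.size}"
        )
    rows = payload.reshape(n_rows, row_floats).astype(float)
    if spec.direct_complex:
        rows = rows[:, :n_direct] + 1j * rows[:, n_direct:]
    if spec.indirect_complex:
        data = (rows[0::2] + 1j * rows[1::2]).T
    else:
        data = rows.T.astype(complex)
    spec.data = np.ascontiguousarray(data)
    return spec


def write_nmrpipe(spectrum: PipeSpectrum, path) -> None:
    n_direct, n_indirect = spectrum.data.shape
    if n_direct != spectrum.n_direct or n_indirect != spectrum.n_indirect:
        raise FormatError("header sizes do not match the data grid")
    if spectrum.indirect_complex:
        rows = np.empty((2 * n_indirect, n_direct), dtype=complex)
        rows[0::2] = spectrum.data.T.real
        rows[1::2] = spectrum.data.T.imag
    else:
        rows = spectrum.data.T
    if spectrum.direct_complex:
        payload = np.concatenate([rows.real, rows.imag], axis=1)
    else:
        payload = rows.real
    with open(path, "wb") as fh:
        fh.write(spectrum.header.astype("<f4").tobytes())
        fh.write(payload.astype("<f4").tobytes())


def spectrum_from_plane(plane: SpectrumPlane) -> PipeSpectrum:
    return make_spectrum(
        plane.data,
        plane.direct.sw,
        plane.indirect.sw,
        direct_domain=plane.direct.domain,
        indirect_domain=plane.indirect.domain,
        direct_complex=False,
        indirect_complex=True,
    )


def plane_from_spectrum(spec: PipeSpectrum, half_dwell: bool = False) -> SpectrumPlane:
    direct = Axis(
        spec.n_direct, spec.sw_direct,
        domain="freq" if spec.header[FDF2FTFLAG] else "time",
    )
    indirect = Axis(
        spec.n_indirect, spec.sw_indirect,
        domain="freq" if spec.header[FDF1FTFLAG] else "time",
        half_dwell=half_dwell,
    )
    return SpectrumPlane(spec.data, direct, indirect)


def write_plane_series(spectra: list[PipeSpectrum], template: str) -> None:
    """Write a 3D dataset as numbered 2D planes (template like 'cube%03d.ft2')."""
    for k, s in enumerate(spectra, start=1):
        write_nmrpipe(s, template % k)


def read_plane_series(template: str, n_planes: int) -> list[PipeSpectrum]:
    return [read_nmrpipe(template % k) for k in range(1, n_planes + 1)]
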