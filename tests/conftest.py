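"""Shared fixtures and independent oracle writers for the native formats.

The MRC and SER writers here are implemented straight from the published
container layouts, independently of the package's own I/O code, so that
reader tests are genuine round trips against a second implementation.
"""

from __future__ import annotations

import struct

import numpy as np
import pytest

from microed_tools.geometry import AcquisitionGeometry

# --------------------------------------------------------------------------
# Oracle MRC2014 writer (independent of microed_tools.frame_io)
# --------------------------------------------------------------------------

_ORACLE_MRC_MODES = {
    np.dtype(np.int8): 0,
    np.dtype(np.int16): 1,
    np.dtype(np.float32): 2,
    np.dtype(np.uint16): 6,
}


def write_oracle_mrc(path, array, extended_header: bytes = b"") -> None:
    """Minimal MRC2014 stack writer built directly from the format spec."""
    array = np.asarray(array)
    assert array.ndim == 3
    mode = _ORACLE_MRC_MODES[np.dtype(array.dtype.base).newbyteorder("=")]
    nz, ny, nx = array.shape
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 28, nx, ny, nz)
    struct.pack_into("<6f", header, 40, nx, ny, nz, 90, 90, 90)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<i", header, 92, len(extended_header))
    struct.pack_into("<i", header, 108, 20140)
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(extended_header)
        fh.write(array.astype(array.dtype.newbyteorder("<")).tobytes())


# --------------------------------------------------------------------------
# Oracle TIA/SER writer (independent of microed_tools.frame_io)
# --------------------------------------------------------------------------

_ORACLE_SER_TAGS = {
    np.dtype(np.uint8): 1,
    np.dtype(np.uint16): 2,
    np.dtype(np.uint32): 3,
    np.dtype(np.int8): 4,
    np.dtype(np.int16): 5,
    np.dtype(np.int32): 6,
    np.dtype(np.float32): 7,
    np.dtype(np.float64): 8,
}


def write_oracle_ser(
    path,
    frames,
    version: int = 0x0210,
    dtype_tag_override: int | None = None,
    truncate_last: int = 0,
) -> None:
    """2-D SER series writer built directly from the published layout.

    ``dtype_tag_override`` and ``truncate_last`` deliberately corrupt the
    output for error-path tests.
    """
    frames = [np.asarray(f) for f in frames]
    n = len(frames)
    offset_fmt, offset_size = ("<q", 8) if version >= 0x0220 else ("<i", 4)

    header = struct.pack("<3h", 0x4949, 0x0197, version)
    header += struct.pack("<4i", 0x4122, 0x4152, n, n)
    # dimension array: one dimension of size n, no description/units
    dim = struct.pack("<i", n) + struct.pack("<2d", 0.0, 1.0)
    dim += struct.pack("<i", 0) + struct.pack("<i", 0) + struct.pack("<i", 0)

    elements = []
    for f in frames:
        tag = dtype_tag_override or _ORACLE_SER_TAGS[np.dtype(f.dtype.base)]
        elem = struct.pack("<2d", 0.0, 1.0) + struct.pack("<i", 0)
        elem += struct.pack("<2d", 0.0, 1.0) + struct.pack("<i", 0)
        elem += struct.pack("<h", tag)
        elem += struct.pack("<2i", f.shape[1], f.shape[0])
        elem += f.astype(f.dtype.newbyteorder("<")).tobytes()
        elements.append(elem)
    if truncate_last and elements:
        elements[-1] = elements[-1][:-truncate_last]

    preamble = len(header) + offset_size + 4 + len(dim)
    data_start = preamble + 2 * n * offset_size
    data_offsets, pos = [], data_start
    for elem in elements:
        data_offsets.append(pos)
        pos += len(elem)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(struct.pack(offset_fmt, preamble))
        fh.write(struct.pack("<i", 1))
        fh.write(dim)
        for off in data_offsets:
            fh.write(struct.pack(offset_fmt, off))
        for _ in range(n):
            fh.write(struct.pack(offset_fmt, 0))  # tag offsets (unused)
        for elem in elements:
            fh.write(elem)


# --------------------------------------------------------------------------
# Common fixtures
# --------------------------------------------------------------------------


@pytest.fixture
def falcon_geometry() -> AcquisitionGeometry:
    """The Falcon III acquisition geometry used throughout the study."""
    return AcquisitionGeometry(
        voltage_kv=200.0,
        distance_mm=2380.0,
        physical_pixel_um=14.0,
        binning=2,
        frame_shape=(2048, 2048),
        rotation_speed_deg_s=0.45,
        exposure_time_s=1.0,
        exposure_rate=0.01,
    )
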