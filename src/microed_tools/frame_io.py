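"""Reading native camera movie formats and writing SMV diffraction images.

Supports MRC2014 stacks (modes 0, 1, 2, 6) and TIA/ES Vision SER series.
Output is the SMV dialect consumed by MOSFLM/DIALS/XDS/ADXV: a
512-byte-multiple ASCII ``KEY=value;`` header followed by unsigned 16-bit
little-endian pixel data.

Negative pixel values found in the native formats are handled by the
pedestal policy: a per-data-set constant is added to every pixel and
values that remain negative are clipped to zero, with the clipped
fraction reported per frame.  No dark-current or flat-field correction is
ever applied.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from microed_tools.geometry import AcquisitionGeometry

__all__ = [
    "FormatError",
    "UnsupportedModeError",
    "ConfigurationError",
    "FrameStack",
    "ConversionConfig",
    "ConversionReport",
    "SMVHeader",
    "read_mrc_stack",
    "write_mrc_stack",
    "read_ser_series",
    "apply_pedestal",
    "build_smv_header",
    "write_smv",
    "read_smv",
    "write_tiff",
    "convert_dataset",
]


class FormatError(ValueError):
    """The file does not conform to the expected container layout."""


class UnsupportedModeError(FormatError):
    """The container is valid but uses a data type this reader does not handle."""


class ConfigurationError(ValueError):
    """Required acquisition metadata is missing and was not overridden."""


@dataclass
class FrameStack:
    """A 3-D movie of detector frames, indexed (frame, slow, fast)."""

    pixels: np.ndarray
    source_format: str = "SYNTHETIC"
    per_frame_time: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(
                f"pixels must be 3-D (frame, slow, fast), got ndim={self.pixels.ndim}"
            )
        if self.n_frames < 1 or min(self.frame_shape) < 1:
            raise ValueError("stack must contain at least one non-empty frame")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]


@dataclass
class ConversionConfig:
    """Policy knobs for converting a native movie stack to SMV frames."""

    pedestal: int = 0
    saturation_cap: int = 65535
    distance_mm: float | None = None
    beam_center: tuple[float, float] | None = None  # mm
    oscillation_start_deg: float = 0.0
    oscillation_per_frame_deg: float = 0.0
    user_overrides: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pedestal < 0:
            raise ValueError(f"pedestal must be >= 0, got {self.pedestal}")
        if self.saturation_cap <= 0:
            raise ValueError("saturation_cap must be positive")


@dataclass
class ConversionReport:
    frames_written: int
    clipped_fraction_per_frame: list[float]
    saturated_count_per_frame: list[int]
    pedestal_used: int


# ---------------------------------------------------------------------------
# MRC2014
# ---------------------------------------------------------------------------

_MRC_MODE_DTYPES = {
    0: np.dtype("<i1"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}
_MRC_DTYPE_MODES = {
    np.dtype(np.int8): 0,
    np.dtype(np.int16): 1,
    np.dtype(np.float32): 2,
    np.dtype(np.uint16): 6,
}
_MRC_HEADER_BYTES = 1024


def read_mrc_stack(path: str | Path) -> FrameStack:
    """Read an MRC2014 movie stack, preserving pixel values bit-exactly.

    Extended headers are skipped per NSYMBT.  Axis order is taken as
    (NZ, NY, NX) -> (frame, slow, fast); MAPC/MAPR/MAPS permutations are
    not honoured.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER_BYTES:
        raise FormatError(
            f"{path}: file too short for an MRC header "
            f"({len(raw)} < {_MRC_HEADER_BYTES} bytes)"
        )
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    magic = raw[208:212]
    if magic != b"MAP ":
        raise FormatError(f"{path}: bad MAP magic {magic!r}; not an MRC2014 file")
    if mode not in _MRC_MODE_DTYPES:
        raise UnsupportedModeError(
            f"{path}: MRC mode {mode} is not supported "
            f"(supported modes: {sorted(_MRC_MODE_DTYPES)})"
        )
    if nx < 1 or ny < 1 or nz < 1:
        raise FormatError(f"{path}: non-positive dimensions ({nx}, {ny}, {nz})")
    dtype = _MRC_MODE_DTYPES[mode]
    offset = _MRC_HEADER_BYTES + nsymbt
    n_expected = nx * ny * nz
    payload = raw[offset : offset + n_expected * dtype.itemsize]
    if len(payload) < n_expected * dtype.itemsize:
        raise FormatError(
            f"{path}: truncated pixel payload "
            f"({len(payload)} < {n_expected * dtype.itemsize} bytes)"
        )
    pixels = np.frombuffer(payload, dtype=dtype).reshape(nz, ny, nx).copy()
    return FrameStack(pixels=pixels, source_format="MRC")


def write_mrc_stack(
    stack: FrameStack | np.ndarray, path: str | Path, nsymbt_junk: bytes = b""
) -> None:
    """Write a minimal MRC2014 stack (used by the simulator and fixtures)."""
    pixels = stack.pixels if isinstance(stack, FrameStack) else np.asarray(stack)
    if pixels.ndim != 3:
        raise ValueError("expected a 3-D (frame, slow, fast) array")
    dtype = np.dtype(pixels.dtype).newbyteorder("=")
    if np.dtype(dtype.base) not in _MRC_DTYPE_MODES:
        raise UnsupportedModeError(
            f"dtype {pixels.dtype} has no MRC mode; use one of "
            f"{sorted(str(d) for d in _MRC_DTYPE_MODES)}"
        )
    mode = _MRC_DTYPE_MODES[np.dtype(dtype.base)]
    nz, ny, nx = pixels.shape
    header = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # MX, MY, MZ
    struct.pack_into("<6f", header, 40, float(nx), float(ny), float(nz), 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # MAPC, MAPR, MAPS
    arr = pixels.astype(float)
    struct.pack_into("<3f", header, 76, float(arr.min()), float(arr.max()), float(arr.mean()))
    struct.pack_into("<i", header, 92, len(nsymbt_junk))  # NSYMBT
    struct.pack_into("<i", header, 108, 20140)  # NVERSION
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian stamp
    struct.pack_into("<f", header, 216, float(arr.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(nsymbt_junk)
        fh.write(np.ascontiguousarray(pixels, dtype=dtype.newbyteorder("<")).tobytes())


# ---------------------------------------------------------------------------
# TIA / ES Vision SER
# ---------------------------------------------------------------------------

_SER_DTYPES = {
    1: np.dtype("<u1"),
    2: np.dtype("<u2"),
    3: np.dtype("<u4"),
    4: np.dtype("<i1"),
    5: np.dtype("<i2"),
    6: np.dtype("<i4"),
    7: np.dtype("<f4"),
    8: np.dtype("<f8"),
}
_SER_2D = 0x4122


def read_ser_series(path: str | Path) -> FrameStack:
    """Read all 2-D data elements of a TIA/ES Vision SER file, in file order."""
    raw = Path(path).read_bytes()
    try:
        byte_order, series_id, version = struct.unpack_from("<3h", raw, 0)
    except struct.error as exc:
        raise FormatError(f"{path}: file too short for a SER header") from exc
    if byte_order != 0x4949 or series_id != 0x0197:
        raise FormatError(
            f"{path}: bad SER signature (byte order {byte_order:#x}, id {series_id:#x})"
        )
    data_type_id, _tag_type_id, total_elements, valid_elements = struct.unpack_from(
        "<4i", raw, 6
    )
    if data_type_id != _SER_2D:
        raise UnsupportedModeError(
            f"{path}: only 2-D SER series are supported, got DataTypeID {data_type_id:#x}"
        )
    pos = 22
    if version >= 0x0220:
        (offset_array_offset,) = struct.unpack_from("<q", raw, pos)
        pos += 8
        offset_fmt, offset_size = "<q", 8
    else:
        (offset_array_offset,) = struct.unpack_from("<i", raw, pos)
        pos += 4
        offset_fmt, offset_size = "<i", 4
    (n_dims,) = struct.unpack_from("<i", raw, pos)
    pos += 4
    for _ in range(n_dims):  # dimension arrays are read and discarded
        pos += 4 + 8 + 8 + 4
        (desc_len,) = struct.unpack_from("<i", raw, pos)
        pos += 4 + desc_len
        (units_len,) = struct.unpack_from("<i", raw, pos)
        pos += 4 + units_len
    if valid_elements < 1:
        raise FormatError(f"{path}: SER series contains no valid data elements")
    if offset_array_offset + valid_elements * offset_size > len(raw):
        raise FormatError(f"{path}: truncated SER offset array")
    offsets = [
        struct.unpack_from(offset_fmt, raw, offset_array_offset + i * offset_size)[0]
        for i in range(valid_elements)
    ]
    frames = []
    for off in offsets:
        if off + 50 > len(raw):
            raise FormatError(f"{path}: data element header at {off} beyond end of file")
        (dtype_tag,) = struct.unpack_from("<h", raw, off + 40)
        size_x, size_y = struct.unpack_from("<2i", raw, off + 42)
        if dtype_tag not in _SER_DTYPES:
            raise UnsupportedModeError(
                f"{path}: unknown SER data-type tag {dtype_tag}; "
                f"supported tags: {sorted(_SER_DTYPES)}"
            )
        dtype = _SER_DTYPES[dtype_tag]
        nbytes = size_x * size_y * dtype.itemsize
        payload = raw[off + 50 : off + 50 + nbytes]
        if len(payload) < nbytes:
            raise FormatError(
                f"{path}: truncated SER data element ({len(payload)} < {nbytes} bytes)"
            )
        frames.append(np.frombuffer(payload, dtype=dtype).reshape(size_y, size_x))
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"{path}: inconsistent frame shapes {sorted(shapes)}")
    common = np.result_type(*[f.dtype for f in frames])
    pixels = np.stack([f.astype(common) for f in frames])
    return FrameStack(pixels=pixels, source_format="SER")


# ---------------------------------------------------------------------------
# Pedestal policy
# ---------------------------------------------------------------------------


def apply_pedestal(
    stack: FrameStack, pedestal: int
) -> tuple[FrameStack, list[float]]:
    """Add ``pedestal`` to every pixel and clip remaining negatives to zero.

    Returns the adjusted stack and the per-frame fraction of pixels that
    were clipped (raw value at or below ``-pedestal``, i.e. pixels left
    with no signal after the shift).
    """
    if pedestal < 0:
        raise ValueError(f"pedestal must be >= 0, got {pedestal}")
    shifted = stack.pixels.astype(np.float64) + pedestal
    clipped_mask = shifted <= 0
    shifted[shifted < 0] = 0
    n_per_frame = stack.frame_shape[0] * stack.frame_shape[1]
    clipped_fractions = [
        float(clipped_mask[i].sum()) / n_per_frame for i in range(stack.n_frames)
    ]
    if np.issubdtype(stack.pixels.dtype, np.integer):
        shifted = np.rint(shifted).astype(np.int64)
    out = FrameStack(
        pixels=shifted,
        source_format=stack.source_format,
        per_frame_time=stack.per_frame_time,
    )
    return out, clipped_fractions


# ---------------------------------------------------------------------------
# SMV
# ---------------------------------------------------------------------------


class SMVHeader:
    """Ordered ``KEY=value;`` header of an SMV image.

    Serializes to exactly HEADER_BYTES bytes (a multiple of 512), opening
    with ``{`` and closing with ``}`` before the padding.
    """

    def __init__(self, entries: dict[str, str] | None = None) -> None:
        self.entries: dict[str, str] = dict(entries or {})

    def __getitem__(self, key: str) -> str:
        return self.entries[key]

    def __setitem__(self, key: str, value) -> None:
        self.entries[key] = str(value)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def serialize(self) -> bytes:
        def body_for(header_bytes: int) -> bytes:
            entries = dict(self.entries)
            entries["HEADER_BYTES"] = str(header_bytes)
            lines = ["{"]
            lines.append(f"HEADER_BYTES={header_bytes};")
            for key, value in entries.items():
                if key == "HEADER_BYTES":
                    continue
                lines.append(f"{key}={value};")
            lines.append("}")
            return ("\n".join(lines) + "\n").encode("ascii")

        header_bytes = int(self.entries.get("HEADER_BYTES", 512))
        body = body_for(header_bytes)
        while len(body) > header_bytes:
            header_bytes += 512
            body = body_for(header_bytes)
        if header_bytes % 512 != 0:
            raise ValueError(f"HEADER_BYTES must be a multiple of 512, got {header_bytes}")
        self.entries["HEADER_BYTES"] = str(header_bytes)
        return body + b" " * (header_bytes - len(body))

    @classmethod
    def parse(cls, raw: bytes) -> "SMVHeader":
        if not raw.lstrip().startswith(b"{"):
            raise FormatError("SMV header does not start with '{'")
        text = raw.split(b"}", 1)[0].decode("ascii", errors="replace")
        entries: dict[str, str] = {}
        for match in re.finditer(r"(\w+)\s*=\s*([^;]*);", text):
            entries[match.group(1)] = match.group(2).strip()
        return cls(entries)


def build_smv_header(
    geom: AcquisitionGeometry, config: ConversionConfig, frame_index: int
) -> SMVHeader:
    """Derive the SMV header for frame ``frame_index`` (0-based).

    WAVELENGTH comes from the acceleration voltage; OSC_START advances by
    the per-frame oscillation (which may be negative for high-to-zero
    rotation) while OSC_RANGE is always written positive.  User overrides
    are applied last and win over every derived value.
    """
    if config.distance_mm is None and "DISTANCE" not in config.user_overrides:
        raise ConfigurationError(
            "the calibrated sample-to-detector distance is not contained in the "
            "native metadata and must be specified by the user (distance_mm or a "
            "DISTANCE override)"
        )
    rows, cols = geom.frame_shape
    pixel_mm = geom.pixel_size_mm
    osc_start = (
        config.oscillation_start_deg + frame_index * config.oscillation_per_frame_deg
    )
    beam_center = config.beam_center or (cols / 2.0 * pixel_mm, rows / 2.0 * pixel_mm)
    header = SMVHeader()
    header["HEADER_BYTES"] = "512"
    header["DIM"] = "2"
    header["BYTE_ORDER"] = "little_endian"
    header["TYPE"] = "unsigned_short"
    header["SIZE1"] = str(cols)
    header["SIZE2"] = str(rows)
    header["PIXEL_SIZE"] = f"{pixel_mm:.6g}"
    header["BIN"] = f"{geom.binning}x{geom.binning}"
    if config.distance_mm is not None:
        header["DISTANCE"] = f"{config.distance_mm:.6g}"
    header["WAVELENGTH"] = f"{geom.wavelength:.6g}"
    header["OSC_START"] = f"{osc_start:.6g}"
    header["OSC_RANGE"] = f"{abs(config.oscillation_per_frame_deg):.6g}"
    header["PHI"] = f"{osc_start:.6g}"
    header["TIME"] = f"{geom.exposure_time_s:.6g}"
    header["BEAM_CENTER_X"] = f"{beam_center[0]:.6g}"
    header["BEAM_CENTER_Y"] = f"{beam_center[1]:.6g}"
    for key, value in config.user_overrides.items():
        header[key] = value
    return header


def write_smv(
    frame: np.ndarray,
    header: SMVHeader,
    path: str | Path,
    saturation_cap: int = 65535,
) -> int:
    """Write one SMV image; returns the number of saturated (clamped) pixels."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if np.any(frame < 0):
        raise ValueError("frame contains negative values; apply the pedestal first")
    saturated = int(np.count_nonzero(frame > saturation_cap))
    clamped = np.minimum(frame, saturation_cap).astype("<u2")
    header["SIZE1"] = str(frame.shape[1])
    header["SIZE2"] = str(frame.shape[0])
    with open(path, "wb") as fh:
        fh.write(header.serialize())
        fh.write(np.ascontiguousarray(clamped).tobytes())
    return saturated


def read_smv(path: str | Path) -> tuple[np.ndarray, SMVHeader]:
    """Read an SMV image back (for round-trip verification)."""
    raw = Path(path).read_bytes()
    header = SMVHeader.parse(raw[:512])
    header_bytes = int(header["HEADER_BYTES"])
    if header_bytes > 512:
        header = SMVHeader.parse(raw[:header_bytes])
    size1 = int(header["SIZE1"])
    size2 = int(header["SIZE2"])
    expected = size1 * size2 * 2
    payload = raw[header_bytes : header_bytes + expected]
    if len(payload) < expected:
        raise FormatError(f"{path}: truncated SMV payload")
    pixels = np.frombuffer(payload, dtype="<u2").reshape(size2, size1).copy()
    return pixels, header


def write_tiff(frame: np.ndarray, path: str | Path) -> None:
    """Write a single frame as 16-bit TIFF (optional alternative output)."""
    import tifffile

    frame = np.asarray(frame)
    if np.any(frame < 0):
        raise ValueError("frame contains negative values; apply the pedestal first")
    tifffile.imwrite(str(path), np.minimum(frame, 65535).astype(np.uint16))


# ---------------------------------------------------------------------------
# Dataset conversion
# ---------------------------------------------------------------------------

_READERS = {
    ".mrc": read_mrc_stack,
    ".mrcs": read_mrc_stack,
    ".ser": read_ser_series,
}


def read_stack(path: str | Path) -> FrameStack:
    """Dispatch to the appropriate native-format reader by file extension."""
    suffix = Path(path).suffix.lower()
    if suffix not in _READERS:
        raise FormatError(
            f"{path}: unrecognized input format {suffix!r} "
            f"(expected one of {sorted(_READERS)})"
        )
    return _READERS[suffix](path)


def convert_dataset(
    input_path: str | Path,
    geom: AcquisitionGeometry,
    config: ConversionConfig,
    out_dir: str | Path,
    stem: str | None = None,
) -> ConversionReport:
    """Convert a native movie stack into one SMV file per frame.

    Files are named ``<stem>_NNNNN.img`` with a 1-based zero-padded frame
    number.  No corrections beyond the pedestal policy are applied.
    """
    stack = read_stack(input_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or Path(input_path).stem
    adjusted, clipped_fractions = apply_pedestal(stack, config.pedestal)
    saturated_counts = []
    for i in range(adjusted.n_frames):
        header = build_smv_header(geom, config, i)
        out_path = out_dir / f"{stem}_{i + 1:05d}.img"
        saturated_counts.append(
            write_smv(adjusted.pixels[i], header, out_path, config.saturation_cap)
        )
    return ConversionReport(
        frames_written=adjusted.n_frames,
        clipped_fraction_per_frame=clipped_fractions,
        saturated_count_per_frame=saturated_counts,
        pedestal_used=config.pedestal,
    )
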