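import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import write_oracle_mrc, write_oracle_ser
from microed_tools.frame_io import (
    ConfigurationError,
    ConversionConfig,
    FormatError,
    FrameStack,
    SMVHeader,
    UnsupportedModeError,
    apply_pedestal,
    build_smv_header,
    convert_dataset,
    read_mrc_stack,
    read_ser_series,
    read_smv,
    write_mrc_stack,
    write_smv,
    write_tiff,
)
from microed_tools.geometry import AcquisitionGeometry


class TestMRCReader:
    def test_round_trip_signed_mode1(self, tmp_path):
        rng = np.random.default_rng(0)
        frames = rng.integers(-5, 11, size=(3, 8, 6)).astype(np.int16)
        path = tmp_path / "stack.mrc"
        write_oracle_mrc(path, frames)
        stack = read_mrc_stack(path)
        assert stack.n_frames == 3
        assert stack.frame_shape == (8, 6)
        assert stack.source_format == "MRC"
        np.testing.assert_array_equal(stack.pixels, frames)

    @pytest.mark.parametrize("dtype", [np.int8, np.int16, np.float32, np.uint16])
    def test_all_supported_modes(self, tmp_path, dtype):
        frames = np.arange(24, dtype=dtype).reshape(2, 3, 4)
        if np.issubdtype(dtype, np.signedinteger):
            frames = frames - 5
        path = tmp_path / "m.mrc"
        write_oracle_mrc(path, frames)
        np.testing.assert_array_equal(read_mrc_stack(path).pixels, frames)

    def test_extended_header_skipped(self, tmp_path):
        frames = np.arange(-6, 6, dtype=np.int16).reshape(1, 3, 4)
        path = tmp_path / "ext.mrc"
        write_oracle_mrc(path, frames, extended_header=bytes(range(128)))
        np.testing.assert_array_equal(read_mrc_stack(path).pixels, frames)

    def test_zero_length_file(self, tmp_path):
        path = tmp_path / "empty.mrc"
        path.write_bytes(b"")
        with pytest.raises(FormatError):
            read_mrc_stack(path)

    def test_bad_magic(self, tmp_path):
        frames = np.zeros((1, 2, 2), dtype=np.int16)
        path = tmp_path / "bad.mrc"
        write_oracle_mrc(path, frames)
        raw = bytearray(path.read_bytes())
        raw[208:212] = b"XXXX"
        path.write_bytes(bytes(raw))
        with pytest.raises(FormatError):
            read_mrc_stack(path)

    def test_unsupported_mode_named_in_error(self, tmp_path):
        frames = np.zeros((1, 2, 2), dtype=np.int16)
        path = tmp_path / "mode3.mrc"
        write_oracle_mrc(path, frames)
        raw = bytearray(path.read_bytes())
        raw[12] = 3  # complex int16 mode, unsupported
        path.write_bytes(bytes(raw))
        with pytest.raises(UnsupportedModeError, match="3"):
            read_mrc_stack(path)

    def test_truncated_payload(self, tmp_path):
        frames = np.zeros((4, 16, 16), dtype=np.int16)
        path = tmp_path / "trunc.mrc"
        write_oracle_mrc(path, frames)
        raw = path.read_bytes()
        path.write_bytes(raw[:-100])
        with pytest.raises(FormatError):
            read_mrc_stack(path)

    def test_package_writer_matches_oracle_reader_path(self, tmp_path):
        # package writer -> package reader, and oracle writer -> package
        # reader must agree on identical input
        frames = np.arange(-10, 14, dtype=np.int16).reshape(2, 3, 4)
        p1, p2 = tmp_path / "pkg.mrc", tmp_path / "oracle.mrc"
        write_mrc_stack(FrameStack(frames), p1)
        write_oracle_mrc(p2, frames)
        np.testing.assert_array_equal(
            read_mrc_stack(p1).pixels, read_mrc_stack(p2).pixels
        )


class TestSERReader:
    def test_round_trip_int16(self, tmp_path):
        rng = np.random.default_rng(1)
        frames = rng.integers(-100, 100, size=(2, 4, 4)).astype(np.int16)
        path = tmp_path / "s.ser"
        write_oracle_ser(path, list(frames))
        stack = read_ser_series(path)
        assert stack.n_frames == 2
        assert stack.source_format == "SER"
        np.testing.assert_array_equal(stack.pixels, frames)

    def test_float32_negative_value_preserved(self, tmp_path):
        frame = np.array([[0.5, -1.5], [2.25, 3.0]], dtype=np.float32)
        path = tmp_path / "f.ser"
        write_oracle_ser(path, [frame])
        stack = read_ser_series(path)
        assert stack.pixels.dtype.kind == "f"
        np.testing.assert_array_equal(stack.pixels[0], frame)

    def test_version_0220_int64_offsets(self, tmp_path):
        frames = np.arange(32, dtype=np.uint16).reshape(2, 4, 4)
        path = tmp_path / "v22.ser"
        write_oracle_ser(path, list(frames), version=0x0220)
        np.testing.assert_array_equal(read_ser_series(path).pixels, frames)

    def test_truncated_payload_is_an_error(self, tmp_path):
        frames = np.zeros((2, 4, 4), dtype=np.int16)
        path = tmp_path / "t.ser"
        write_oracle_ser(path, list(frames), truncate_last=8)
        with pytest.raises(FormatError):
            read_ser_series(path)

    def test_unknown_dtype_tag(self, tmp_path):
        path = tmp_path / "u.ser"
        write_oracle_ser(path, [np.zeros((2, 2), dtype=np.int16)], dtype_tag_override=99)
        with pytest.raises(UnsupportedModeError, match="99"):
            read_ser_series(path)

    def test_not_a_ser_file(self, tmp_path):
        path = tmp_path / "junk.ser"
        path.write_bytes(b"\x00" * 64)
        with pytest.raises(FormatError):
            read_ser_series(path)

    def test_reader_equivalence_mrc_vs_ser(self, tmp_path):
        rng = np.random.default_rng(2)
        frames = rng.integers(-50, 500, size=(3, 8, 8)).astype(np.int16)
        mrc, ser = tmp_path / "a.mrc", tmp_path / "a.ser"
        write_oracle_mrc(mrc, frames)
        write_oracle_ser(ser, list(frames))
        np.testing.assert_array_equal(
            read_mrc_stack(mrc).pixels, read_ser_series(ser).pixels
        )


class TestApplyPedestal:
    def test_no_clipping(self):
        stack = FrameStack(np.array([[[-3, 0, 5]]], dtype=np.int16))
        out, clipped = apply_pedestal(stack, 8)
        np.testing.assert_array_equal(out.pixels[0, 0], [5, 8, 13])
        assert clipped == [0.0]

    def test_clipping_below_negative_pedestal(self):
        stack = FrameStack(np.array([[[-10, -8, 7]]], dtype=np.int16))
        out, clipped = apply_pedestal(stack, 8)
        np.testing.assert_array_equal(out.pixels[0, 0], [0, 0, 15])
        assert clipped == [pytest.approx(2 / 3)]

    def test_gaussian_tail_matches_brute_force(self):
        rng = np.random.default_rng(3)
        frame = rng.normal(0.0, 5.0, size=(64, 64))
        stack = FrameStack(frame[None])
        pedestal = 4
        out, clipped = apply_pedestal(stack, pedestal)
        expected = sum(
            1 for v in frame.ravel() if v + pedestal < 0
        ) / frame.size  # elementwise oracle
        assert clipped[0] == pytest.approx(expected)
        assert np.all(out.pixels >= 0)

    def test_negative_pedestal_rejected(self):
        with pytest.raises(ValueError):
            apply_pedestal(FrameStack(np.zeros((1, 2, 2))), -1)

    def test_conservation_when_nothing_clipped(self):
        rng = np.random.default_rng(4)
        frame = rng.integers(-7, 100, size=(1, 32, 32)).astype(np.int32)
        stack = FrameStack(frame)
        out, clipped = apply_pedestal(stack, 8)
        assert clipped == [0.0]
        assert out.pixels.sum() == frame.sum() + 8 * frame[0].size

    @given(st.integers(min_value=0, max_value=50))
    @settings(max_examples=30, deadline=None)
    def test_monotone_clipped_fraction_in_pedestal(self, pedestal):
        rng = np.random.default_rng(5)
        frame = rng.normal(-10.0, 20.0, size=(1, 32, 32))
        _, low = apply_pedestal(FrameStack(frame), pedestal)
        _, high = apply_pedestal(FrameStack(frame), pedestal + 5)
        assert high[0] <= low[0]


class TestSMVHeader:
    def _config(self, **kwargs):
        defaults = dict(
            pedestal=8,
            distance_mm=2380.0,
            oscillation_start_deg=-30.0,
            oscillation_per_frame_deg=0.45,
        )
        defaults.update(kwargs)
        return ConversionConfig(**defaults)

    def test_wavelength_derived_from_voltage(self, falcon_geometry):
        header = build_smv_header(falcon_geometry, self._config(), 0)
        assert float(header["WAVELENGTH"]) == pytest.approx(0.025079, abs=5e-7)

    def test_oscillation_at_frame_zero(self, falcon_geometry):
        header = build_smv_header(falcon_geometry, self._config(), 0)
        assert float(header["OSC_START"]) == -30.0
        assert float(header["OSC_RANGE"]) == 0.45

    def test_oscillation_advances_per_frame(self, falcon_geometry):
        header = build_smv_header(falcon_geometry, self._config(), 10)
        assert float(header["OSC_START"]) == pytest.approx(-30.0 + 10 * 0.45)

    def test_negative_rotation_keeps_positive_range(self, falcon_geometry):
        config = self._config(
            oscillation_start_deg=30.0, oscillation_per_frame_deg=-0.45
        )
        h0 = build_smv_header(falcon_geometry, config, 0)
        h1 = build_smv_header(falcon_geometry, config, 1)
        assert float(h1["OSC_START"]) < float(h0["OSC_START"])
        assert float(h0["OSC_RANGE"]) == 0.45

    def test_pixel_size_from_binning(self, falcon_geometry):
        header = build_smv_header(falcon_geometry, self._config(), 0)
        assert float(header["PIXEL_SIZE"]) == pytest.approx(0.028)

    def test_missing_distance_is_a_configuration_error(self, falcon_geometry):
        with pytest.raises(ConfigurationError, match="specified by the user"):
            build_smv_header(falcon_geometry, self._config(distance_mm=None), 0)

    def test_distance_override_suffices(self, falcon_geometry):
        config = self._config(
            distance_mm=None, user_overrides={"DISTANCE": "2380.0"}
        )
        header = build_smv_header(falcon_geometry, config, 0)
        assert header["DISTANCE"] == "2380.0"

    def test_user_overrides_win(self, falcon_geometry):
        config = self._config(user_overrides={"WAVELENGTH": "9.9"})
        header = build_smv_header(falcon_geometry, config, 0)
        assert header["WAVELENGTH"] == "9.9"

    def test_serialization_contract(self, falcon_geometry):
        header = build_smv_header(falcon_geometry, self._config(), 0)
        raw = header.serialize()
        assert len(raw) == int(header["HEADER_BYTES"])
        assert len(raw) % 512 == 0
        assert raw.startswith(b"{")
        assert b"WAVELENGTH=" in raw
        parsed = SMVHeader.parse(raw)
        assert parsed.entries == header.entries

    def test_large_header_grows_in_512_steps(self):
        header = SMVHeader({f"KEY{i:03d}": "x" * 20 for i in range(40)})
        raw = header.serialize()
        assert len(raw) % 512 == 0
        assert len(raw) >= 1024


class TestWriteSMV:
    def _header(self):
        return SMVHeader({"HEADER_BYTES": "512", "DIM": "2"})

    def test_boundary_values_round_trip(self, tmp_path):
        frame = np.array([[0, 65535], [1, 2]], dtype=np.uint16)
        path = tmp_path / "b.img"
        assert write_smv(frame, self._header(), path) == 0
        out, _ = read_smv(path)
        np.testing.assert_array_equal(out, frame)

    def test_saturation_clamped_and_counted(self, tmp_path):
        frame = np.array([[70000, 10], [0, 1]], dtype=np.int64)
        path = tmp_path / "s.img"
        assert write_smv(frame, self._header(), path) == 1
        out, _ = read_smv(path)
        assert out[0, 0] == 65535

    def test_negative_values_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_smv(np.array([[-1, 0]]), self._header(), tmp_path / "n.img")

    def test_file_size_contract(self, tmp_path):
        frame = np.zeros((16, 24), dtype=np.uint16)
        path = tmp_path / "z.img"
        write_smv(frame, self._header(), path)
        _, header = read_smv(path)
        assert path.stat().st_size == int(header["HEADER_BYTES"]) + 2 * 16 * 24
        assert int(header["SIZE1"]) == 24
        assert int(header["SIZE2"]) == 16

    @given(
        frame=hnp.arrays(
            dtype=np.uint16,
            shape=hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=24),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_is_bit_exact(self, frame, tmp_path_factory):
        path = tmp_path_factory.mktemp("smv") / "rt.img"
        write_smv(frame, self._header(), path)
        out, _ = read_smv(path)
        np.testing.assert_array_equal(out, frame)


class TestTIFF:
    def test_round_trip(self, tmp_path):
        import tifffile

        frame = np.arange(64, dtype=np.uint16).reshape(8, 8)
        path = tmp_path / "f.tif"
        write_tiff(frame, path)
        np.testing.assert_array_equal(tifffile.imread(str(path)), frame)


class TestConvertDataset:
    def _setup(self, tmp_path, frames):
        path = tmp_path / "in.mrc"
        write_oracle_mrc(path, frames)
        geom = AcquisitionGeometry(
            voltage_kv=200.0,
            distance_mm=2380.0,
            binning=2,
            frame_shape=frames.shape[1:],
        )
        config = ConversionConfig(
            pedestal=8, distance_mm=2380.0, oscillation_per_frame_deg=0.45
        )
        return path, geom, config

    def test_three_frames_three_files(self, tmp_path):
        frames = np.arange(48, dtype=np.int16).reshape(3, 4, 4) - 4
        path, geom, config = self._setup(tmp_path, frames)
        report = convert_dataset(path, geom, config, tmp_path / "out")
        assert report.frames_written == 3
        files = sorted((tmp_path / "out").glob("*.img"))
        assert [f.name for f in files] == ["in_00001.img", "in_00002.img", "in_00003.img"]
        assert len(report.clipped_fraction_per_frame) == 3
        assert report.pedestal_used == 8

    def test_pedestal_applied_to_output(self, tmp_path):
        frames = np.array([[[-3, 0], [5, -20]]], dtype=np.int16)
        path, geom, config = self._setup(tmp_path, frames)
        report = convert_dataset(path, geom, config, tmp_path / "out")
        out, _ = read_smv(tmp_path / "out" / "in_00001.img")
        np.testing.assert_array_equal(out, [[5, 8], [13, 0]])
        assert report.clipped_fraction_per_frame[0] == pytest.approx(0.25)

    def test_determinism_byte_identical(self, tmp_path):
        rng = np.random.default_rng(6)
        frames = rng.integers(-20, 200, size=(2, 8, 8)).astype(np.int16)
        path, geom, config = self._setup(tmp_path, frames)
        convert_dataset(path, geom, config, tmp_path / "o1")
        convert_dataset(path, geom, config, tmp_path / "o2")
        for f1 in sorted((tmp_path / "o1").glob("*.img")):
            f2 = tmp_path / "o2" / f1.name
            assert f1.read_bytes() == f2.read_bytes()

    def test_ser_input_same_output(self, tmp_path):
        rng = np.random.default_rng(7)
        frames = rng.integers(-20, 200, size=(2, 8, 8)).astype(np.int16)
        mrc_path, geom, config = self._setup(tmp_path, frames)
        ser_path = tmp_path / "in.ser"
        write_oracle_ser(ser_path, list(frames))
        convert_dataset(mrc_path, geom, config, tmp_path / "om")
        convert_dataset(ser_path, geom, config, tmp_path / "os")
        a, _ = read_smv(tmp_path / "om" / "in_00001.img")
        b, _ = read_smv(tmp_path / "os" / "in_00001.img")
        np.testing.assert_array_equal(a, b)
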