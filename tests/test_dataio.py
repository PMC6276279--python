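import numpy as np
import pytest

from credkit.dataio import (SmvHeader, SmvParseError, next_experiment_dir,
                            parse_dials_params, read_experiment_log, read_mrc,
                            read_smv, read_tiff, write_dials_params,
                            write_experiment_log, write_geo_corr_smv, write_mrc,
                            write_redp, write_smv, write_tiff, write_xds_inp)
from credkit.distortion import DistortionModel
from credkit.frames import DetectorFrame, GeometryState
from credkit.physics import BeamParameters, InvalidArgumentError
from credkit.schedule import (AcquisitionSchedule, RotationMetadata,
                              build_schedule, dials_exclusions)


def corrected_frame(pixels):
    return DetectorFrame(pixels=pixels, geometry_state=GeometryState.CORRECTED516)


@pytest.fixture()
def dataset2_schedule():
    # 430 data frames, defocus every 10th; rotation rate = range / total time
    # (102.55 deg / 224.7 s), which puts 0.2336 deg in each 0.512 s slot
    speed = 102.55 / 224.7
    return build_schedule(n_data=430, n_interval=10, frame_time=0.512,
                          start_angle=-43.90, rotation_speed=speed)


class TestSmv:
    def test_bit_exact_round_trip(self, tmp_path, rng):
        pix = rng.integers(0, 65536, size=(516, 516)).astype(float)
        header = SmvHeader(beam_center_x=258.25, beam_center_y=255.5,
                           osc_start=-43.9, osc_range=0.2337, exposure=0.5)
        path = write_smv(corrected_frame(pix), header, tmp_path / "f.img")
        frame, hdr = read_smv(path)
        assert np.array_equal(frame.pixels, pix)
        assert hdr == header

    def test_counts_clamped_to_uint16(self, tmp_path):
        pix = np.zeros((516, 516))
        pix[0, 0] = 70000
        path = write_smv(corrected_frame(pix), SmvHeader(), tmp_path / "f.img")
        frame, _ = read_smv(path)
        assert frame.pixels[0, 0] == 65535

    def test_osc_range_from_dataset2_schedule(self, tmp_path, dataset2_schedule):
        header = SmvHeader(osc_range=dataset2_schedule.oscillation_per_slot)
        path = write_smv(corrected_frame(np.zeros((516, 516))), header,
                         tmp_path / "f.img")
        _, hdr = read_smv(path)
        assert hdr.osc_range == pytest.approx(0.2336, abs=1e-4)

    def test_malformed_header_names_offending_key(self, tmp_path):
        path = tmp_path / "bad.img"
        head = b"{\nHEADER_BYTES= 512;\nTYPE=unsigned_short;\n}\n"
        path.write_bytes(head.ljust(512, b"\x00") + b"\x00" * 8)
        with pytest.raises(SmvParseError, match="SIZE1"):
            read_smv(path)

    def test_raw_frame_rejected(self, tmp_path):
        raw = DetectorFrame(pixels=np.zeros((512, 512)),
                            geometry_state=GeometryState.RAW512)
        with pytest.raises(InvalidArgumentError):
            write_smv(raw, SmvHeader(), tmp_path / "f.img")

    def test_writer_is_deterministic(self, tmp_path, rng):
        pix = rng.integers(0, 1000, size=(516, 516)).astype(float)
        p1 = write_smv(corrected_frame(pix), SmvHeader(), tmp_path / "a.img")
        p2 = write_smv(corrected_frame(pix), SmvHeader(), tmp_path / "b.img")
        assert p1.read_bytes() == p2.read_bytes()


class TestTiffMrc:
    def test_tiff_round_trip_with_metadata(self, tmp_path, rng):
        pix = rng.integers(0, 5000, size=(516, 516)).astype(float)
        meta = {"camera_length": 250.0, "frame_index": 3}
        path = write_tiff(corrected_frame(pix), meta, tmp_path / "f.tiff")
        data, meta2 = read_tiff(path)
        assert np.array_equal(data, pix)
        assert meta2 == meta

    def test_mrc_round_trip_with_metadata(self, tmp_path, rng):
        pix = rng.integers(0, 5000, size=(516, 516)).astype(float)
        meta = {"wavelength": 0.02508, "exposure": 0.5}
        path = write_mrc(corrected_frame(pix), meta, tmp_path / "f.mrc")
        data, meta2 = read_mrc(path)
        assert np.array_equal(data, pix)
        assert meta2 == meta


class TestXdsInp:
    def write(self, tmp_path, schedule, distortion=None, center=(257.1, 255.9)):
        return write_xds_inp(schedule, center, distortion,
                             BeamParameters(camera_length=250.0),
                             tmp_path / "XDS.INP")

    def test_dataset2_has_43_exclude_lines(self, tmp_path, dataset2_schedule):
        text = self.write(tmp_path, dataset2_schedule).read_text()
        excl = [l for l in text.splitlines() if l.startswith("EXCLUDE_DATA_RANGE=")]
        assert len(excl) == 43
        assert excl[0] == "EXCLUDE_DATA_RANGE= 11 11"
        assert "DATA_RANGE= 1 473" in text

    def test_untrusted_rectangles_present(self, tmp_path, dataset2_schedule):
        text = self.write(tmp_path, dataset2_schedule).read_text()
        assert "UNTRUSTED_RECTANGLE= 255 262 0 517" in text
        assert "UNTRUSTED_RECTANGLE= 0 517 255 262" in text

    def test_wavelength_printed_to_5_significant_figures(self, tmp_path,
                                                         dataset2_schedule):
        text = self.write(tmp_path, dataset2_schedule).read_text()
        assert "X-RAY_WAVELENGTH= 0.02508" in text

    def test_orgx_orgy_one_based(self, tmp_path, dataset2_schedule):
        text = self.write(tmp_path, dataset2_schedule).read_text()
        assert "ORGX= 258.1000 ORGY= 256.9000" in text

    def test_no_geo_corr_without_distortion(self, tmp_path, dataset2_schedule):
        text = self.write(tmp_path, dataset2_schedule,
                          DistortionModel(eccentricity=0.0)).read_text()
        assert "GEO_CORR" not in text

    def test_geo_corr_referenced_with_distortion(self, tmp_path,
                                                 dataset2_schedule):
        text = self.write(tmp_path, dataset2_schedule,
                          DistortionModel(eccentricity=0.22)).read_text()
        assert "X-GEO_CORR= GEO_CORR_X.img" in text
        assert "Y-GEO_CORR= GEO_CORR_Y.img" in text

    def test_missing_beam_center_refused(self, tmp_path, dataset2_schedule):
        with pytest.raises(InvalidArgumentError, match="beam-center"):
            write_xds_inp(dataset2_schedule, None, None, BeamParameters(),
                          tmp_path / "XDS.INP")

    def test_golden_file_stability(self, tmp_path, dataset2_schedule):
        (tmp_path / "a").mkdir()
        (tmp_path / "b").mkdir()
        a = self.write(tmp_path / "a", dataset2_schedule)
        b = self.write(tmp_path / "b", dataset2_schedule)
        assert a.read_text() == b.read_text()

    def test_geo_corr_tables_written_as_smv(self, tmp_path):
        m = DistortionModel(eccentricity=0.22, center=(258, 258))
        px, py = write_geo_corr_smv(m, tmp_path)
        frame, _ = read_smv(py)
        # bias of 32768 encodes zero offset
        assert frame.pixels[258, 258] == 32768
        assert frame.pixels.min() < 32768 < frame.pixels.max()


class TestDialsParams:
    def test_no_gaps_single_token(self, tmp_path):
        s = build_schedule(n_data=7, n_interval=10)
        text = write_dials_params(s, tmp_path / "d.txt").read_text()
        assert "scan_range=1,7" in text
        assert "exclude_images" not in text.split("\n")[0].replace(
            "dials.find_spots", "")

    def test_dataset2_43_exclude_tokens(self, tmp_path, dataset2_schedule):
        text = write_dials_params(dataset2_schedule, tmp_path / "d.txt").read_text()
        assert text.count("exclude_images=") == 43

    def test_round_trip_matches_source_ranges(self, tmp_path, dataset2_schedule):
        path = write_dials_params(dataset2_schedule, tmp_path / "d.txt")
        parsed = parse_dials_params(path)
        assert parsed == dials_exclusions(dataset2_schedule)


class TestRedp:
    def test_midpoint_angles(self, tmp_path):
        s = build_schedule(n_data=10, n_interval=99, frame_time=1.0,
                           start_angle=0.0, rotation_speed=1.0)
        lines = write_redp(s, tmp_path / "r.txt").read_text().strip().splitlines()
        assert len(lines) == 11
        angles = [float(l.split()[1]) for l in lines[1:]]
        assert angles == pytest.approx([0.5 + i for i in range(10)])

    def test_empty_schedule_header_only(self, tmp_path):
        s = AcquisitionSchedule(slots=[])
        lines = write_redp(s, tmp_path / "r.txt").read_text().strip().splitlines()
        assert lines == ["# frame  tilt_angle(deg)"]

    def test_angle_monotonicity_follows_rotation_sign(self, tmp_path):
        s = build_schedule(n_data=10, n_interval=99, rotation_speed=-0.7)
        lines = write_redp(s, tmp_path / "r.txt").read_text().strip().splitlines()
        angles = [float(l.split()[1]) for l in lines[1:]]
        assert all(a > b for a, b in zip(angles, angles[1:]))


class TestExperimentLog:
    def test_directories_increment_and_never_overwrite(self, tmp_path):
        d1 = next_experiment_dir(tmp_path)
        d2 = next_experiment_dir(tmp_path)
        assert d1.name == "exp_000001"
        assert d2.name == "exp_000002"
        assert d1.exists() and d2.exists()

    def test_exhausted_suffixes_raise(self, tmp_path):
        next_experiment_dir(tmp_path, limit=1)
        with pytest.raises(IOError):
            next_experiment_dir(tmp_path, limit=1)

    def test_log_round_trips_numeric_fields(self, tmp_path):
        s = build_schedule(n_data=30, n_interval=10)
        meta = RotationMetadata.from_schedule(s)
        path = write_experiment_log(meta, tmp_path / "log.yaml")
        assert read_experiment_log(path) == meta

    def test_dataset1_tilt_range(self, tmp_path):
        # 554 data + 55 defocus slots sweeping -64.06 .. 63.91
        speed = 127.97 / (609 * 0.512)
        s = build_schedule(n_data=554, n_interval=10, frame_time=0.512,
                           start_angle=-64.06, rotation_speed=speed)
        meta = RotationMetadata.from_schedule(s)
        path = write_experiment_log(meta, tmp_path / "log.yaml")
        loaded = read_experiment_log(path)
        assert loaded.tilt_range == pytest.approx(127.97, abs=1e-9)
        assert loaded.end_angle == pytest.approx(63.91, abs=1e-9)
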