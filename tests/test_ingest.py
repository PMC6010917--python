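"""NMEA conversion, raw-file parsing, and the track-cleaning rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grazetrack import ingest

from conftest import constant_cadence_fixes


class TestNmeaConversion:
    @pytest.mark.parametrize("field,hemi,expected", [
        ("4916.46", "N", 49 + 16.46 / 60),          # the GPGLL staple
        ("0000.00", "N", 0.0),
        ("12345.67", "W", -(123 + 45.67 / 60)),
        ("4916.46", "S", -(49 + 16.46 / 60)),
    ])
    def test_decode(self, field, hemi, expected):
        assert ingest.nmea_to_decimal(field, hemi) == pytest.approx(
            expected, abs=1e-9)

    @pytest.mark.parametrize("field,hemi", [
        ("4966.00", "N"),   # minutes >= 60
        ("49xx.46", "N"),   # non-numeric
        ("4916.46", "Q"),   # bad hemisphere
        ("9.46", "N"),      # too short for a degrees part
    ])
    def test_decode_rejects(self, field, hemi):
        with pytest.raises(ValueError):
            ingest.nmea_to_decimal(field, hemi)

    def test_encode_worked_example(self):
        assert ingest.decimal_to_nmea(49.274333333, True) == ("4916.4600", "N")
        assert ingest.decimal_to_nmea(-(123 + 45.67 / 60), False) == (
            "12345.6700", "W")

    @settings(derandomize=True, max_examples=200)
    @given(lat=st.floats(-89.999, 89.999), lon=st.floats(-179.999, 179.999))
    def test_round_trip_within_encoding_precision(self, lat, lon):
        """decode(encode(x)) is within 1e-6 degrees at 4 minute decimals."""
        for dd, is_lat in ((lat, True), (lon, False)):
            fld, hemi = ingest.decimal_to_nmea(dd, is_lat)
            back = ingest.nmea_to_decimal(fld, hemi)
            assert back == pytest.approx(dd, abs=1.0e-6)


class TestParseLoggerFile:
    GOOD = "070717,120000.000,1,4600.0000,N,10239.0000,W,8"

    def test_parses_good_skips_truncated(self, tmp_path):
        p = tmp_path / "L01.TXT"
        p.write_text("\n".join([self.GOOD, self.GOOD,
                                "070717,1200", self.GOOD]) + "\n")
        df = ingest.parse_logger_file(p)
        assert len(df) == 3
        assert df.attrs["n_malformed"] == 1

    def test_empty_file(self, tmp_path):
        p = tmp_path / "L02.TXT"
        p.write_text("")
        df = ingest.parse_logger_file(p)
        assert df.empty

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ingest.parse_logger_file(tmp_path / "nope.TXT")


class TestTimestamps:
    @pytest.mark.parametrize("utc,offset,expected", [
        ("2017-07-07 03:00", -6, "2017-07-06 21:00"),
        ("2017-07-07 03:00", 0, "2017-07-07 03:00"),
        ("2017-07-07 00:30", -6, "2017-07-06 18:30"),
    ])
    def test_localize(self, utc, offset, expected):
        assert ingest.localize_timestamp(pd.Timestamp(utc), offset) == \
            pd.Timestamp(expected)


class TestDedupe:
    def _records(self):
        return pd.DataFrame({
            "utc_date": ["2017-07-07"] * 4,
            "utc_time": ["12:00:00.000", "12:00:20.000"] * 2,
            "fix_quality": 1, "lat_field": "4600.0000",
            "lat_hemisphere": "N", "lon_field": "10239.0000",
            "lon_hemisphere": "W", "satellites": 8,
        })

    def test_exact_duplicates_halved(self):
        df = pd.concat([self._records()] * 2, ignore_index=True)
        assert len(ingest.dedupe(df)) == len(self._records().drop_duplicates())

    def test_identity_without_duplicates(self):
        df = self._records().drop_duplicates().reset_index(drop=True)
        pd.testing.assert_frame_equal(ingest.dedupe(df), df)

    def test_same_time_different_coords_kept(self):
        df = self._records().drop_duplicates().reset_index(drop=True)
        other = df.copy()
        other.loc[:, "lat_field"] = "4601.0000"
        both = pd.concat([df, other], ignore_index=True)
        assert len(ingest.dedupe(both)) == len(both)


class TestCropAndAssign:
    def test_identity_when_inside(self, square_pastures, default_config):
        e0, n0 = default_config.origin_utm()
        fx = constant_cadence_fixes(easting0=e0 + 400, northing0=n0 + 400)
        kept, counts = ingest.crop_and_assign(fx, square_pastures, "P1")
        assert len(kept) == len(fx)
        assert counts == {"wrong_pasture": 0, "out_of_bounds": 0}

    def test_wrong_side_of_fence_discarded(self, square_pastures,
                                           default_config):
        e0, n0 = default_config.origin_utm()
        fx = constant_cadence_fixes(n=1, easting0=e0 + 801.0,
                                    northing0=n0 + 400)
        kept, counts = ingest.crop_and_assign(fx, square_pastures, "P1")
        assert len(kept) == 0
        assert counts["wrong_pasture"] == 1

    def test_far_outlier_out_of_bounds(self, square_pastures, default_config):
        e0, n0 = default_config.origin_utm()
        fx = constant_cadence_fixes(n=1, easting0=e0 + 10_000,
                                    northing0=n0 + 10_000)
        kept, counts = ingest.crop_and_assign(fx, square_pastures, "P1")
        assert len(kept) == 0
        assert counts["out_of_bounds"] == 1

    def test_unknown_pasture(self, square_pastures):
        with pytest.raises(KeyError):
            ingest.crop_and_assign(constant_cadence_fixes(n=1),
                                   square_pastures, "P9")


class TestDaytimeFilter:
    def test_boundaries_half_open(self):
        fx = constant_cadence_fixes(start="2017-07-07 03:59:59", n=2,
                                    step_s=1)
        kept = ingest.daytime_filter(fx)
        assert len(kept) == 1
        assert pd.Timestamp(kept["time_local"].iloc[0]).hour == 4

    def test_uniform_day_keeps_75_percent(self):
        fx = constant_cadence_fixes(start="2017-07-07 00:00:00",
                                    n=24 * 180, step_s=20)
        kept = ingest.daytime_filter(fx)
        assert len(kept) / len(fx) == pytest.approx(0.75)


class TestDeploymentValidation:
    @pytest.mark.parametrize("n,valid", [(999, False), (1000, True),
                                         (16000, True)])
    def test_min_fix_threshold(self, n, valid):
        dep = ingest.Deployment("L1", "A1", "P1", "july",
                                constant_cadence_fixes(n=n, step_s=20))
        assert ingest.validate_deployment(dep).valid is valid


class TestCleaningPipeline:
    def _raw(self, default_config, n=60):
        """Raw records inside P1 with planted duplicates / outliers."""
        from grazetrack.synthetic_herd import (HerdSimConfig, observe_fixes,
                                               simulate_herd, emit_logger_files)
        cfg = HerdSimConfig(n_animals=1, duration_days=1, fine_step_s=20,
                            fix_failure_prob=0, outlier_prob=0, seed=9)
        fixes = observe_fixes(simulate_herd(cfg)[0]).head(n)
        import tempfile, pathlib
        with tempfile.TemporaryDirectory() as td:
            path = emit_logger_files(fixes, td)[0]
            lines = pathlib.Path(path).read_text().strip().split("\n")
        # plant: 5 duplicate rows, 1 wrong-pasture row, 1 far outlier
        lines = lines + lines[:5]
        wrong = lines[0].split(",")
        wrong[5] = "10238.1000"   # ~1.2 km east of origin: beyond the
        #                           shared fence, inside neighbouring P2
        far = lines[1].split(",")
        far[3], far[5] = "4630.0000", "10239.0000"   # ~55 km north
        lines += [",".join(wrong), ",".join(far)]
        return "\n".join(lines) + "\n"

    def test_removal_counts_sum_to_row_loss(self, tmp_path, square_pastures,
                                            default_config):
        p = tmp_path / "L03.TXT"
        p.write_text(self._raw(default_config))
        raw = ingest.parse_logger_file(p)
        dep = ingest.clean_deployment(raw, square_pastures, "P1",
                                      daytime=None, min_fixes=10)
        c = dep.removal_counts
        assert c["duplicate"] == 5
        assert c["wrong_pasture"] >= 1
        assert c["out_of_bounds"] >= 1
        removed = c["duplicate"] + c["wrong_pasture"] + c["out_of_bounds"]
        assert removed == len(raw) - len(dep.fixes)

    def test_pipeline_idempotent(self, tmp_path, square_pastures,
                                 default_config):
        """Cleaning its own output changes nothing."""
        p = tmp_path / "L04.TXT"
        p.write_text(self._raw(default_config))
        raw = ingest.parse_logger_file(p)
        dep1 = ingest.clean_deployment(raw, square_pastures, "P1",
                                       daytime=None, min_fixes=10)
        fx = dep1.fixes
        fx2, counts = ingest.crop_and_assign(fx, square_pastures, "P1")
        pd.testing.assert_frame_equal(fx2, fx)
        assert sum(counts.values()) == 0


def test_to_utm_warns_outside_zone():
    with pytest.warns(UserWarning):
        ingest.to_utm(46.0, -95.0)
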