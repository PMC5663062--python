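"""Core types, spectrum file round trips, and the bundled library fixture."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chrysoraman import (
    DEFAULT_GRID,
    CoverageError,
    Peak,
    PeakPattern,
    RamanSpectrum,
    SpectralLibrary,
    SpectrumParseError,
    ValidationError,
    WavenumberGrid,
    export_library_csv,
    load_library,
    read_spectrum,
    save_library,
    write_spectrum,
)


class TestGridAndTypes:
    def test_default_grid_covers_scan_range_at_unit_resolution(self):
        assert len(DEFAULT_GRID) == 1401
        assert DEFAULT_GRID.wavenumbers[0] == 400
        assert DEFAULT_GRID.wavenumbers[-1] == 1800

    @pytest.mark.parametrize(
        "kwargs",
        [dict(start=1800, stop=400), dict(step=0), dict(step=-1)],
    )
    def test_degenerate_grids_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            WavenumberGrid(**kwargs)

    def test_spectrum_length_and_finiteness_enforced(self):
        with pytest.raises(ValidationError):
            RamanSpectrum(grid=DEFAULT_GRID, intensities=np.zeros(7))
        bad = np.zeros(1401)
        bad[3] = np.nan
        with pytest.raises(ValidationError):
            RamanSpectrum(grid=DEFAULT_GRID, intensities=bad)

    def test_pattern_requires_increasing_positions_and_unit_maximum(self):
        with pytest.raises(ValidationError):
            PeakPattern("x", [Peak(700, 1.0), Peak(650, 0.5)])
        with pytest.raises(ValidationError):
            PeakPattern("x", [Peak(650, 0.5), Peak(700, 0.9)])
        pattern = PeakPattern("x", [Peak(650, 0.5), Peak(700, 1.0)])
        assert pattern.strongest_position() == 700

    def test_peak_field_ranges(self):
        with pytest.raises(ValidationError):
            Peak(position=700, normalized_intensity=1.2)
        with pytest.raises(ValidationError):
            Peak(position=700, height=-1.0)


class TestSpectrumIO:
    def test_zero_signal_file_reads_as_zeros_on_default_grid(self, tmp_path):
        path = tmp_path / "zeros.txt"
        path.write_text("".join(f"{wn} 0.0\n" for wn in range(400, 1801)))
        spectrum = read_spectrum(path)
        assert len(spectrum.intensities) == 1401
        assert np.all(spectrum.intensities == 0)

    def test_linear_function_interpolates_exactly_from_finer_axis(self, tmp_path):
        path = tmp_path / "ramp.txt"
        axis = np.arange(400, 1800.5, 0.5)
        path.write_text("".join(f"{wn} {wn}\n" for wn in axis))
        spectrum = read_spectrum(path)
        np.testing.assert_allclose(spectrum.intensities, spectrum.wavenumbers, rtol=1e-12)

    def test_comma_delimited_accepted(self, tmp_path):
        path = tmp_path / "csvish.txt"
        path.write_text("".join(f"{wn},{wn % 7}\n" for wn in range(400, 1801)))
        spectrum = read_spectrum(path)
        assert spectrum.intensities[0] == 400 % 7

    def test_malformed_row_error_names_the_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        rows = [f"{wn} 1.0" for wn in range(400, 1801)]
        rows[4] = "404 not-a-number"
        path.write_text("\n".join(rows))
        with pytest.raises(SpectrumParseError, match=":5:"):
            read_spectrum(path)

    def test_narrow_coverage_rejected(self, tmp_path):
        path = tmp_path / "narrow.txt"
        path.write_text("".join(f"{wn} 1.0\n" for wn in range(600, 1201)))
        with pytest.raises(CoverageError):
            read_spectrum(path)

    def test_zero_spectrum_writes_1401_data_rows(self, tmp_path):
        spectrum = RamanSpectrum(grid=DEFAULT_GRID, intensities=np.zeros(1401))
        path = write_spectrum(spectrum, tmp_path / "zero.txt")
        rows = [l for l in path.read_text().splitlines() if l and not l.startswith("#")]
        assert len(rows) == 1401

    def test_metadata_round_trips_as_comment_header(self, tmp_path):
        spectrum = RamanSpectrum(
            grid=DEFAULT_GRID,
            intensities=np.ones(1401),
            label="sample",
            metadata={"excitation_nm": "785", "power_mW": "3.3"},
        )
        path = write_spectrum(spectrum, tmp_path / "meta.txt")
        header = [l for l in path.read_text().splitlines() if l.startswith("#")]
        assert any("excitation_nm: 785" in l for l in header)
        back = read_spectrum(path)
        assert back.metadata["power_mW"] == "3.3"
        assert back.label == "sample"

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_write_then_read_identity_within_1e6_relative(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        spectrum = RamanSpectrum(
            grid=DEFAULT_GRID,
            intensities=rng.normal(0, 1000, 1401),
        )
        path = tmp_path_factory.mktemp("io") / "s.txt"
        back = read_spectrum(write_spectrum(spectrum, path))
        np.testing.assert_allclose(back.intensities, spectrum.intensities, rtol=1e-6, atol=1e-4)


class TestLibraryIO:
    def test_bundled_fixture_round_trips_exactly(self, library, tmp_path):
        path = save_library(library, tmp_path / "lib.json")
        back = load_library(path)
        assert len(back) == len(library)
        for pattern in library:
            other = back[pattern.cultivar]
            assert other.positions == pattern.positions
            assert other.intensities == pattern.intensities

    def test_empty_library_round_trips(self, tmp_path):
        empty = SpectralLibrary(name="empty", patterns={})
        back = load_library(save_library(empty, tmp_path / "empty.json"))
        assert len(back) == 0
        assert back.name == "empty"

    def test_duplicate_cultivar_names_rejected_on_load(self, tmp_path):
        doc = {
            "schema_version": 1,
            "name": "dup",
            "patterns": [
                {"cultivar": "X", "peaks": [{"position": 700, "normalized_intensity": 1}]},
                {"cultivar": "X", "peaks": [{"position": 800, "normalized_intensity": 1}]},
            ],
        }
        path = tmp_path / "dup.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError, match="duplicate"):
            load_library(path)

    def test_out_of_range_intensity_rejected_on_load(self, tmp_path):
        doc = {
            "schema_version": 1,
            "name": "bad",
            "patterns": [
                {"cultivar": "X", "peaks": [{"position": 700, "normalized_intensity": 1.4}]}
            ],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError):
            load_library(path)

    def test_csv_export_lists_every_peak(self, library, tmp_path):
        path = export_library_csv(library, tmp_path / "lib.csv")
        rows = path.read_text().splitlines()
        assert rows[0] == "cultivar,position,normalized_intensity"
        assert len(rows) - 1 == sum(len(p) for p in library)


class TestBundledLibraryFacts:
    def test_contains_26_cultivars(self, library):
        assert len(library) == 26

    def test_every_pattern_normalized_to_unit_maximum(self, library):
        for pattern in library:
            assert max(pattern.intensities) == 1

    def test_strongest_peak_of_every_cultivar_in_731_734(self, library):
        strongest = {p.cultivar: p.strongest_position() for p in library}
        assert all(731 <= pos <= 734 for pos in strongest.values())
        assert max(strongest.values()) == 734
        assert strongest["Blue Eye"] == 734

    def test_row_wise_peak_and_intensity_counts_agree(self, library):
        for pattern in library:
            assert len(pattern.positions) == len(pattern.intensities)
        assert len(library["Marshal Flag"]) == 9
        assert len(library["Jade Feng"]) == 11

    def test_white_jade_four_decimal_intensity_kept_verbatim(self, library):
        pattern = library["White Jade"]
        value = dict(zip(pattern.positions, pattern.intensities))[1022]
        assert value == 0.0422
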