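"""Spectral types, msp / SQLite / CSV round-trips, and mzML I/O."""

import numpy as np
import pytest

from specmatch.spectra_io import (
    LibraryEntry,
    Scan,
    SpectralLibrary,
    Spectrum,
    library_to_sqlite,
    load_library_sqlite,
    normalize_spectrum,
    read_csv_library,
    read_msp,
    read_mzml,
    write_msp,
    write_mzml,
)

MSP_FIXTURE = """\
Name: Alanine
PRECURSORMZ: 90.0549
PRECURSORTYPE: [M+H]+
IONMODE: Positive
FORMULA: C3H7NO2
Comment: class=amino_acid source=synthetic
Num Peaks: 3
44.0495 100.0
72.0444 35.5
90.0549 10.0

Name: Serine
PrecursorMZ: 106.0499
Num Peaks: 2
60.0444; 100.0
88.0393; 22.0
"""


def entry(name="X", precursor=500.0, peaks=((100.0, 50.0), (200.0, 100.0))):
    return LibraryEntry(
        compound_name=name,
        precursor_mz=precursor,
        adduct="[M+H]+",
        polarity=+1,
        spectrum=Spectrum.from_peaks(list(peaks)),
        formula="C10H10",
        metadata={"class": "test"},
    )


class TestSpectrum:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([100.0, 99.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            Spectrum(np.array([100.0]), np.array([-1.0]))
        with pytest.raises(ValueError):
            Spectrum(np.array([100.0]), np.array([1.0, 2.0]))

    def test_empty_allowed(self):
        assert len(Spectrum(np.array([]), np.array([]))) == 0

    def test_from_peaks_sorts_and_sums_duplicates(self):
        s = Spectrum.from_peaks([(200.0, 1.0), (100.0, 2.0), (200.0, 3.0)])
        assert s.mz.tolist() == [100.0, 200.0]
        assert s.intensity.tolist() == [2.0, 4.0]


class TestNormalize:
    def test_base_peak_scaled_to_100(self):
        s = Spectrum(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
        assert normalize_spectrum(s).intensity.tolist() == [25.0, 50.0, 100.0]

    def test_single_peak(self):
        s = Spectrum(np.array([7.0]), np.array([7.0]))
        assert normalize_spectrum(s).intensity.tolist() == [100.0]

    def test_idempotent(self):
        s = normalize_spectrum(Spectrum(np.array([1.0, 2.0]), np.array([3.0, 9.0])))
        assert normalize_spectrum(s) == s

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            normalize_spectrum(Spectrum(np.array([1.0]), np.array([0.0])))
        with pytest.raises(ValueError):
            normalize_spectrum(Spectrum(np.array([]), np.array([])))


class TestMsp:
    def test_fixture_parses_both_records(self, tmp_path):
        path = tmp_path / "lib.msp"
        path.write_text(MSP_FIXTURE)
        lib = read_msp(path)
        assert len(lib) == 2
        ala, ser = lib.entries
        assert ala.compound_name == "Alanine"
        assert ala.precursor_mz == pytest.approx(90.0549)
        assert ala.adduct == "[M+H]+"
        assert ala.metadata["class"] == "amino_acid"
        assert ala.spectrum.mz.tolist() == [44.0495, 72.0444, 90.0549]
        assert ser.compound_name == "Serine"
        assert ser.spectrum.intensity.tolist() == [100.0, 22.0]  # semicolon sep

    def test_num_peaks_mismatch_skips_record_only(self, tmp_path):
        bad = "Name: Broken\nPRECURSORMZ: 100.0\nNum Peaks: 3\n50.0 1.0\n60.0 2.0\n\n"
        path = tmp_path / "lib.msp"
        path.write_text(bad + MSP_FIXTURE)
        with pytest.warns(UserWarning, match="Broken"):
            lib = read_msp(path)
        assert [e.compound_name for e in lib] == ["Alanine", "Serine"]

    def test_missing_precursor_flagged_unsearchable(self, tmp_path):
        path = tmp_path / "lib.msp"
        path.write_text("Name: NoPrec\nNum Peaks: 1\n100.0 1.0\n")
        lib = read_msp(path)
        assert len(lib) == 1
        assert not lib.entries[0].searchable
        assert lib.query_precursor_window(0.0, 1e6) == []

    def test_roundtrip_lossless(self, tmp_path):
        rng = np.random.default_rng(3)
        entries = [
            entry(
                name=f"cmpd_{i}",
                precursor=float(rng.uniform(100, 1000)),
                peaks=[
                    (float(m), float(rng.uniform(1, 100)))
                    for m in np.sort(rng.uniform(50, 900, 8))
                ],
            )
            for i in range(5)
        ]
        lib = SpectralLibrary("rt", entries)
        p1, p2 = tmp_path / "a.msp", tmp_path / "b.msp"
        write_msp(lib, p1)
        lib2 = read_msp(p1)
        write_msp(lib2, p2)
        lib3 = read_msp(p2)
        for a, b in zip(lib.entries, lib3.entries):
            assert a.compound_name == b.compound_name
            assert a.adduct == b.adduct
            np.testing.assert_allclose(b.precursor_mz, a.precursor_mz, rtol=1e-6)
            np.testing.assert_allclose(b.spectrum.mz, a.spectrum.mz, rtol=1e-6)
            np.testing.assert_allclose(b.spectrum.intensity, a.spectrum.intensity, rtol=1e-6)

    def test_empty_library_roundtrip(self, tmp_path):
        path = tmp_path / "empty.msp"
        write_msp(SpectralLibrary("empty", []), path)
        assert len(read_msp(path)) == 0

    def test_single_peak_num_peaks_line(self, tmp_path):
        path = tmp_path / "one.msp"
        write_msp(SpectralLibrary("one", [entry(peaks=[(100.0, 1.0)])]), path)
        assert "Num Peaks: 1" in path.read_text()


class TestSqlite:
    def test_roundtrip_equality(self, tmp_path):
        lib = SpectralLibrary("sq", [entry("A", 400.0), entry("B", 600.0)])
        db = tmp_path / "lib.db"
        library_to_sqlite(lib, db)
        loaded = load_library_sqlite(db)
        assert loaded.name == "sq"
        for a, b in zip(lib.entries, loaded.entries):
            assert a.compound_name == b.compound_name
            assert a.precursor_mz == b.precursor_mz
            assert a.metadata == b.metadata
            assert a.spectrum == b.spectrum

    def test_empty_library(self, tmp_path):
        db = tmp_path / "empty.db"
        library_to_sqlite(SpectralLibrary("e", []), db)
        assert len(load_library_sqlite(db)) == 0

    def test_schema_version_mismatch_raises(self, tmp_path):
        import sqlite3

        db = tmp_path / "old.db"
        library_to_sqlite(SpectralLibrary("v", [entry()]), db)
        con = sqlite3.connect(db)
        con.execute("UPDATE meta SET value='999' WHERE key='schema_version'")
        con.commit()
        con.close()
        with pytest.raises(ValueError, match="schema version"):
            load_library_sqlite(db)


class TestPrecursorIndex:
    def test_window_query_equals_linear_scan(self):
        rng = np.random.default_rng(11)
        entries = [
            entry(f"c{i}", float(rng.uniform(100, 1000))) for i in range(2000)
        ]
        lib = SpectralLibrary("idx", entries)
        for _ in range(300):
            center = rng.uniform(100, 1000)
            half = center * rng.uniform(1, 50) * 1e-6
            got = {e.compound_name for e in lib.query_precursor_window(center - half, center + half)}
            want = {
                e.compound_name
                for e in entries
                if center - half <= e.precursor_mz <= center + half
            }
            assert got == want


class TestMzml:
    def test_roundtrip_preserves_scans(self, tmp_path, synthetic_run):
        sample = "sample_1"
        orig = synthetic_run.scans_by_sample[sample][:50]
        path = tmp_path / "run.mzML"
        write_mzml(orig, path)
        scans = read_mzml(path)
        assert len(scans) == len(orig)
        for a, b in zip(scans, orig):
            assert a.ms_level == b.ms_level
            assert a.rt == pytest.approx(b.rt, abs=1e-9)
            np.testing.assert_array_equal(a.spectrum.mz, b.spectrum.mz)
            np.testing.assert_array_equal(a.spectrum.intensity, b.spectrum.intensity)
            if b.ms_level == 2:
                assert a.precursor_mz == pytest.approx(b.precursor_mz)

    def test_ms1_only_file(self, tmp_path):
        scans = [
            Scan(1, 1, 0.5, +1, Spectrum(np.array([100.0]), np.array([5.0]))),
            Scan(2, 1, 1.0, +1, Spectrum(np.array([]), np.array([]))),
        ]
        path = tmp_path / "ms1.mzML"
        write_mzml(scans, path)
        out = read_mzml(path)
        assert [s.ms_level for s in out] == [1, 1]
        assert len(out[1].spectrum) == 0

    def test_empty_ms2_spectrum_retained(self, tmp_path):
        scans = [
            Scan(1, 2, 0.5, +1, Spectrum(np.array([]), np.array([])),
                 precursor_mz=500.0, precursor_isolation_width=1.0),
        ]
        path = tmp_path / "e.mzML"
        write_mzml(scans, path)
        out = read_mzml(path)
        assert out[0].ms_level == 2
        assert out[0].precursor_mz == pytest.approx(500.0)
        assert len(out[0].spectrum) == 0

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_mzml(tmp_path / "absent.mzML")


class TestCsvLibrary:
    def test_one_row_per_peak_dialect(self, tmp_path):
        path = tmp_path / "lib.csv"
        path.write_text(
            "compound,precursor_mz,adduct,mz,intensity\n"
            "X,500.0,[M+H]+,100.0,50.0\n"
            "X,500.0,[M+H]+,200.0,100.0\n"
            "Y,600.0,[M+Na]+,150.0,80.0\n"
        )
        lib = read_csv_library(path)
        assert len(lib) == 2
        x = lib.entries[0]
        assert x.compound_name == "X"
        assert x.spectrum.mz.tolist() == [100.0, 200.0]

    def test_missing_columns_raise(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("compound,mz\nX,100\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_csv_library(path)
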