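import numpy as np
import pandas as pd
import pytest

from oxiraman.exceptions import (
    ManifestError,
    SpectrumParseError,
    SpectrumValidationError,
)
from oxiraman.spectra import (
    DatasetManifest,
    ManifestEntry,
    Spectrum,
    load_manifest,
    read_spectrum,
    save_manifest,
    write_spectrum,
)
from oxiraman.synthetic import SyntheticDatasetSpec, generate_mixture_series, generate_pure_spectrum


class TestReadSpectrum:
    def test_reads_two_point_file(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("1000,0.1\n1001,0.2\n")
        s = read_spectrum(p)
        assert len(s) == 2
        assert np.all(np.diff(s.wavenumbers) > 0)
        np.testing.assert_allclose(s.intensities, [0.1, 0.2])

    def test_row_order_invariance(self, tmp_path):
        asc = tmp_path / "asc.txt"
        desc = tmp_path / "desc.txt"
        asc.write_text("1000 0.1\n1001 0.2\n1002 0.4\n")
        desc.write_text("1002 0.4\n1001 0.2\n1000 0.1\n")
        a, d = read_spectrum(asc), read_spectrum(desc)
        np.testing.assert_array_equal(a.wavenumbers, d.wavenumbers)
        np.testing.assert_array_equal(a.intensities, d.intensities)

    def test_comment_lines_ignored(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("# a comment\n1000 0.1\n# mid comment\n1001 0.2\n")
        assert len(read_spectrum(p)) == 2

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1000 0.1\n1001 spam\n")
        with pytest.raises(SpectrumParseError, match=":2:"):
            read_spectrum(p)

    def test_single_column_row_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1000 0.1\n1001\n")
        with pytest.raises(SpectrumParseError, match=":2:"):
            read_spectrum(p)

    def test_duplicate_wavenumber_rejected(self, tmp_path):
        p = tmp_path / "dup.txt"
        p.write_text("1000 0.1\n1000 0.2\n1001 0.3\n")
        with pytest.raises(SpectrumValidationError, match="duplicate"):
            read_spectrum(p)

    def test_non_finite_rejected(self, tmp_path):
        p = tmp_path / "nan.txt"
        p.write_text("1000 0.1\n1001 nan\n")
        with pytest.raises(SpectrumValidationError, match="non-finite"):
            read_spectrum(p)

    def test_too_short_rejected(self, tmp_path):
        p = tmp_path / "short.txt"
        p.write_text("1000 0.1\n")
        with pytest.raises(SpectrumValidationError, match="fewer than 2"):
            read_spectrum(p)


class TestSpectrumInvariants:
    def test_region_requires_min_points(self):
        with pytest.raises(SpectrumValidationError, match=">= 8 points"):
            Spectrum(np.array([10.0, 50.0]), np.array([1.0, 2.0]), region="thz")

    @pytest.mark.parametrize(
        "region, lo, hi",
        [("thz", 120.0, 300.0), ("fingerprint", 1000.0, 1500.0), ("sers", 500.0, 1600.0)],
    )
    def test_region_coverage_enforced(self, region, lo, hi):
        wn = np.linspace(lo, hi, 50)
        with pytest.raises(SpectrumValidationError):
            Spectrum(wn, np.ones(50), region=region)

    def test_fraction_bounds(self):
        wn = np.linspace(1.0, 2.0, 10)
        with pytest.raises(SpectrumValidationError, match="outside"):
            Spectrum(wn, np.ones(10), fraction_pct=150.0)

    def test_decreasing_axis_rejected(self):
        with pytest.raises(SpectrumValidationError, match="strictly increasing"):
            Spectrum(np.array([2.0, 1.0, 3.0]), np.zeros(3))


class TestWriteReadRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_numeric_round_trip_on_generated_spectra(self, tmp_path, seed):
        s = generate_pure_spectrum("dGTP", noise_sd=0.02, seed=seed)
        p = write_spectrum(s, tmp_path / f"s{seed}.txt")
        back = read_spectrum(p)
        np.testing.assert_allclose(back.wavenumbers, s.wavenumbers, atol=1e-4)
        np.testing.assert_allclose(back.intensities, s.intensities, rtol=1e-9, atol=1e-12)

    def test_metadata_round_trip(self, tmp_path):
        wn = np.linspace(10.0, 200.0, 50)
        s = Spectrum(wn, np.ones(50), species="dGTP", fraction_pct=4.0,
                     region="thz", replicate=2, baseline_corrected=True,
                     normalized="reference")
        p = write_spectrum(s, tmp_path / "meta.txt")
        assert "# region: thz" in p.read_text()
        back = read_spectrum(p)
        assert back.species == "dGTP"
        assert back.fraction_pct == 4.0
        assert back.region == "thz"
        assert back.replicate == 2
        assert back.baseline_corrected is True
        assert back.normalized == "reference"

    def test_rewrite_is_byte_stable(self, tmp_path):
        s = generate_pure_spectrum("dGTP", noise_sd=0.01, seed=3)
        p1 = write_spectrum(s, tmp_path / "a.txt")
        p2 = write_spectrum(read_spectrum(p1), tmp_path / "b.txt")
        assert p1.read_text() == p2.read_text()


class TestManifest:
    @pytest.fixture
    def written_series(self, tmp_path):
        spec = SyntheticDatasetSpec(seed=1)
        return generate_mixture_series(spec, out_dir=tmp_path), tmp_path

    def test_default_series_has_18_entries(self, written_series):
        (manifest, spectra), tmp_path = written_series
        assert len(manifest) == 18  # 6 fractions x 3 replicates
        assert len(spectra) == 18
        loaded = load_manifest(tmp_path / "manifest.csv")
        assert len(loaded) == 18
        for e in loaded:
            assert e.path.exists()

    def test_round_trip_preserves_entries(self, written_series, tmp_path):
        (manifest, _), src = written_series
        loaded = load_manifest(src / "manifest.csv")
        save_manifest(loaded, src / "again.csv")
        again = load_manifest(src / "again.csv")
        assert {(e.path, e.species, e.fraction_pct, e.replicate) for e in again} == {
            (e.path, e.species, e.fraction_pct, e.replicate) for e in loaded
        }

    def test_fraction_out_of_bounds_rejected(self, tmp_path):
        f = tmp_path / "f.txt"
        f.write_text("1 1\n2 2\n")
        pd.DataFrame(
            [{"path": "f.txt", "species": "x", "fraction_pct": 150, "replicate": 1}]
        ).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ManifestError, match="outside"):
            load_manifest(tmp_path / "m.csv")

    def test_missing_referenced_file_listed(self, tmp_path):
        pd.DataFrame(
            [{"path": "nope.txt", "species": "x", "fraction_pct": 1, "replicate": 1}]
        ).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ManifestError, match="nope.txt"):
            load_manifest(tmp_path / "m.csv")

    def test_duplicate_paths_rejected(self, tmp_path):
        e = ManifestEntry(path=tmp_path / "a.txt", species="x", fraction_pct=1.0)
        with pytest.raises(ManifestError, match="duplicate"):
            DatasetManifest(entries=(e, e))
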