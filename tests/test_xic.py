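"""Run reading, XIC extraction, and peak integration."""

import base64
import struct
import zlib

import numpy as np
import pytest

from acylswath import (
    AcylPeptide,
    Chromatogram,
    SpectrumRun,
    extract_xic,
    integrate_peak,
    ms1_isotope_areas,
    read_run,
    write_mzml,
)
from acylswath.xic import Scan


def make_run(scans):
    return SpectrumRun(scans)


def flat_ms1_run(mz_peaks, rts):
    scans = []
    for t in rts:
        mz = np.array([m for m, _ in mz_peaks])
        inten = np.array([v for _, v in mz_peaks])
        scans.append(Scan(1, t, mz, inten))
    return make_run(scans)


class TestReadRun:
    def test_mzml_roundtrip_preserves_scans(self, tmp_path, rng):
        scans = []
        for i in range(6):
            mz = np.sort(rng.uniform(400, 1200, 25))
            inten = rng.uniform(10, 1e5, 25)
            level = 1 if i % 3 == 0 else 2
            iso = (500.0, 525.0) if level == 2 else None
            scans.append(Scan(level, 0.05 * i, mz, inten, 0 if level == 2 else None, iso))
        path = tmp_path / "r.mzML"
        write_mzml(path, scans)
        run = read_run(path)
        assert len(run.scans) == len(scans)
        for orig, back in zip(scans, run.scans):
            assert back.ms_level == orig.ms_level
            assert back.rt == pytest.approx(orig.rt, abs=1e-6)
            np.testing.assert_allclose(back.mz, orig.mz)
            np.testing.assert_allclose(back.intensity, orig.intensity)

    def test_simulator_bundle_roundtrip(self, single_site_bundle, loaded_single):
        run, scheme, _ = loaded_single
        truth = single_site_bundle.truth
        ms1 = run.select(1)
        assert len(ms1) == len(truth["cycle_rt_min"])
        np.testing.assert_allclose(
            [s.rt for s in ms1], truth["cycle_rt_min"], atol=1e-5
        )
        assert run.ms2_windows == sorted(
            {sp["window"] for sp in truth["peptides"][0]["species"]}
        )

    def test_ms1_only_run_gives_empty_ms2(self, tmp_path):
        path = tmp_path / "ms1.mzML"
        write_mzml(path, [Scan(1, 0.1, np.array([500.0]), np.array([10.0]))])
        run = read_run(path)
        assert run.select(2, 0) == []

    def test_truncated_file_is_format_error(self, tmp_path):
        good = tmp_path / "g.mzML"
        write_mzml(good, [Scan(1, 0.1, np.array([500.0]), np.array([10.0]))])
        bad = tmp_path / "bad.mzML"
        bad.write_text(good.read_text()[: len(good.read_text()) // 2])
        with pytest.raises(ValueError, match="could not parse"):
            read_run(bad)

    def test_minimal_mzxml_accepted(self, tmp_path):
        pairs = struct.pack(">4f", 500.0, 1000.0, 600.0, 2000.0)
        peaks = base64.b64encode(pairs).decode()
        xml = f"""<?xml version="1.0"?>
<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">
 <msRun scanCount="2">
  <scan num="1" msLevel="1" retentionTime="PT60.0S" peaksCount="2">
   <peaks precision="32" byteOrder="network" compressionType="none">{peaks}</peaks>
  </scan>
  <scan num="2" msLevel="2" retentionTime="PT61.0S" peaksCount="2">
   <precursorMz windowWideness="25.0">512.5</precursorMz>
   <peaks precision="32" byteOrder="network" compressionType="none">{peaks}</peaks>
  </scan>
 </msRun>
</mzXML>"""
        p = tmp_path / "r.mzXML"
        p.write_text(xml)
        run = read_run(p)
        assert [s.ms_level for s in run.scans] == [1, 2]
        assert run.scans[0].rt == pytest.approx(1.0)
        assert run.scans[1].isolation == pytest.approx((500.0, 525.0))
        np.testing.assert_allclose(run.scans[1].mz, [500.0, 600.0])


class TestExtractXic:
    def test_exact_target_reproduced_identically(self):
        run = flat_ms1_run([(500.0, 1234.5)], [0.1, 0.2, 0.3])
        chrom = extract_xic(run, 500.0, 20.0, (0.0, 1.0), level=1)
        np.testing.assert_allclose(chrom.intensity, [1234.5] * 3)

    def test_absent_target_gives_zero_chromatogram(self):
        run = flat_ms1_run([(500.0, 10.0)], [0.1, 0.2])
        chrom = extract_xic(run, 900.0, 20.0, (0.0, 1.0), level=1)
        assert chrom.intensity.sum() == 0

    def test_peaks_at_twice_tolerance_excluded(self):
        target, ppm = 600.0, 20.0
        off = target * 2 * ppm * 1e-6
        run = flat_ms1_run([(target - off, 50.0), (target + off, 50.0)], [0.1])
        chrom = extract_xic(run, target, ppm, (0.0, 1.0), level=1)
        assert chrom.intensity.sum() == 0

    def test_narrowing_tolerance_never_increases_signal(self, rng):
        peaks = [(600.0 + d, v) for d, v in zip(rng.normal(0, 0.02, 40), rng.uniform(1, 100, 40))]
        run = flat_ms1_run(peaks, [0.1])
        prev = np.inf
        for ppm in (50.0, 30.0, 20.0, 10.0, 5.0, 1.0):
            total = extract_xic(run, 600.0, ppm, (0.0, 1.0), level=1).intensity.sum()
            assert total <= prev + 1e-9
            prev = total

    def test_empty_rt_range_flagged_not_error(self):
        run = flat_ms1_run([(500.0, 10.0)], [0.1, 0.2])
        chrom = extract_xic(run, 500.0, 20.0, (5.0, 6.0), level=1)
        assert chrom.empty_range and len(chrom.rt) == 0

    def test_ms2_requires_window(self):
        run = flat_ms1_run([(500.0, 10.0)], [0.1])
        with pytest.raises(ValueError, match="window"):
            extract_xic(run, 500.0, level=2)


class TestIntegratePeak:
    def gaussian_chrom(self, amp=1000.0, sd=0.1, apex=5.0):
        rt = np.linspace(apex - 8 * sd, apex + 8 * sd, 161)  # grid contains the apex
        return Chromatogram(500.0, 20.0, rt, amp * np.exp(-((rt - apex) ** 2) / (2 * sd**2)), "MS1")

    def test_flat_zero_chromatogram(self):
        chrom = Chromatogram(500.0, 20.0, np.array([0.1, 0.2, 0.3]), np.zeros(3), "MS1")
        assert integrate_peak(chrom, (0.0, 1.0)).area == 0.0

    def test_gaussian_area_matches_closed_form(self):
        amp, sd = 1000.0, 0.1
        pa = integrate_peak(self.gaussian_chrom(amp, sd), (4.0, 6.0))
        assert pa.area == pytest.approx(amp * sd * np.sqrt(2 * np.pi), rel=0.01)
        assert pa.apex_rt == pytest.approx(5.0, abs=0.01)

    def test_additive_over_disjoint_subintervals(self):
        chrom = self.gaussian_chrom()
        lo, mid, hi = 4.4, 5.0, 5.6
        whole = integrate_peak(chrom, (lo, hi)).area
        left = integrate_peak(chrom, (lo, mid)).area
        right = integrate_peak(chrom, (mid, hi)).area
        assert left + right == pytest.approx(whole, rel=1e-9)

    def test_interference_outside_borders_contributes_nothing(self):
        rt = np.arange(0.0, 10.0, 0.01)
        signal = 100.0 * np.exp(-((rt - 5.0) ** 2) / (2 * 0.1**2))
        interf = 1e6 * np.exp(-((rt - 8.0) ** 2) / (2 * 0.1**2))
        both = Chromatogram(500.0, 20.0, rt, signal + interf, "MS1")
        clean = Chromatogram(500.0, 20.0, rt, signal, "MS1")
        a = integrate_peak(both, (4.0, 6.0)).area
        b = integrate_peak(clean, (4.0, 6.0)).area
        assert a == pytest.approx(b, rel=1e-6)

    def test_single_point_flagged_low_points(self):
        chrom = Chromatogram(500.0, 20.0, np.array([5.0]), np.array([10.0]), "MS1")
        pa = integrate_peak(chrom, (4.9, 5.1))
        assert pa.area == 0.0 and pa.low_points


class TestMs1IsotopeAreas:
    def test_envelope_proportions_recovered(self, loaded_single, single_site_bundle):
        from acylswath.simulate import averagine_envelope

        run, _, target = loaded_single
        truth = single_site_bundle.truth["peptides"][0]
        heavy = target.peptide(["heavy"])
        areas = ms1_isotope_areas(run, heavy, 3, 20.0, tuple(truth["rt_borders"]))
        from acylswath import peptide_mono_mass

        env = averagine_envelope(peptide_mono_mass(heavy))
        ratios = np.array([a.area for a in areas])
        # light-species M+3/M+4 bleed into the heavy channels at 2+ keeps this
        # from being exact even noise-free (no isotope-overlap correction)
        np.testing.assert_allclose(ratios / ratios[0], env[:3] / env[0], rtol=0.01)

    def test_n1_returns_monoisotopic_only(self, loaded_single):
        run, _, target = loaded_single
        areas = ms1_isotope_areas(run, target.peptide(["heavy"]), 1)
        assert len(areas) == 1

    def test_charge2_isotope_spacing(self):
        from acylswath.xic import ISOTOPE_SPACING

        assert ISOTOPE_SPACING / 2 == pytest.approx(0.50168)
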