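"""EIC extraction, peak detection, peak-group formation, MS2 assignment
and consensus spectra, mostly against generator ground truth."""

import numpy as np
import pytest

from specmatch.peak_grouping import (
    EIC,
    GroupingParams,
    assign_ms2,
    build_consensus,
    detect_peaks,
    extract_eics,
    form_peak_groups,
    merge_eics,
    process_slice,
)
from specmatch.pipeline import build_peak_groups
from specmatch.slicing import Slice, build_slices, merge_slices
from specmatch.spectra_io import Scan, Spectrum
from specmatch.synthetic_data import RunConfig, generate_run


def gaussian_scans(center=10.0, sigma=0.05, height=1e6, mz=500.0,
                   rt_lo=9.0, rt_hi=11.0, step=1 / 60):
    scans = []
    for i, rt in enumerate(np.arange(rt_lo, rt_hi, step)):
        inten = height * np.exp(-0.5 * ((rt - center) / sigma) ** 2)
        spectrum = (
            Spectrum(np.array([mz]), np.array([inten]))
            if inten > 1.0
            else Spectrum(np.array([]), np.array([]))
        )
        scans.append(Scan(i + 1, 1, float(rt), +1, spectrum))
    return scans


def one_slice(mz=500.0, rt_lo=9.0, rt_hi=11.0, half_mz=0.01):
    return Slice(mz - half_mz, mz + half_mz, rt_lo, rt_hi, [("a", 1)])


class TestExtractEics:
    def test_planted_gaussian_apex_recovered(self):
        eics = extract_eics(one_slice(), {"a": gaussian_scans()})
        eic = eics[0]
        apex = eic.intensity.max()
        assert apex == pytest.approx(1e6, rel=0.01)
        assert eic.rt[np.argmax(eic.intensity)] == pytest.approx(10.0, abs=1 / 60)

    def test_empty_window_gives_zero_trace(self):
        slice_ = one_slice(mz=800.0)
        eic = extract_eics(slice_, {"a": gaussian_scans()})[0]
        assert np.all(eic.intensity == 0)

    def test_two_centroids_in_window_sum(self):
        scans = [
            Scan(1, 1, 10.0, +1,
                 Spectrum(np.array([499.995, 500.005]), np.array([100.0, 200.0])))
        ]
        eic = extract_eics(one_slice(), {"a": scans})[0]
        assert eic.intensity.tolist() == [300.0]


class TestMergeEics:
    def test_single_eic_identity(self):
        e = EIC("a", np.array([1.0, 2.0]), np.array([5.0, 6.0]))
        merged = merge_eics([e])
        assert merged.rt.tolist() == [1.0, 2.0]
        assert merged.intensity.tolist() == [5.0, 6.0]

    def test_identical_eics_double(self):
        e = EIC("a", np.array([1.0, 2.0]), np.array([5.0, 6.0]))
        merged = merge_eics([e, EIC("b", e.rt, e.intensity)])
        assert merged.intensity.tolist() == [10.0, 12.0]

    def test_disjoint_grids_concatenate(self):
        a = EIC("a", np.array([1.0]), np.array([5.0]))
        b = EIC("b", np.array([2.0]), np.array([7.0]))
        merged = merge_eics([a, b])
        assert merged.rt.tolist() == [1.0, 2.0]
        assert merged.intensity.tolist() == [5.0, 7.0]


class TestDetectPeaks:
    def test_single_gaussian_one_peak(self):
        eic = extract_eics(one_slice(), {"a": gaussian_scans()})[0]
        peaks = detect_peaks(eic, 5, 1e4)
        assert len(peaks) == 1
        apex, start, end = peaks[0]
        assert apex == pytest.approx(10.0, abs=2 / 60)
        assert start < apex < end

    def test_flat_zero_trace_no_peaks(self):
        eic = EIC("a", np.linspace(0, 1, 30), np.zeros(30))
        assert detect_peaks(eic, 5, 0.0) == []

    def test_two_separated_gaussians_two_peaks(self):
        rts = np.arange(9.0, 11.0, 1 / 60)
        trace = 1e6 * np.exp(-0.5 * ((rts - 9.5) / 0.05) ** 2)
        trace += 8e5 * np.exp(-0.5 * ((rts - 10.5) / 0.05) ** 2)
        peaks = detect_peaks(EIC("a", rts, trace), 5, 1e4)
        assert len(peaks) == 2
        (a1, _, e1), (a2, s2, _) = peaks
        assert a1 == pytest.approx(9.5, abs=2 / 60)
        assert a2 == pytest.approx(10.5, abs=2 / 60)
        assert e1 <= s2 or e1 < a2  # boundary between the apexes

    def test_window_longer_than_trace_raises(self):
        eic = EIC("a", np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            detect_peaks(eic, 5, 0.0)

    def test_even_window_rejected(self):
        eic = EIC("a", np.linspace(0, 1, 30), np.zeros(30))
        with pytest.raises(ValueError):
            detect_peaks(eic, 4, 0.0)


class TestFormPeakGroups:
    def test_same_compound_three_samples_one_group(self):
        scans = {
            s: gaussian_scans(center=10.0 + d)
            for s, d in [("s1", 0.0), ("s2", 0.05), ("s3", -0.05)]
        }
        groups = form_peak_groups(one_slice(), extract_eics(one_slice(), scans))
        assert len(groups) == 1
        assert sorted(p.sample_id for p in groups[0].peaks) == ["s1", "s2", "s3"]

    def test_distinct_rt_compounds_two_groups(self):
        scans = {
            "A": gaussian_scans(center=5.0, rt_lo=4.0, rt_hi=16.0),
            "B": gaussian_scans(center=15.0, rt_lo=4.0, rt_hi=16.0),
        }
        slice_ = one_slice(rt_lo=4.0, rt_hi=16.0)
        groups = form_peak_groups(slice_, extract_eics(slice_, scans))
        assert len(groups) == 2
        assert [len(g.peaks) for g in groups] == [1, 1]
        assert {g.peaks[0].sample_id for g in groups} == {"A", "B"}

    def test_empty_eics_no_groups(self):
        assert form_peak_groups(one_slice(), [EIC("a", np.array([]), np.array([]))]) == []

    def test_group_window_inside_slice(self, synthetic_run):
        groups = build_peak_groups(synthetic_run.scans_by_sample)
        for g in groups:
            assert g.slice.rt_min <= g.rt_start <= g.rt_end <= g.slice.rt_max


class TestAssignMs2:
    def _group_at(self, rt, slice_):
        from specmatch.peak_grouping import Peak, PeakGroup

        return PeakGroup(
            slice=slice_, rt_apex=rt, rt_start=rt - 0.1, rt_end=rt + 0.1,
            peaks=[Peak("a", rt, rt - 0.1, rt + 0.1, 1e6, 1e5)],
        )

    def _ms2(self, scan_id, rt):
        return Scan(scan_id, 2, rt, +1,
                    Spectrum(np.array([100.0]), np.array([1.0])), precursor_mz=500.0)

    def test_scans_within_tolerance_assigned(self):
        slice_ = Slice(499.99, 500.01, 9.0, 11.0, [("a", 1), ("a", 2)])
        scans = {"a": [self._ms2(1, 9.9), self._ms2(2, 10.1)]}
        groups = assign_ms2([self._group_at(10.0, slice_)], slice_, scans, 0.5)
        assert groups[0].ms2_scans == [("a", 1), ("a", 2)]

    def test_scan_beyond_tolerance_unassigned(self):
        slice_ = Slice(499.99, 500.01, 9.0, 13.0, [("a", 1)])
        scans = {"a": [self._ms2(1, 12.0)]}
        groups = assign_ms2([self._group_at(10.0, slice_)], slice_, scans, 0.5)
        assert groups[0].ms2_scans == []

    def test_nearest_group_wins(self):
        slice_ = Slice(499.99, 500.01, 9.0, 11.0, [("a", 1)])
        scans = {"a": [self._ms2(1, 10.19)]}
        g1, g2 = self._group_at(10.0, slice_), self._group_at(10.4, slice_)
        assign_ms2([g1, g2], slice_, scans, 0.5)
        assert g1.ms2_scans == [("a", 1)]
        assert g2.ms2_scans == []

    def test_each_seed_assigned_at_most_once(self, synthetic_run):
        scans = synthetic_run.scans_by_sample
        slices = merge_slices(build_slices(scans))
        for slice_ in slices:
            groups = process_slice(slice_, scans)
            assigned = [key for g in groups for key in g.ms2_scans]
            assert len(assigned) == len(set(assigned))
            assert set(assigned) <= set(slice_.seed_scan_ids)


class TestBuildConsensus:
    def test_single_spectrum_identity(self):
        s = Spectrum(np.array([100.0, 200.0]), np.array([10.0, 50.0]))
        assert build_consensus([s]) == s

    def test_identical_copies_reproduce_spectrum(self):
        s = Spectrum(np.array([100.0, 200.0, 300.0]), np.array([10.0, 50.0, 25.0]))
        for n in (2, 3, 7):
            consensus = build_consensus([s] * n)
            np.testing.assert_allclose(consensus.mz, s.mz)
            np.testing.assert_allclose(consensus.intensity, s.intensity)

    def test_nearby_fragments_weighted_mean(self):
        a = Spectrum(np.array([100.0000]), np.array([50.0]))
        b = Spectrum(np.array([100.0005]), np.array([50.0]))
        consensus = build_consensus([a, b], fragment_tol_ppm=20)
        assert len(consensus) == 1
        assert consensus.mz[0] == pytest.approx(100.00025)
        assert consensus.intensity[0] == pytest.approx(50.0)

    def test_min_presence_fraction_drops_rare_fragments(self):
        common = Spectrum(np.array([100.0]), np.array([50.0]))
        rare = Spectrum(np.array([100.0, 300.0]), np.array([50.0, 99.0]))
        consensus = build_consensus([common, common, rare], min_presence_fraction=0.5)
        assert consensus.mz.tolist() == [100.0]

    def test_all_empty_spectra_empty_consensus(self):
        empty = Spectrum(np.array([]), np.array([]))
        assert len(build_consensus([empty, empty])) == 0


class TestSyntheticRecovery:
    def test_planted_compounds_grouped_with_ms2(self, synthetic_run):
        """>= 95% of planted compounds give exactly one annotatable group."""
        groups = build_peak_groups(synthetic_run.scans_by_sample)
        hits = {}
        for g in groups:
            if not g.annotatable:
                continue
            for comp in synthetic_run.compounds:
                if (
                    g.slice.mz_min <= comp.precursor_mz <= g.slice.mz_max
                    and abs(g.rt_apex - comp.rt_true) < 0.2
                ):
                    hits.setdefault(comp.name, []).append(g)
        n = len(synthetic_run.compounds)
        exactly_one = sum(1 for v in hits.values() if len(v) == 1)
        assert len(hits) >= 0.95 * n
        assert exactly_one >= 0.95 * n
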