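"""EIC extraction, peak detection, cross-sample peak groups, MS2
assignment and consensus spectra.

For every merged slice, each sample's MS1 scans inside the slice RT range
are reduced to an extracted ion chromatogram (EIC) over the slice m/z
window. Per-sample EICs are summed into a merged EIC whose peaks define
peak groups; each sample's own peaks are then attached to the group whose
RT window contains their apex, the slice's seed MS2 scans are assigned to
groups by RT proximity, and the assigned MS2 spectra are combined into
one consensus spectrum per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from specmatch.slicing import Slice
from specmatch.spectra_io import Scan, Spectrum

DEFAULT_SMOOTHING_WINDOW = 5
DEFAULT_MIN_HEIGHT = 1e4
DEFAULT_RT_TOLERANCE_MIN = 0.5
DEFAULT_FRAGMENT_TOL_PPM = 20.0
DEFAULT_MIN_PRESENCE_FRACTION = 0.0


@dataclass
class GroupingParams:
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW
    min_height: float = DEFAULT_MIN_HEIGHT
    rt_tolerance_min: float = DEFAULT_RT_TOLERANCE_MIN
    fragment_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM
    min_presence_fraction: float = DEFAULT_MIN_PRESENCE_FRACTION


@dataclass
class EIC:
    """Intensity-vs-RT trace of one sample inside a slice's m/z window."""

    sample_id: str
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")
        if self.rt.size > 1 and np.any(np.diff(self.rt) < 0):
            raise ValueError("rt must be ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class Peak:
    """A chromatographic peak picked from one sample's EIC."""

    sample_id: str
    rt_apex: float
    rt_start: float
    rt_end: float
    height: float
    area: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rt_start <= self.rt_apex <= self.rt_end:
            raise ValueError("require rt_start <= rt_apex <= rt_end")
        if self.height <= 0:
            raise ValueError("peak height must be positive")


@dataclass
class PeakGroup:
    """Cross-sample peak set for one eluting species, plus its MS2 evidence."""

    slice: Slice
    rt_apex: float
    rt_start: float
    rt_end: float
    peaks: list[Peak] = field(default_factory=list)
    ms2_scans: list[tuple[str, int]] = field(default_factory=list)
    consensus: Spectrum | None = None

    @property
    def annotatable(self) -> bool:
        """At least one assigned MS2 scan — the annotation requirement."""
        return len(self.ms2_scans) > 0


def extract_eics(slice_: Slice, scans_by_sample: dict[str, list[Scan]]) -> list[EIC]:
    """One EIC per sample: summed MS1 centroid intensity inside the slice
    m/z window, at every MS1 scan time within the slice RT range."""
    eics = []
    for sample_id, scans in scans_by_sample.items():
        rts: list[float] = []
        intens: list[float] = []
        for scan in scans:
            if scan.ms_level != 1 or not slice_.rt_min <= scan.rt <= slice_.rt_max:
                continue
            mz = scan.spectrum.mz
            lo = np.searchsorted(mz, slice_.mz_min, side="left")
            hi = np.searchsorted(mz, slice_.mz_max, side="right")
            rts.append(scan.rt)
            intens.append(float(scan.spectrum.intensity[lo:hi].sum()))
        order = np.argsort(rts, kind="stable")
        eics.append(
            EIC(sample_id, np.asarray(rts)[order] if rts else np.array([]),
                np.asarray(intens)[order] if rts else np.array([]))
        )
    return eics


def merge_eics(eics: list[EIC]) -> EIC:
    """Sum per-sample EICs on the union of their RT grids.

    A sample contributes 0 at RTs where it has no scan; no interpolation
    or resampling is performed.
    """
    if not eics:
        raise ValueError("merge_eics requires at least one EIC")
    grid = np.unique(np.concatenate([e.rt for e in eics]))
    total = np.zeros_like(grid)
    for e in eics:
        if e.rt.size == 0:
            continue
        pos = np.searchsorted(grid, e.rt)
        np.add.at(total, pos, e.intensity)
    return EIC("__merged__", grid, total)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    # reflect-pad so edges keep their local level
    pad = window // 2
    padded = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]]) if pad else x
    return np.convolve(padded, kernel, mode="valid")


def detect_peaks(
    eic: EIC,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
    min_height: float = DEFAULT_MIN_HEIGHT,
) -> list[tuple[float, float, float]]:
    """Pick (rt_apex, rt_start, rt_end) peaks from a single EIC.

    The trace is smoothed with a centered moving average; apexes are
    strict local maxima of the smoothed trace above ``min_height``
    (plateaus take their leftmost point); boundaries extend from each
    apex to the nearest local minimum of the smoothed trace, or to the
    first zero, on each side. Peaks come out sorted by apex RT.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be an odd positive integer")
    n = eic.rt.size
    if n == 0:
        return []
    if smoothing_window > n:
        raise ValueError(
            f"smoothing_window {smoothing_window} longer than trace ({n} points)"
        )
    smooth = _moving_average(eic.intensity, smoothing_window)
    peaks = []
    for i in range(n):
        if smooth[i] < min_height or smooth[i] <= 0:
            continue
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < n - 1 else -np.inf
        if not (smooth[i] > left and smooth[i] >= right):
            continue
        if smooth[i] == right:  # leftmost point of a plateau only
            j = i
            while j < n - 1 and smooth[j + 1] == smooth[i]:
                j += 1
            if j < n - 1 and smooth[j + 1] > smooth[i]:
                continue
        lo = i
        while lo > 0 and smooth[lo - 1] < smooth[lo] and smooth[lo - 1] > 0:
            lo -= 1
        hi = i
        while hi < n - 1 and smooth[hi + 1] < smooth[hi] and smooth[hi + 1] > 0:
            hi += 1
        peaks.append((i, lo, hi))
    out = []
    seen_apex: set[int] = set()
    for i, lo, hi in peaks:
        if i in seen_apex:
            continue
        seen_apex.add(i)
        out.append((float(eic.rt[i]), float(eic.rt[lo]), float(eic.rt[hi])))
    out.sort()
    return out


def _largest_odd(n: int) -> int:
    return n if n % 2 else n - 1


def _raw_peak_stats(eic: EIC, rt_start: float, rt_end: float) -> tuple[float, float, float]:
    """Apex RT, height and trapezoidal area of the raw trace in a window."""
    mask = (eic.rt >= rt_start) & (eic.rt <= rt_end)
    rts, ys = eic.rt[mask], eic.intensity[mask]
    apex = int(np.argmax(ys))
    area = float(np.trapezoid(ys, rts)) if rts.size > 1 else 0.0
    return float(rts[apex]), float(ys[apex]), area


def form_peak_groups(
    slice_: Slice, eics: list[EIC], params: GroupingParams | None = None
) -> list[PeakGroup]:
    """Build one peak group per merged-EIC peak and attach sample peaks.

    Each sample's own EIC peaks are assigned to the group whose RT window
    contains the sample peak apex; an apex inside no window goes to the
    group with the nearest window edge (tie: earlier group). Groups that
    collect no sample peak are dropped.
    """
    params = params or GroupingParams()
    non_empty = [e for e in eics if e.rt.size]
    if not non_empty:
        return []
    merged = merge_eics(non_empty)
    window = min(params.smoothing_window, _largest_odd(merged.rt.size))
    merged_peaks = detect_peaks(merged, window, params.min_height)
    if not merged_peaks:
        return []
    groups = [
        PeakGroup(slice=slice_, rt_apex=apex, rt_start=start, rt_end=end)
        for apex, start, end in merged_peaks
    ]
    for eic in non_empty:
        w = min(params.smoothing_window, _largest_odd(eic.rt.size))
        if w < 1:
            continue
        for apex, start, end in detect_peaks(eic, w, params.min_height):
            rt_apex, height, area = _raw_peak_stats(eic, start, end)
            peak = Peak(eic.sample_id, rt_apex, start, end, height, area)
            gi = _nearest_group(groups, peak.rt_apex)
            groups[gi].peaks.append(peak)
    return [g for g in groups if g.peaks]


def _nearest_group(groups: list[PeakGroup], rt: float) -> int:
    best, best_dist = 0, np.inf
    for i, g in enumerate(groups):
        if g.rt_start <= rt <= g.rt_end:
            dist = 0.0
        else:
            dist = min(abs(rt - g.rt_start), abs(rt - g.rt_end))
        if dist < best_dist:
            best, best_dist = i, dist
    return best


def assign_ms2(
    groups: list[PeakGroup],
    slice_: Slice,
    scans_by_sample: dict[str, list[Scan]],
    rt_tolerance_min: float = DEFAULT_RT_TOLERANCE_MIN,
) -> list[PeakGroup]:
    """Assign each seed MS2 scan of the slice to the group with the
    nearest apex RT, if within ``rt_tolerance_min``; at most one group
    per scan. Returns the same group list, mutated."""
    if not groups:
        return groups
    scan_lookup = {
        (sid, sc.scan_id): sc for sid, scans in scans_by_sample.items() for sc in scans
    }
    for seed in slice_.seed_scan_ids:
        scan = scan_lookup.get(seed)
        if scan is None:
            continue
        dists = [abs(g.rt_apex - scan.rt) for g in groups]
        gi = int(np.argmin(dists))
        if dists[gi] <= rt_tolerance_min:
            groups[gi].ms2_scans.append(seed)
    return groups


def build_consensus(
    ms2_spectra: list[Spectrum],
    fragment_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    min_presence_fraction: float = DEFAULT_MIN_PRESENCE_FRACTION,
) -> Spectrum:
    """Combine MS2 spectra of one group into a consensus spectrum.

    Fragments from all scans are clustered greedily: seeds are taken in
    descending intensity order and absorb all still-unclustered fragments
    within the ppm window. Each cluster becomes one consensus peak at the
    intensity-weighted mean m/z with the mean intensity (averaged over
    contributing scans). Clusters present in fewer than
    ``min_presence_fraction`` of the scans are dropped unless there is
    only one scan.
    """
    if not ms2_spectra:
        raise ValueError("build_consensus requires at least one spectrum")
    n_scans = len(ms2_spectra)
    frags: list[tuple[float, float, int]] = []  # (mz, intensity, scan index)
    for s_idx, spec in enumerate(ms2_spectra):
        for mz, inten in zip(spec.mz, spec.intensity):
            frags.append((float(mz), float(inten), s_idx))
    if not frags:
        return Spectrum(np.array([]), np.array([]))
    order = sorted(range(len(frags)), key=lambda i: (-frags[i][1], frags[i][0]))
    mz_sorted = sorted(range(len(frags)), key=lambda i: frags[i][0])
    mz_values = [frags[i][0] for i in mz_sorted]
    clustered = [False] * len(frags)
    peaks: list[tuple[float, float]] = []
    from bisect import bisect_left, bisect_right

    for seed in order:
        if clustered[seed]:
            continue
        seed_mz = frags[seed][0]
        half = seed_mz * fragment_tol_ppm * 1e-6
        lo = bisect_left(mz_values, seed_mz - half)
        hi = bisect_right(mz_values, seed_mz + half)
        members = [mz_sorted[i] for i in range(lo, hi) if not clustered[mz_sorted[i]]]
        for i in members:
            clustered[i] = True
        scans_present = {frags[i][2] for i in members}
        if n_scans > 1 and len(scans_present) / n_scans < min_presence_fraction:
            continue
        weight = sum(frags[i][1] for i in members)
        if weight > 0:
            mean_mz = sum(frags[i][0] * frags[i][1] for i in members) / weight
        else:
            mean_mz = sum(frags[i][0] for i in members) / len(members)
        mean_inten = weight / n_scans
        peaks.append((mean_mz, mean_inten))
    return Spectrum.from_peaks(peaks)


def process_slice(
    slice_: Slice,
    scans_by_sample: dict[str, list[Scan]],
    params: GroupingParams | None = None,
    discard_unannotated: bool = False,
) -> list[PeakGroup]:
    """Full per-slice pipeline: EICs -> groups -> MS2 assignment -> consensus."""
    params = params or GroupingParams()
    eics = extract_eics(slice_, scans_by_sample)
    groups = form_peak_groups(slice_, eics, params)
    groups = assign_ms2(groups, slice_, scans_by_sample, params.rt_tolerance_min)
    scan_lookup = {
        (sid, sc.scan_id): sc for sid, scans in scans_by_sample.items() for sc in scans
    }
    for g in groups:
        spectra = [
            scan_lookup[key].spectrum
            for key in g.ms2_scans
            if key in scan_lookup and len(scan_lookup[key].spectrum)
        ]
        if spectra:
            g.consensus = build_consensus(
                spectra, params.fragment_tol_ppm, params.min_presence_fraction
            )
    if discard_unannotated:
        groups = [g for g in groups if g.annotatable]
    return groups
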