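"""MS2-seeded slices of (m/z, RT) space and their progressive merging.

Each MS2 event seeds a rectangular slice centered on its precursor m/z and
retention time. Slices are then merged — regardless of sample of origin —
whenever they overlap in both the m/z and RT axes, until no two slices
overlap. The merged slices define the search space for peak detection.

Intervals are closed: a shared endpoint counts as overlap, so endpoint
ties merge deterministically. Merged bounds are coordinate-wise unions of
the members; the ppm half-width is frozen at slice creation and never
re-derived after merging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from specmatch.spectra_io import Scan

DEFAULT_MZ_HALF_WIDTH_PPM = 20.0
DEFAULT_RT_HALF_WIDTH_MIN = 0.5


@dataclass
class Slice:
    """An (m/z, RT) rectangle seeded by one or more MS2 scans."""

    mz_min: float
    mz_max: float
    rt_min: float
    rt_max: float
    seed_scan_ids: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValueError("require mz_min < mz_max")
        if not self.rt_min < self.rt_max:
            raise ValueError("require rt_min < rt_max")
        if not self.seed_scan_ids:
            raise ValueError("slice requires at least one seed MS2 scan")

    @property
    def mz_center(self) -> float:
        return 0.5 * (self.mz_min + self.mz_max)

    def overlaps(self, other: "Slice") -> bool:
        """Closed-interval overlap in BOTH axes simultaneously."""
        return (
            self.mz_min <= other.mz_max
            and other.mz_min <= self.mz_max
            and self.rt_min <= other.rt_max
            and other.rt_min <= self.rt_max
        )

    def union(self, other: "Slice") -> "Slice":
        return Slice(
            mz_min=min(self.mz_min, other.mz_min),
            mz_max=max(self.mz_max, other.mz_max),
            rt_min=min(self.rt_min, other.rt_min),
            rt_max=max(self.rt_max, other.rt_max),
            seed_scan_ids=self.seed_scan_ids + other.seed_scan_ids,
        )


def build_slices(
    scans_by_sample: dict[str, list[Scan]],
    mz_half_width_ppm: float = DEFAULT_MZ_HALF_WIDTH_PPM,
    rt_half_width_min: float = DEFAULT_RT_HALF_WIDTH_MIN,
) -> list[Slice]:
    """One slice per MS2 scan, centered at (precursor m/z, scan RT).

    The m/z half-width is ``mz_half_width_ppm`` converted to Th at the
    precursor m/z; the RT half-width is in minutes.
    """
    if mz_half_width_ppm <= 0 or rt_half_width_min <= 0:
        raise ValueError("slice half-widths must be positive")
    slices: list[Slice] = []
    for sample_id, scans in scans_by_sample.items():
        for scan in scans:
            if scan.ms_level != 2:
                continue
            half_mz = scan.precursor_mz * mz_half_width_ppm * 1e-6
            slices.append(
                Slice(
                    mz_min=scan.precursor_mz - half_mz,
                    mz_max=scan.precursor_mz + half_mz,
                    rt_min=max(0.0, scan.rt - rt_half_width_min),
                    rt_max=scan.rt + rt_half_width_min,
                    seed_scan_ids=[(sample_id, scan.scan_id)],
                )
            )
    return slices


def merge_slices(slices: list[Slice]) -> list[Slice]:
    """Merge slices until no two overlap in both m/z and RT.

    Sweep by ascending mz_min with an active set; because a union can
    widen a slice into new overlaps, the sweep is iterated to a fixed
    point. Output bounds are unions of merged members and seed lists are
    concatenated, so the result is independent of input order (as a set
    of bound tuples; seed lists are sorted for determinism).
    """
    current = [
        Slice(s.mz_min, s.mz_max, s.rt_min, s.rt_max, list(s.seed_scan_ids))
        for s in slices
    ]
    changed = True
    while changed:
        changed = False
        current.sort(key=lambda s: (s.mz_min, s.rt_min, s.mz_max, s.rt_max))
        merged: list[Slice] = []
        # active: merged slices whose mz interval may still reach upcoming ones
        active: list[int] = []
        for s in current:
            placed = False
            active = [i for i in active if merged[i].mz_max >= s.mz_min]
            for i in active:
                if merged[i].overlaps(s):
                    merged[i] = merged[i].union(s)
                    changed = True
                    placed = True
                    break
            if not placed:
                merged.append(s)
                active.append(len(merged) - 1)
        current = merged
    for s in current:
        s.seed_scan_ids.sort()
    current.sort(key=lambda s: (s.mz_min, s.rt_min, s.mz_max, s.rt_max))
    return current
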