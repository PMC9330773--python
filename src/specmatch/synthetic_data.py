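"""Seeded synthetic DDA LC-MS/MS runs, libraries and score sets with
known ground truth.

The generator plants compounds from a spectral library as Gaussian
chromatographic peaks, samples MS1 scans on a fixed time grid (precursor
centroids with ppm jitter plus exponential baseline noise peaks), and
fires MS2 scans DDA-style — top-k precursors per MS1 cycle with a
dynamic-exclusion window. With a chimerism rate, a temporally co-eluting
contaminant's fragment spectrum is merged into an MS2 scan, emulating
co-isolation. All randomness flows from one integer seed through a
``numpy.random.default_rng`` generator, so equal seeds give identical
runs on any platform.

What it deliberately does not emulate: isotope envelopes, adduct
co-detection, cross-sample RT drift, detector saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from specmatch.library_compare import ComparisonSet
from specmatch.spectra_io import (
    LibraryEntry,
    Scan,
    SpectralLibrary,
    Spectrum,
    write_mzml,
)

__all__ = [
    "RunConfig",
    "PlantedCompound",
    "SyntheticRun",
    "generate_run",
    "make_decoy_library",
    "generate_comparison_scores",
]


@dataclass
class RunConfig:
    """Study conditions for one synthetic multi-sample DDA experiment."""

    n_samples: int = 3
    n_compounds: int = 20
    rt_min: float = 1.0  # minutes
    rt_max: float = 15.0
    ms1_interval_s: float = 1.0
    dda_top_k: int = 3
    dynamic_exclusion_s: float = 15.0
    peak_sigma_min: float = 0.05
    base_height: float = 1.0e6
    height_decades: float = 0.0  # per-compound log10 spread of peak heights
    baseline_level: float = 500.0  # mean of exponential noise-peak intensity
    noise_peaks_per_scan: int = 5
    ms2_noise_peaks: int = 5  # chemical-noise fragments per MS2 scan
    mz_jitter_ppm: float = 3.0
    intensity_cv: float = 0.1
    chimerism_rate: float = 0.0
    isolation_width: float = 1.0  # Th, recorded on MS2 scans
    min_trigger_height: float = 1.0e4  # precursor intensity needed to fire MS2
    coelution_fraction: float = 0.0  # of own height to count as co-eluting
    polarity: int = +1  # single-polarity acquisition
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.chimerism_rate, self.coelution_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be within [0, 1]")
        if self.n_samples < 1 or self.n_compounds < 1:
            raise ValueError("need at least one sample and one compound")
        if not self.rt_min < self.rt_max:
            raise ValueError("require rt_min < rt_max")


@dataclass
class PlantedCompound:
    """Ground truth for one planted compound."""

    name: str
    precursor_mz: float
    rt_true: float
    sigma_min: float
    height_by_sample: dict[str, float]
    entry: LibraryEntry
    samples: list[str] = field(default_factory=list)


@dataclass
class SyntheticRun:
    """Scans per sample plus the ground-truth table."""

    scans_by_sample: dict[str, list[Scan]]
    compounds: list[PlantedCompound]
    config: RunConfig

    def ground_truth(self) -> pd.DataFrame:
        rows = []
        for comp in self.compounds:
            ms2_counts = {s: 0 for s in comp.samples}
            for sample, scans in self.scans_by_sample.items():
                for scan in scans:
                    if (
                        scan.ms_level == 2
                        and abs(scan.precursor_mz - comp.precursor_mz)
                        / comp.precursor_mz
                        < 50e-6
                        and abs(scan.rt - comp.rt_true) < 4 * comp.sigma_min
                    ):
                        ms2_counts[sample] = ms2_counts.get(sample, 0) + 1
            for sample in comp.samples:
                rows.append(
                    {
                        "compound": comp.name,
                        "precursor_mz": comp.precursor_mz,
                        "rt_true": comp.rt_true,
                        "sample": sample,
                        "height": comp.height_by_sample[sample],
                        "expected_ms2_count": ms2_counts[sample],
                    }
                )
        return pd.DataFrame(rows)

    def write_mzml(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for sample, scans in self.scans_by_sample.items():
            path = out_dir / f"{sample}.mzML"
            write_mzml(scans, path)
            paths.append(path)
        return paths


def _gauss(rt: float, center: float, sigma: float, height: float) -> float:
    return height * float(np.exp(-0.5 * ((rt - center) / sigma) ** 2))


def _jitter_spectrum(
    spectrum: Spectrum, rng: np.random.Generator, ppm: float, cv: float, scale: float
) -> list[tuple[float, float]]:
    peaks = []
    for mz, inten in zip(spectrum.mz, spectrum.intensity):
        jmz = mz * (1.0 + rng.normal(0.0, ppm) * 1e-6)
        jint = max(0.0, inten * scale * (1.0 + rng.normal(0.0, cv)))
        peaks.append((float(jmz), float(jint)))
    return peaks


def generate_run(config: RunConfig, library: SpectralLibrary) -> SyntheticRun:
    """Plant ``config.n_compounds`` library entries into a synthetic run.

    Compounds get distinct retention times (spaced at least 4 sigma apart
    unless the library is too crowded), per-sample heights log-jittered
    by ``intensity_cv``, Gaussian MS1 elution, and DDA-triggered MS2
    scans carrying the library fragment spectrum with ppm jitter. With
    ``chimerism_rate`` > 0, fragments of a co-eluting contaminant are
    merged into MS2 scans at that probability.
    """
    rng = np.random.default_rng(config.seed)
    # one candidate entry per compound name, acquisition polarity only
    searchable, seen = [], set()
    for e in library:
        if (
            e.searchable
            and len(e.spectrum)
            and e.polarity == config.polarity
            and e.compound_name not in seen
        ):
            searchable.append(e)
            seen.add(e.compound_name)
    if len(searchable) < config.n_compounds:
        raise ValueError(
            f"library has {len(searchable)} usable entries, "
            f"need {config.n_compounds}"
        )
    picked_idx = rng.choice(len(searchable), size=config.n_compounds, replace=False)
    samples = [f"sample_{i + 1}" for i in range(config.n_samples)]

    # distinct RTs: jittered positions on a uniform grid across the gradient
    grid = np.linspace(config.rt_min + 0.5, config.rt_max - 0.5, config.n_compounds)
    rts = grid + rng.uniform(-0.2, 0.2, size=config.n_compounds) * (
        grid[1] - grid[0] if config.n_compounds > 1 else 1.0
    )
    compounds = []
    for i, idx in enumerate(picked_idx):
        entry = searchable[int(idx)]
        # compound abundance spans height_decades orders of magnitude;
        # per-sample variation on top of that is the intensity CV
        abundance = config.base_height * 10.0 ** float(
            rng.uniform(-config.height_decades / 2, config.height_decades / 2)
        )
        heights = {
            s: abundance * float(np.exp(rng.normal(0.0, config.intensity_cv)))
            for s in samples
        }
        compounds.append(
            PlantedCompound(
                name=entry.compound_name,
                precursor_mz=float(entry.precursor_mz),
                rt_true=float(rts[i]),
                sigma_min=config.peak_sigma_min,
                height_by_sample=heights,
                entry=entry,
                samples=list(samples),
            )
        )

    interval_min = config.ms1_interval_s / 60.0
    ms1_grid = np.arange(config.rt_min, config.rt_max + 1e-9, interval_min)
    scans_by_sample: dict[str, list[Scan]] = {}
    for sample in samples:
        scans: list[Scan] = []
        scan_id = 0
        exclusion: dict[str, float] = {}  # compound -> last MS2 rt
        for rt in ms1_grid:
            rt = float(rt)
            centroids: list[tuple[float, float]] = []
            eluting: list[tuple[PlantedCompound, float]] = []
            for comp in compounds:
                inten = _gauss(rt, comp.rt_true, comp.sigma_min, comp.height_by_sample[sample])
                if inten < 1.0:
                    continue
                mz = comp.precursor_mz * (
                    1.0 + rng.normal(0.0, config.mz_jitter_ppm) * 1e-6
                )
                centroids.append((float(mz), inten))
                eluting.append((comp, inten))
            for _ in range(config.noise_peaks_per_scan):
                centroids.append(
                    (
                        float(rng.uniform(100.0, 1000.0)),
                        float(rng.exponential(config.baseline_level)),
                    )
                )
            scan_id += 1
            scans.append(
                Scan(
                    scan_id=scan_id,
                    ms_level=1,
                    rt=rt,
                    polarity=config.polarity,
                    spectrum=Spectrum.from_peaks(centroids),
                )
            )
            # DDA cycle: top-k eluting precursors, dynamic exclusion
            eluting.sort(key=lambda pair: -pair[1])
            fired = 0
            for comp, inten in eluting:
                if fired >= config.dda_top_k:
                    break
                if inten < config.min_trigger_height:
                    continue
                last = exclusion.get(comp.name)
                if last is not None and (rt - last) * 60.0 < config.dynamic_exclusion_s:
                    continue
                exclusion[comp.name] = rt
                fired += 1
                ms2_rt = rt + interval_min * fired / (config.dda_top_k + 1)
                peaks = _jitter_spectrum(
                    comp.entry.spectrum,
                    rng,
                    config.mz_jitter_ppm,
                    config.intensity_cv,
                    scale=inten / 100.0,
                )
                # chimeric co-isolation: merge a co-eluting contaminant
                for other, other_inten in eluting:
                    if other is comp:
                        continue
                    if other_inten < config.coelution_fraction * other.height_by_sample[sample]:
                        continue
                    if rng.random() < config.chimerism_rate:
                        peaks += _jitter_spectrum(
                            other.entry.spectrum,
                            rng,
                            config.mz_jitter_ppm,
                            config.intensity_cv,
                            scale=other_inten / 100.0,
                        )
                for _ in range(config.ms2_noise_peaks):
                    peaks.append(
                        (
                            float(rng.uniform(50.0, comp.precursor_mz)),
                            float(rng.exponential(0.05 * inten)),
                        )
                    )
                scan_id += 1
                scans.append(
                    Scan(
                        scan_id=scan_id,
                        ms_level=2,
                        rt=float(ms2_rt),
                        polarity=config.polarity,
                        spectrum=Spectrum.from_peaks(peaks),
                        precursor_mz=comp.precursor_mz,
                        precursor_isolation_width=config.isolation_width,
                    )
                )
        scans_by_sample[sample] = scans
    return SyntheticRun(scans_by_sample, compounds, config)


def make_decoy_library(
    library: SpectralLibrary,
    n_decoys: int,
    seed: int,
    perturb_fraction: float = 0.5,
    name: str | None = None,
) -> SpectralLibrary:
    """Augment a library with decoy entries for precision benchmarks.

    Each decoy copies a real entry's precursor m/z (so it survives
    precursor filtering) but has ``perturb_fraction`` of its fragment m/z
    values shifted by several Da, making it a plausible wrong answer.
    Decoys are named ``DECOY_<i>_<source>``.
    """
    rng = np.random.default_rng(seed)
    pool = [e for e in library if e.searchable and len(e.spectrum) >= 2]
    entries = list(library.entries)
    for i in range(n_decoys):
        src = pool[int(rng.integers(len(pool)))]
        mz = src.spectrum.mz.copy()
        n_shift = max(1, int(round(perturb_fraction * mz.size)))
        which = rng.choice(mz.size, size=n_shift, replace=False)
        mz[which] += rng.uniform(3.0, 30.0, size=n_shift) * rng.choice([-1.0, 1.0], size=n_shift)
        mz = np.abs(mz) + 1.0
        entries.append(
            LibraryEntry(
                compound_name=f"DECOY_{i}_{src.compound_name}",
                precursor_mz=src.precursor_mz,
                adduct=src.adduct,
                polarity=src.polarity,
                spectrum=Spectrum.from_peaks(
                    list(zip(mz.tolist(), src.spectrum.intensity.tolist()))
                ),
                metadata={"decoy": "true"},
            )
        )
    return SpectralLibrary(name or f"{library.name}_with_decoys", entries)


def generate_comparison_scores(
    n_agree: int,
    n_disagree: int,
    agree_dist: tuple[float, float],
    disagree_dist: tuple[float, float],
    seed: int,
    library_name: str = "synthetic",
) -> ComparisonSet:
    """Seeded agreement/disagreement score sets from zero-truncated normals.

    ``agree_dist`` and ``disagree_dist`` are (mean, sd) of normal
    distributions truncated at zero — emulating the unimodal score
    histograms that motivate the Retention Balance Point.
    """
    if n_agree <= 0 or n_disagree <= 0:
        raise ValueError("n_agree and n_disagree must be positive")
    rng = np.random.default_rng(seed)

    def draw(n: int, mean: float, sd: float) -> list[float]:
        a = (0.0 - mean) / sd
        return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng).tolist()

    return ComparisonSet(
        library_name=library_name,
        agreements=draw(n_agree, *agree_dist),
        disagreements=draw(n_disagree, *disagree_dist),
    )
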