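"""End-to-end convenience wrappers: scans -> slices -> peak groups ->
annotations. Thin glue over the slicing, peak_grouping and
library_search modules; the CLI and the test benchmarks both run through
these entry points."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from specmatch.library_search import SearchParams, search_dataset
from specmatch.peak_grouping import GroupingParams, PeakGroup, process_slice
from specmatch.slicing import (
    DEFAULT_MZ_HALF_WIDTH_PPM,
    DEFAULT_RT_HALF_WIDTH_MIN,
    build_slices,
    merge_slices,
)
from specmatch.spectra_io import Scan, SpectralLibrary


@dataclass
class PipelineParams:
    """All knobs of the grouping+search pipeline in one place."""

    mz_half_width_ppm: float = DEFAULT_MZ_HALF_WIDTH_PPM
    rt_half_width_min: float = DEFAULT_RT_HALF_WIDTH_MIN
    grouping: GroupingParams = field(default_factory=GroupingParams)
    search: SearchParams = field(default_factory=SearchParams)
    discard_unannotated_groups: bool = False


def build_peak_groups(
    scans_by_sample: dict[str, list[Scan]],
    params: PipelineParams | None = None,
) -> list[PeakGroup]:
    """MS2-seeded slices, merged, then per-slice peak grouping with MS2
    assignment and consensus spectra."""
    params = params or PipelineParams()
    slices = merge_slices(
        build_slices(
            scans_by_sample, params.mz_half_width_ppm, params.rt_half_width_min
        )
    )
    groups: list[PeakGroup] = []
    for slice_ in slices:
        groups.extend(
            process_slice(
                slice_,
                scans_by_sample,
                params.grouping,
                discard_unannotated=params.discard_unannotated_groups,
            )
        )
    return groups


def annotate_run(
    scans_by_sample: dict[str, list[Scan]],
    libraries: list[SpectralLibrary],
    params: PipelineParams | None = None,
) -> tuple[list[PeakGroup], pd.DataFrame]:
    """Full pipeline: peak groups plus the per-library annotation table."""
    params = params or PipelineParams()
    groups = build_peak_groups(scans_by_sample, params)
    annotatable = [g for g in groups if g.annotatable and g.consensus is not None]
    table = search_dataset(annotatable, libraries, params.search)
    return annotatable, table


def chimeric_precision_benchmark(
    library: SpectralLibrary,
    seed: int,
    chimerism_rate: float = 0.8,
    n_decoys: int = 60,
    n_compounds: int = 20,
    n_samples: int = 3,
    n_unknown: int = 8,
    rt_max: float = 4.0,
) -> dict[str, float]:
    """Precision of the hypergeometric score vs the cosine on a chimeric
    run searched against a decoy-augmented library.

    Generates a DDA run with heavy co-isolation, then removes
    ``n_unknown`` of the planted compounds from the search library —
    their peak groups stand in for background features whose true
    identity is not in the library and can only be annotated wrongly
    (typically by a decoy). Each score type ranks all accepted
    annotations by its own scale; the reported precision is taken at
    the highest recall both scores reach, so the comparison is between
    rankings rather than raw score values.
    """
    from specmatch.library_search import (
        precision_at_recall,
        precision_recall_curve,
    )
    from specmatch.spectra_io import SpectralLibrary as _Library
    from specmatch.synthetic_data import (
        RunConfig,
        generate_run,
        make_decoy_library,
    )

    run = generate_run(
        RunConfig(
            n_compounds=n_compounds,
            n_samples=n_samples,
            chimerism_rate=chimerism_rate,
            height_decades=2.0,
            rt_max=rt_max,  # crowded gradient so co-isolation really occurs
            seed=seed,
        ),
        library,
    )
    import numpy as np

    rng = np.random.default_rng(seed + 1)
    unknown = {
        run.compounds[int(i)].name
        for i in rng.choice(len(run.compounds), size=n_unknown, replace=False)
    }
    reduced = [e for e in library if e.compound_name not in unknown]
    # decoys come from the FULL library: a decoy of a held-out compound is
    # an isobaric wrong species sitting at that feature's precursor m/z
    decoys = [
        e
        for e in make_decoy_library(library, n_decoys, seed=seed + 2)
        if e.metadata.get("decoy")
    ]
    search_lib = _Library(library.name + "_with_decoys", reduced + decoys)
    out: dict[str, float] = {}
    curves = {}
    for score_type in ("hgs", "dot"):
        params = PipelineParams()
        params.search.score_type = score_type
        groups, table = annotate_run(run.scans_by_sample, [search_lib], params)
        truth = match_groups_to_truth(groups, run.ground_truth())
        curves[score_type] = precision_recall_curve(table, truth, search_lib.name)
    matched_recall = min(float(c["recall"].max()) for c in curves.values())
    for score_type, curve in curves.items():
        out[f"{score_type}_precision"] = precision_at_recall(curve, matched_recall)
    out["matched_recall"] = matched_recall
    return out


def match_groups_to_truth(
    groups: list[PeakGroup],
    ground_truth: pd.DataFrame,
    rt_window_min: float = 0.5,
) -> dict[int, tuple[str, float]]:
    """Map group index -> (true compound, true RT) by precursor and RT.

    A group is attributed to the planted compound whose precursor m/z
    falls inside the group's slice window and whose true RT is nearest
    the group apex (within ``rt_window_min``).
    """
    truth = ground_truth.drop_duplicates("compound")
    out: dict[int, tuple[str, float]] = {}
    for gid, group in enumerate(groups):
        best = None
        for _, row in truth.iterrows():
            if not group.slice.mz_min <= row["precursor_mz"] <= group.slice.mz_max:
                continue
            dist = abs(group.rt_apex - row["rt_true"])
            if dist <= rt_window_min and (best is None or dist < best[0]):
                best = (dist, str(row["compound"]), float(row["rt_true"]))
        if best is not None:
            out[gid] = (best[1], best[2])
    return out
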