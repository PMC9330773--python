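"""Precursor-filtered spectral-library search of peak-group consensus
spectra, ranking, annotation tables, and precision evaluation.

Candidates for each peak group are library entries whose precursor m/z
lies within a ppm window of the slice's precursor center (slices are
precursor-centered, so the seed-precursor mean — the slice m/z center —
is compared, not a peak apex m/z) and whose polarity matches. Each
candidate is scored against the consensus spectrum, ranked, and filtered
by a minimum score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from specmatch.peak_grouping import PeakGroup
from specmatch.scoring import ScoringConfig, score_spectra
from specmatch.spectra_io import SpectralLibrary

DEFAULT_PRECURSOR_TOL_PPM = 20.0


@dataclass
class SearchParams:
    """Search-time knobs: tolerances, score type, acceptance threshold."""

    precursor_tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM
    fragment_tol_ppm: float = 20.0
    score_type: str = "hgs"
    min_score: float = 0.0
    N: int = 100_000
    intensity_power: float = 0.5
    polarity: int = +1
    retain_unannotated: bool = True

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")

    def scoring_config(self) -> ScoringConfig:
        return ScoringConfig(
            N=self.N,
            fragment_tol_ppm=self.fragment_tol_ppm,
            score_type=self.score_type,
            intensity_power=self.intensity_power,
        )


@dataclass
class MatchResult:
    """One scored library candidate for one peak group."""

    group: PeakGroup
    library_name: str
    entry_name: str
    adduct: str
    score: float
    k: int
    m: int
    n: int
    rank: int = 0
    entry: object = field(default=None, repr=False)


def search_group(
    group: PeakGroup, library: SpectralLibrary, params: SearchParams
) -> list[MatchResult]:
    """Score all precursor/polarity-compatible entries against the group
    consensus, sorted descending by score (ties: higher k, then compound
    name). Results below ``min_score`` are dropped."""
    if group.consensus is None or len(group.consensus) == 0:
        return []
    center = group.slice.mz_center
    candidates = [
        e
        for e in library.query_precursor_ppm(center, params.precursor_tol_ppm)
        if e.polarity == params.polarity
    ]
    config = params.scoring_config()
    results = []
    for entry in candidates:
        score, matches = score_spectra(group.consensus, entry.spectrum, config)
        if score < params.min_score:
            continue
        results.append(
            MatchResult(
                group=group,
                library_name=library.name,
                entry_name=entry.compound_name,
                adduct=entry.adduct,
                score=score,
                k=matches.k,
                m=matches.m,
                n=matches.n,
                entry=entry,
            )
        )
    results.sort(key=lambda r: (-r.score, -r.k, r.entry_name))
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results


def search_dataset(
    groups: list[PeakGroup],
    libraries: list[SpectralLibrary],
    params: SearchParams,
) -> pd.DataFrame:
    """Annotate every peak group against every library.

    Returns one row per group with columns ``group_id, mz, rt`` plus, per
    library L, ``L_compound, L_adduct, L_score, L_k, L_m, L_n``. Only the
    rank-1 hit per (group, library) enters the table; groups with no hit
    in any library are kept iff ``retain_unannotated``.
    """
    if not libraries:
        raise ValueError("search_dataset requires at least one library")
    rows = []
    for gid, group in enumerate(groups):
        row: dict[str, object] = {
            "group_id": gid,
            "mz": group.slice.mz_center,
            "rt": group.rt_apex,
        }
        annotated = False
        for lib in libraries:
            hits = search_group(group, lib, params)
            if hits:
                best = hits[0]
                annotated = True
                row.update(
                    {
                        f"{lib.name}_compound": best.entry_name,
                        f"{lib.name}_adduct": best.adduct,
                        f"{lib.name}_score": best.score,
                        f"{lib.name}_k": best.k,
                        f"{lib.name}_m": best.m,
                        f"{lib.name}_n": best.n,
                    }
                )
            else:
                row.update(
                    {
                        f"{lib.name}_compound": None,
                        f"{lib.name}_adduct": None,
                        f"{lib.name}_score": np.nan,
                        f"{lib.name}_k": 0,
                        f"{lib.name}_m": 0,
                        f"{lib.name}_n": 0,
                    }
                )
        if annotated or params.retain_unannotated:
            rows.append(row)
    columns = ["group_id", "mz", "rt"]
    for lib in libraries:
        columns += [
            f"{lib.name}_{c}" for c in ("compound", "adduct", "score", "k", "m", "n")
        ]
    return pd.DataFrame(rows, columns=columns)


def precision_recall_curve(
    annotations: pd.DataFrame,
    ground_truth: dict[int, tuple[str, float]],
    library_name: str,
    rt_window_min: float = 0.5,
) -> pd.DataFrame:
    """Cumulative precision/recall walking down the score ranking.

    Row i gives precision and recall when exactly the i+1 best-scoring
    annotations are accepted. Recall is measured against the number of
    ground-truth compounds. Used to compare score types at matched
    recall, where each score's threshold axis is scaled to its own
    maximum.
    """
    score_col = f"{library_name}_score"
    compound_col = f"{library_name}_compound"
    frame = annotations.dropna(subset=[score_col]).sort_values(
        score_col, ascending=False
    )
    n_true = len({name for name, _ in ground_truth.values()})
    correct_flags = []
    for _, row in frame.iterrows():
        truth = ground_truth.get(int(row["group_id"]))
        correct_flags.append(
            truth is not None
            and row[compound_col] == truth[0]
            and abs(float(row["rt"]) - truth[1]) <= rt_window_min
        )
    cum_correct = np.cumsum(correct_flags)
    n_accepted = np.arange(1, len(frame) + 1)
    return pd.DataFrame(
        {
            "threshold": frame[score_col].to_numpy(),
            "accepted": n_accepted,
            "precision": cum_correct / n_accepted,
            "recall": cum_correct / max(n_true, 1),
        }
    )


def precision_at_recall(curve: pd.DataFrame, target_recall: float) -> float:
    """Precision at the tightest threshold whose recall reaches the target."""
    reached = curve[curve["recall"] >= target_recall]
    if reached.empty:
        return float("nan")
    return float(reached["precision"].iloc[0])


def evaluate_precision(
    annotations: pd.DataFrame,
    ground_truth: dict[int, tuple[str, float]],
    library_name: str,
    thresholds: np.ndarray | list[float] | None = None,
    rt_window_min: float = 0.5,
    n_thresholds: int = 50,
) -> pd.DataFrame:
    """Precision of accepted annotations as a function of score threshold.

    ``ground_truth`` maps group_id to (true compound name, true RT). An
    accepted annotation is correct when the compound name matches and the
    group apex RT is within ``rt_window_min`` of the true RT. Thresholds
    default to a grid scaled to the score's maximum so different score
    types can share one plot axis. Rows where nothing is accepted carry
    NaN precision (undefined, not zero).
    """
    score_col = f"{library_name}_score"
    compound_col = f"{library_name}_compound"
    frame = annotations.dropna(subset=[score_col])
    scores = frame[score_col].to_numpy(dtype=float)
    if thresholds is None:
        max_score = scores.max() if scores.size else 1.0
        thresholds = np.linspace(0.0, max_score, n_thresholds)
    records = []
    for thr in np.asarray(thresholds, dtype=float):
        accepted = frame[frame[score_col] >= thr]
        n_accepted = len(accepted)
        if n_accepted == 0:
            records.append({"threshold": thr, "precision": np.nan, "accepted": 0})
            continue
        correct = 0
        for _, row in accepted.iterrows():
            truth = ground_truth.get(int(row["group_id"]))
            if truth is None:
                continue
            true_name, true_rt = truth
            if (
                row[compound_col] == true_name
                and abs(float(row["rt"]) - true_rt) <= rt_window_min
            ):
                correct += 1
        records.append(
            {"threshold": thr, "precision": correct / n_accepted, "accepted": n_accepted}
        )
    return pd.DataFrame(records)
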