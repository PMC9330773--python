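"""Fragment matching and spectral similarity scores.

Five scores are provided for comparing an observed (consensus) MS/MS
spectrum to a reference library spectrum:

- ``hgs`` — hypergeometric score. With m observed fragments, n reference
  fragments, k one-to-one fragment matches, and N non-overlapping m/z
  buckets in which a chance match could occur,

      Score(k, m, n, N) = -ln( C(m,k) * C(N-m, n-k) / C(N,n) )

  i.e. the negative log-probability of observing k or-exactly-k matches
  by chance under a hypergeometric draw. Intensities are ignored, which
  makes the score robust to chimeric spectra and to intensity-free
  (in-silico) libraries.
- ``mvh`` — multi-class weighted hypergeometric score: reference
  fragments are ranked into three intensity classes and the per-class
  match counts are scored under a multivariate hypergeometric model.
- ``dot`` — cosine of intensity-weighted vectors over matched/unmatched
  fragment slots (square-root intensity weighting by default).
- ``frac_matched`` — k/n, the fraction of reference fragments matched.
- ``tic_fraction`` — matched reference intensity over total reference
  intensity.

N models instrument resolving power: two peaks that ought to match must
fall in the same bucket. For high-resolution data N should be large, on
the order of 1e5 or more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from specmatch.spectra_io import Spectrum

DEFAULT_N = 100_000
DEFAULT_FRAGMENT_TOL_PPM = 20.0
SCORE_TYPES = ("hgs", "mvh", "dot", "frac_matched", "tic_fraction")


@dataclass
class FragmentMatchSet:
    """Result of one-to-one fragment matching between two spectra."""

    k: int  # matched fragment pairs
    m: int  # observed fragment count
    n: int  # reference fragment count
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    matched_ref_intensity_sum: float = 0.0
    total_ref_intensity_sum: float = 0.0


@dataclass
class ScoringConfig:
    """Knobs shared by all scores."""

    N: int = DEFAULT_N
    fragment_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM
    score_type: str = "hgs"
    intensity_power: float = 0.5  # dot product weighting exponent

    def __post_init__(self) -> None:
        if self.score_type not in SCORE_TYPES:
            raise ValueError(
                f"unknown score_type {self.score_type!r}; one of {SCORE_TYPES}"
            )


def match_fragments(
    observed: Spectrum, reference: Spectrum, tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM
) -> FragmentMatchSet:
    """Greedy one-to-one fragment matching.

    Reference fragments are processed in descending intensity order; each
    claims the nearest (in ppm) still-unmatched observed fragment within
    ``tol_ppm``. Ties on distance go to the lower observed m/z; ties on
    reference intensity go to the lower reference m/z. Deterministic.
    """
    m, n = len(observed), len(reference)
    out = FragmentMatchSet(
        k=0, m=m, n=n, total_ref_intensity_sum=float(reference.intensity.sum())
    )
    if m == 0 or n == 0:
        return out
    ref_order = sorted(range(n), key=lambda j: (-reference.intensity[j], reference.mz[j]))
    taken = np.zeros(m, dtype=bool)
    obs_mz = observed.mz
    for j in ref_order:
        ref_mz = reference.mz[j]
        half = ref_mz * tol_ppm * 1e-6
        lo = int(np.searchsorted(obs_mz, ref_mz - half, side="left"))
        hi = int(np.searchsorted(obs_mz, ref_mz + half, side="right"))
        best_i = -1
        best_dist = math.inf
        for i in range(lo, hi):
            if taken[i]:
                continue
            dist = abs(obs_mz[i] - ref_mz)
            # strict < keeps the lower-m/z candidate on exact distance ties
            if dist < best_dist:
                best_dist = dist
                best_i = i
        if best_i >= 0:
            taken[best_i] = True
            ppm_err = (obs_mz[best_i] - ref_mz) / ref_mz * 1e6
            out.pairs.append((best_i, j, float(ppm_err)))
            out.matched_ref_intensity_sum += float(reference.intensity[j])
    out.k = len(out.pairs)
    return out


def _log_binom(a: int, b: int) -> float:
    """ln C(a, b) for 0 <= b <= a, accurate to ~1e-12 relative.

    For a small lower index (the usual case: b is a fragment count while
    a may be the bucket count N ~ 1e5-1e7) the direct log-gamma route
    cancels catastrophically, so sum ln((a-i)/(b'-i)) over the b' =
    min(b, a-b) factors instead; fall back to log-gamma when both
    indices are large.
    """
    b = min(b, a - b)
    if b == 0:
        return 0.0
    if b <= 10_000:
        i = np.arange(b, dtype=np.float64)
        return float(np.sum(np.log((a - i) / (b - i))))
    return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))


def _check_tuple(k: int, m: int, n: int, N: int) -> None:
    if not (0 <= k <= min(m, n)):
        raise ValueError(f"invalid match tuple: need 0 <= k <= min(m, n), got {(k, m, n, N)}")
    if m > N or n > N:
        raise ValueError(f"invalid match tuple: need m <= N and n <= N, got {(k, m, n, N)}")
    if n - k > N - m:
        raise ValueError(
            f"invalid match tuple: need n - k <= N - m (N too small), got {(k, m, n, N)}"
        )


def hypergeometric_score(k: int, m: int, n: int, N: int) -> float:
    """-ln of the hypergeometric probability of exactly k fragment matches.

    Computed with log-binomials (log-gamma), never raw factorials, so it
    is finite for any valid tuple at any N. Non-negative because the
    probability is at most 1. Invalid tuples raise rather than clamp.
    """
    _check_tuple(k, m, n, N)
    log_p = _log_binom(m, k) + _log_binom(N - m, n - k) - _log_binom(N, n)
    return max(0.0, -log_p)


def mvh_score_from_counts(
    class_sizes: list[int], class_matches: list[int], m: int, N: int
) -> float:
    """-ln multivariate hypergeometric probability of per-class match counts.

    ``class_sizes`` partitions the n reference fragments into intensity
    classes; ``class_matches`` are the matched counts per class. The m
    observed fragments draw from N buckets of which n_i belong to class i:

        P = [ prod_i C(n_i, k_i) ] * C(N - n, m - k) / C(N, m)

    With a single class this reduces exactly to the hypergeometric score
    (by the symmetry of C(m,k)C(N-m,n-k)/C(N,n) in m and n).
    """
    if len(class_sizes) != len(class_matches):
        raise ValueError("class_sizes and class_matches length mismatch")
    n = sum(class_sizes)
    k = sum(class_matches)
    for n_i, k_i in zip(class_sizes, class_matches):
        if not 0 <= k_i <= n_i:
            raise ValueError(f"invalid class counts: k_i={k_i}, n_i={n_i}")
    if not (0 <= k <= min(m, n)) or m > N or n > N:
        raise ValueError(f"invalid match tuple {(k, m, n, N)}")
    if m - k > N - n:
        raise ValueError(f"need m - k <= N - n, got m={m}, k={k}, n={n}, N={N}")
    log_p = (
        sum(_log_binom(n_i, k_i) for n_i, k_i in zip(class_sizes, class_matches))
        + _log_binom(N - n, m - k)
        - _log_binom(N, m)
    )
    return max(0.0, -log_p)


def split_intensity_classes(
    reference: Spectrum, n_classes: int = 3
) -> list[list[int]]:
    """Partition reference fragment indices into intensity-rank classes.

    Fragments are ranked by descending intensity (ties to lower m/z) and
    cut into ``n_classes`` contiguous groups of near-equal size, the top
    group first. Fewer fragments than classes yields fewer groups.
    """
    n = len(reference)
    order = sorted(range(n), key=lambda j: (-reference.intensity[j], reference.mz[j]))
    n_classes = min(n_classes, n) if n else 0
    classes: list[list[int]] = []
    start = 0
    for c in range(n_classes):
        size = (n - start) // (n_classes - c)
        classes.append(order[start : start + size])
        start += size
    return classes


def mvh_score(
    observed: Spectrum, reference: Spectrum, config: ScoringConfig | None = None
) -> float:
    """Three-intensity-class hypergeometric score of an observed/reference pair."""
    config = config or ScoringConfig()
    if len(observed) == 0 or len(reference) == 0:
        raise ValueError("mvh_score requires non-empty spectra")
    matches = match_fragments(observed, reference, config.fragment_tol_ppm)
    matched_ref = {j for _, j, _ in matches.pairs}
    classes = split_intensity_classes(reference, 3)
    sizes = [len(c) for c in classes]
    hits = [sum(1 for j in c if j in matched_ref) for c in classes]
    return mvh_score_from_counts(sizes, hits, matches.m, config.N)


def dot_product(
    observed: Spectrum,
    reference: Spectrum,
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    intensity_power: float = 0.5,
) -> float:
    """Cosine similarity over matched fragment slots, in [0, 1].

    Intensities are raised to ``intensity_power`` (0.5 = square-root
    weighting, 1.0 = plain cosine). Matched pairs contribute to the inner
    product; unmatched fragments on either side contribute to the norms
    only, so chimeric contamination dilutes the score.
    """
    if len(observed) == 0 or len(reference) == 0:
        return 0.0
    w_obs = observed.intensity**intensity_power
    w_ref = reference.intensity**intensity_power
    norm = math.sqrt(float((w_obs**2).sum())) * math.sqrt(float((w_ref**2).sum()))
    if norm == 0:
        return 0.0
    matches = match_fragments(observed, reference, tol_ppm)
    inner = sum(float(w_obs[i] * w_ref[j]) for i, j, _ in matches.pairs)
    return min(1.0, inner / norm)


def fraction_ref_matched(match_set: FragmentMatchSet) -> float:
    """k/n — the fraction of reference fragments with an observed match."""
    if match_set.n == 0:
        raise ValueError("fraction_ref_matched undefined for an empty reference")
    return match_set.k / match_set.n


def tic_fraction_matched(match_set: FragmentMatchSet) -> float:
    """Matched reference intensity over total reference intensity."""
    if match_set.total_ref_intensity_sum <= 0:
        raise ValueError("tic_fraction_matched undefined: reference TIC is zero")
    return match_set.matched_ref_intensity_sum / match_set.total_ref_intensity_sum


def score_spectra(
    observed: Spectrum, reference: Spectrum, config: ScoringConfig
) -> tuple[float, FragmentMatchSet]:
    """Score a spectrum pair with the configured score type.

    Returns (score, match_set); the match set carries the (k, m, n) used.
    """
    matches = match_fragments(observed, reference, config.fragment_tol_ppm)
    if config.score_type == "hgs":
        score = hypergeometric_score(matches.k, matches.m, matches.n, config.N)
    elif config.score_type == "mvh":
        score = mvh_score(observed, reference, config)
    elif config.score_type == "dot":
        score = dot_product(
            observed, reference, config.fragment_tol_ppm, config.intensity_power
        )
    elif config.score_type == "frac_matched":
        score = fraction_ref_matched(matches) if matches.n else 0.0
    elif config.score_type == "tic_fraction":
        score = (
            tic_fraction_matched(matches)
            if matches.total_ref_intensity_sum > 0
            else 0.0
        )
    else:  # pragma: no cover - guarded by ScoringConfig
        raise ValueError(config.score_type)
    return score, matches
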