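"""Fragment matching and the five similarity scores, checked against
exact big-integer oracles and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specmatch.scoring import (
    ScoringConfig,
    dot_product,
    fraction_ref_matched,
    hypergeometric_score,
    match_fragments,
    mvh_score,
    mvh_score_from_counts,
    split_intensity_classes,
    tic_fraction_matched,
)
from specmatch.spectra_io import Spectrum

from .oracles import exact_hgs, exact_mvh


def spec(mz, intensity=None):
    return Spectrum(np.asarray(mz, float),
                    np.asarray(intensity if intensity is not None else [100.0] * len(mz), float))


class TestMatchFragments:
    def test_identical_spectra_full_match(self):
        s = spec([100.0, 150.0, 200.0, 250.0, 300.0])
        result = match_fragments(s, s, tol_ppm=10)
        assert result.k == 5
        assert all(err == 0.0 for *_, err in result.pairs)

    def test_disjoint_spectra_no_match(self):
        assert match_fragments(spec([100.0, 200.0]), spec([150.0, 250.0]), 10).k == 0

    def test_equidistant_tie_goes_to_lower_mz(self):
        # observed 100.000 and 100.001 are both 5 ppm from ref 100.0005
        obs = spec([100.000, 100.001])
        ref = spec([100.0005])
        result = match_fragments(obs, ref, tol_ppm=20)
        assert result.k == 1
        assert result.pairs[0][0] == 0  # lower-m/z observed fragment

    def test_one_to_one_under_intensity_priority(self):
        # two ref fragments compete for one observed; the taller ref wins it
        obs = spec([100.0])
        ref = spec([100.0000, 100.0005], [10.0, 90.0])
        result = match_fragments(obs, ref, tol_ppm=20)
        assert result.k == 1
        assert result.pairs[0][1] == 1  # the 90-intensity reference fragment

    def test_empty_inputs(self):
        empty = spec([])
        assert match_fragments(empty, spec([100.0]), 10).k == 0
        assert match_fragments(spec([100.0]), empty, 10).k == 0


class TestHypergeometricScore:
    def test_perfect_match_saturated_buckets_is_zero(self):
        assert hypergeometric_score(10, 10, 10, 10) == 0.0

    def test_agrees_with_exact_oracle_spot_value(self):
        expected = exact_hgs(5, 10, 10, 100_000)
        got = hypergeometric_score(5, 10, 10, 100_000)
        assert got == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("N", [1_000, 100_000, 10_000_000])
    @pytest.mark.parametrize("n", [1, 5, 20])
    def test_oracle_grid(self, n, N):
        for m in range(n, 51, 7):
            for k in range(0, n + 1):
                if n - k > N - m:
                    continue
                expected = exact_hgs(k, m, n, N)
                got = hypergeometric_score(k, m, n, N)
                assert got == pytest.approx(expected, rel=1e-9, abs=1e-12), (k, m, n, N)

    def test_monotone_in_k(self):
        scores = [hypergeometric_score(k, 20, 20, 100_000) for k in range(21)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 30))
            m = int(rng.integers(n, 60))
            k = int(rng.integers(0, n + 1))
            assert hypergeometric_score(k, m, n, 100_000) >= 0.0

    @pytest.mark.parametrize(
        "bad", [(5, 4, 10, 100), (11, 20, 10, 100), (-1, 5, 5, 100), (0, 90, 20, 100)]
    )
    def test_invalid_tuples_raise(self, bad):
        k, m, n, N = bad
        with pytest.raises(ValueError):
            hypergeometric_score(k, m, n, N)

    def test_chimeric_noise_enters_only_through_m(self):
        """Unmatched observed fragments change the score only via the
        C(m,k) factor; the drop equals the oracle's ln C(60,10) exactly
        and the noisy score stays a decisive match (p < 1e-30)."""
        clean = hypergeometric_score(10, 10, 10, 100_000)
        noisy = hypergeometric_score(10, 60, 10, 100_000)
        assert clean - noisy == pytest.approx(
            exact_hgs(10, 10, 10, 100_000) - exact_hgs(10, 60, 10, 100_000),
            rel=1e-9,
        )
        assert noisy > 30.0  # still overwhelming evidence of a match


class TestMvhScore:
    def test_perfect_match_all_buckets_is_zero(self):
        obs = spec([100.0, 200.0, 300.0], [10, 20, 30])
        assert mvh_score(obs, obs, ScoringConfig(N=3)) == 0.0

    def test_three_class_toy_against_exact_oracle(self):
        expected = exact_mvh([2, 2, 2], [2, 1, 0], m=5, N=1_000)
        got = mvh_score_from_counts([2, 2, 2], [2, 1, 0], m=5, N=1_000)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_single_class_reduces_to_hgs(self):
        k, m, n, N = 4, 12, 6, 100_000
        assert mvh_score_from_counts([n], [k], m, N) == pytest.approx(
            hypergeometric_score(k, m, n, N), rel=1e-9
        )

    def test_class_split_is_balanced_and_ordered(self):
        ref = spec(list(range(100, 100 + 9)), [9, 8, 7, 6, 5, 4, 3, 2, 1])
        classes = split_intensity_classes(ref, 3)
        assert [len(c) for c in classes] == [3, 3, 3]
        # top class holds the three most intense fragments
        assert sorted(classes[0]) == [0, 1, 2]

    def test_matching_high_intensity_class_scores_higher(self):
        """Matching the intense third of the reference should beat
        matching the weak third with the same k."""
        high = mvh_score_from_counts([3, 3, 3], [3, 0, 0], m=3, N=1_000)
        low = mvh_score_from_counts([3, 3, 3], [0, 0, 3], m=3, N=1_000)
        assert high == pytest.approx(low)  # symmetric classes, same size
        mixed = mvh_score_from_counts([4, 3, 2], [4, 0, 0], m=4, N=1_000)
        weak = mvh_score_from_counts([4, 3, 2], [0, 0, 2], m=4, N=1_000)
        assert mixed > weak  # larger class fully matched is less probable


class TestDotProduct:
    def test_identical_spectra_score_one(self):
        s = spec([100.0, 200.0, 300.0], [10, 50, 100])
        assert dot_product(s, s, 10) == pytest.approx(1.0)

    def test_disjoint_spectra_score_zero(self):
        assert dot_product(spec([100.0]), spec([500.0]), 10) == 0.0

    def test_sqrt_weighted_closed_form(self):
        obs = spec([100.0], [4.0])
        ref = spec([100.0, 200.0], [1.0, 1.0])
        # sqrt weights: obs (2), ref (1,1): inner 2, norms 2 and sqrt(2)
        assert dot_product(obs, ref, 10) == pytest.approx(2 / (2 * math.sqrt(2)))

    def test_symmetric(self):
        a = spec([100.0, 150.0, 300.0], [5, 80, 100])
        b = spec([100.0, 150.0, 250.0], [50, 20, 30])
        assert dot_product(a, b, 10) == pytest.approx(dot_product(b, a, 10))

    def test_matches_matchms_on_unambiguous_spectra(self):
        """Cross-check against matchms CosineGreedy where greedy
        assignment is unambiguous (well-separated peaks)."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(42)
        for _ in range(10):
            mz_a = np.sort(rng.choice(np.arange(100, 900, 2.0), 12, replace=False))
            mz_b = np.sort(rng.choice(np.arange(100, 900, 2.0), 12, replace=False))
            ia = rng.uniform(10, 100, 12)
            ib = rng.uniform(10, 100, 12)
            ours = dot_product(spec(mz_a, ia), spec(mz_b, ib), tol_ppm=100)
            sa = matchms.Spectrum(mz=mz_a, intensities=ia, metadata_harmonization=False)
            sb = matchms.Spectrum(mz=mz_b, intensities=ib, metadata_harmonization=False)
            theirs = float(
                CosineGreedy(tolerance=0.1, intensity_power=0.5)
                .pair(sa, sb)["score"]
            )
            assert ours == pytest.approx(theirs, abs=1e-8)

    def test_chimeric_noise_halves_cosine(self):
        """50 unmatched fragments collapse the cosine by > 50% while the
        hypergeometric score barely moves (chimera robustness contrast)."""
        ref_mz = np.arange(200.0, 300.0, 10.0)  # 10 fragments
        ref = spec(ref_mz, np.full(10, 50.0))
        noise_mz = np.arange(400.0, 650.0, 5.0)  # 50 fragments
        chimeric = spec(
            np.concatenate([ref_mz, noise_mz]),
            np.concatenate([np.full(10, 50.0), np.full(50, 50.0)]),
        )
        clean_dot = dot_product(ref, ref, 10)
        noisy_dot = dot_product(chimeric, ref, 10)
        assert noisy_dot < 0.5 * clean_dot


class TestFractionScores:
    def test_fraction_matched(self):
        obs = spec([100.0, 200.0, 300.0])
        ref = spec([100.0, 200.0, 300.0, 400.0])
        assert fraction_ref_matched(match_fragments(obs, ref, 10)) == 0.75

    def test_full_match_both_one(self):
        s = spec([100.0, 200.0], [80.0, 20.0])
        result = match_fragments(s, s, 10)
        assert fraction_ref_matched(result) == 1.0
        assert tic_fraction_matched(result) == 1.0

    def test_tic_weighted_by_intensity(self):
        obs = spec([100.0])
        ref = spec([100.0, 200.0], [80.0, 20.0])
        result = match_fragments(obs, ref, 10)
        assert tic_fraction_matched(result) == pytest.approx(0.8)
        assert fraction_ref_matched(result) == pytest.approx(0.5)

    def test_empty_reference_raises(self):
        result = match_fragments(spec([100.0]), spec([]), 10)
        with pytest.raises(ValueError):
            fraction_ref_matched(result)
        with pytest.raises(ValueError):
            tic_fraction_matched(result)


@settings(deadline=None, max_examples=150, derandomize=True)
@given(
    n=st.integers(1, 25),
    extra_m=st.integers(0, 30),
    k_frac=st.floats(0.0, 1.0),
    N=st.sampled_from([1_000, 100_000, 10_000_000]),
)
def test_hgs_matches_exact_oracle_property(n, extra_m, k_frac, N):
    m = n + extra_m
    k = round(k_frac * n)
    if n - k > N - m:
        return
    assert hypergeometric_score(k, m, n, N) == pytest.approx(
        exact_hgs(k, m, n, N), rel=1e-9, abs=1e-12
    )
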