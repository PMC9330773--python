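"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: exact big-integer
rational arithmetic for the hypergeometric scores, and a quadratic
fixed-point union for slice merging.
"""

from fractions import Fraction
from math import comb, log


def exact_hgs(k: int, m: int, n: int, N: int) -> float:
    """-ln( C(m,k) C(N-m,n-k) / C(N,n) ) with exact integers, log last."""
    p = Fraction(comb(m, k) * comb(N - m, n - k), comb(N, n))
    return log(p.denominator) - log(p.numerator)


def exact_mvh(class_sizes, class_matches, m: int, N: int) -> float:
    """-ln( prod_i C(n_i,k_i) * C(N-n, m-k) / C(N,m) ), exact rational."""
    n, k = sum(class_sizes), sum(class_matches)
    num = comb(N - n, m - k)
    for n_i, k_i in zip(class_sizes, class_matches):
        num *= comb(n_i, k_i)
    p = Fraction(num, comb(N, m))
    return log(p.denominator) - log(p.numerator)


def brute_force_merge(rects):
    """Fixed-point union of overlapping (mz_min, mz_max, rt_min, rt_max)
    rectangles: repeatedly union any overlapping pair until stable.
    Returns a sorted list of bound tuples."""
    rects = [tuple(r) for r in rects]
    changed = True
    while changed:
        changed = False
        out = []
        while rects:
            cur = rects.pop()
            merged_any = True
            while merged_any:
                merged_any = False
                keep = []
                for other in rects:
                    if (
                        cur[0] <= other[1]
                        and other[0] <= cur[1]
                        and cur[2] <= other[3]
                        and other[2] <= cur[3]
                    ):
                        cur = (
                            min(cur[0], other[0]),
                            max(cur[1], other[1]),
                            min(cur[2], other[2]),
                            max(cur[3], other[3]),
                        )
                        merged_any = True
                        changed = True
                    else:
                        keep.append(other)
                rects = keep
            out.append(cur)
        rects = out
    return sorted(rects)
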