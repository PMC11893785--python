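"""Independent oracles used by the test suite.

Each oracle is deliberately implemented by a different route than the
package code it checks: exhaustive dynamic programming for motif tiling,
factorial-formula rational enumeration for Fisher's exact test, and
scipy-based permutation enumeration for Spearman's test.
"""

from fractions import Fraction
from math import factorial


def min_noise_dp(seq: str, motifs: tuple[str, ...]) -> int:
    """Minimum number of noise nt over all tilings of ``seq`` by motifs."""
    n = len(seq)
    dp = [0] * (n + 1)
    for i in range(1, n + 1):
        best = dp[i - 1] + 1  # position i-1 left as noise
        for motif in motifs:
            m = len(motif)
            if i >= m and seq[i - m : i] == motif:
                best = min(best, dp[i - m])
        dp[i] = best
    return dp[n]


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided small-p Fisher p-value by full rational enumeration.

    Point probabilities from the factorial formula
    p = r1! r2! c1! c2! / (n! a! b! c! d!), summed over every table with
    the observed margins whose probability is <= the observed one.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    c2 = n - c1

    def prob(x: int) -> Fraction:
        aa, bb, cc, dd = x, r1 - x, c1 - x, r2 - (c1 - x)
        num = factorial(r1) * factorial(r2) * factorial(c1) * factorial(c2)
        den = (
            factorial(n)
            * factorial(aa)
            * factorial(bb)
            * factorial(cc)
            * factorial(dd)
        )
        return Fraction(num, den)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    observed = prob(a)
    return sum(
        (p for x in range(lo, hi + 1) if (p := prob(x)) <= observed),
        Fraction(0),
    )
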