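"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own numerics: the two-sided exact
p-value is computed by full enumeration of all 2x2 tables sharing the
observed margins, with exact integer arithmetic for the tie comparison.
"""

from math import comb

# same relative tie tolerance the test's subject uses, applied exactly:
# include table j iff num_j * 10^7 <= num_obs * (10^7 + 1)
_SCALE = 10**7


def enumeration_p_value(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided exact p by enumeration over the hypergeometric support."""
    N, K = n1 + n2, k1 + k2
    lo, hi = max(0, K - n2), min(K, n1)
    numerators = [comb(K, k) * comb(N - K, n1 - k) for k in range(lo, hi + 1)]
    observed = numerators[k1 - lo]
    included = sum(v for v in numerators if v * _SCALE <= observed * (_SCALE + 1))
    return included / comb(N, n1)
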