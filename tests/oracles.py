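"""Independent brute-force oracles, kept deliberately separate from the
implementation: plain enumeration with explicit pair tables and direct
summation, no shared helpers with the package."""

from __future__ import annotations

import math

PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


def brute_force_delta_g(window: str, asd: str, params) -> float:
    """Minimum duplex energy by exhaustive enumeration of every alignment
    offset and every contiguous stretch of consecutive complementary pairs.

    Stacks are summed in window order to match the implementation's
    arithmetic order exactly.
    """
    ok_pairs = PAIRS | (WOBBLE if params.allow_gu else set())
    asd_35 = asd[::-1]  # ASD read 3'->5'
    best = 0.0
    n, m = len(window), len(asd_35)
    for offset in range(-m + 1, n):
        # start/length enumeration of candidate helices
        for start_k in range(m):
            i0 = offset + start_k
            if i0 < 0:
                continue
            for length in range(2, m - start_k + 1):
                i1 = i0 + length - 1
                if i1 >= n:
                    break
                ks = range(start_k, start_k + length)
                if not all(
                    (window[offset + k], asd_35[k]) in ok_pairs for k in ks
                ):
                    continue
                total = params.init_dg
                for i in range(i0, i1):
                    total += params.stack_dg[
                        (window[i] + window[i + 1],
                         asd_35[i - offset] + asd_35[i - offset + 1])
                    ]
                for i in (i0, i1):
                    if (window[i], asd_35[i - offset]) in (
                        {("A", "U"), ("U", "A")} | WOBBLE
                    ):
                        total += params.terminal_au_dg
                if total < best:
                    best = total
    return best


def binomial_tail_by_summation(k: int, n: int, p: float, upper: bool) -> float:
    """P[X >= k] (upper) or P[X <= k] (lower) by direct summation of the
    binomial mass function."""
    def pmf(i: int) -> float:
        return math.comb(n, i) * p**i * (1 - p) ** (n - i)

    if upper:
        return sum(pmf(i) for i in range(k, n + 1))
    return sum(pmf(i) for i in range(0, k + 1))
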