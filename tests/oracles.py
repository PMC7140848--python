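"""Independent oracles used by the test suite.

These deliberately avoid the recursions of the production code: folding is
checked against exhaustive enumeration of every nested structure (evaluated
with the shared loop-decomposition energy function), and pair maximisation
against a plain Nussinov dynamic program.
"""

from __future__ import annotations

from functools import lru_cache

from mirpipe.rnafold import (MIN_HAIRPIN, EnergyModel, encode, pair_type,
                             structure_energy)


def enumerate_structures(seq: str):
    """Yield every nested pair set (min hairpin loop 3) of ``seq``."""
    codes = encode(seq)
    n = len(codes)

    @lru_cache(maxsize=None)
    def region(i: int, j: int) -> tuple:
        """All structures of region [i, j] as tuples of pairs."""
        if j - i < MIN_HAIRPIN + 1:
            return ((),)
        out = list(region(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if pair_type(codes[i], codes[k]) < 0:
                continue
            for inner in region(i + 1, k - 1):
                for rest in region(k + 1, j):
                    out.append(((i, k),) + inner + rest)
        return tuple(out)

    yield from region(0, n - 1)


def brute_force_mfe(seq: str, model: EnergyModel | None = None) -> float:
    """Minimum energy over every enumerated structure."""
    model = model or EnergyModel()
    best = 0.0
    for pairs in enumerate_structures(seq):
        e = structure_energy(seq, pairs, model)
        if e < best:
            best = e
    return best


def nussinov_max_pairs(seq: str) -> int:
    """Classic base-pair maximisation DP with minimum hairpin loop 3."""
    codes = encode(seq)
    n = len(codes)
    dp = [[0] * n for _ in range(n)]
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                if pair_type(codes[i], codes[k]) >= 0:
                    inner = dp[i + 1][k - 1] if k - 1 > i + 1 else 0
                    rest = dp[k + 1][j] if k + 1 < j else 0
                    best = max(best, 1 + inner + rest)
            dp[i][j] = best
    return dp[0][n - 1]
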