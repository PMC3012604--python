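"""Independent brute-force oracles for alignment scores.

These enumerate every possible alignment explicitly and are exponential
in sequence length — usable only for tiny inputs, which is the point:
they share no code path with the aligner they check.

Gap convention matches the package contract: a gap of length L costs
gap_open + L * gap_extend.
"""

from __future__ import annotations


def brute_force_global(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Maximum affine-gap global alignment score by full enumeration."""
    best = [float("-inf")]

    def rec(i: int, j: int, prev: str | None, acc: float) -> None:
        if i == len(a) and j == len(b):
            if acc > best[0]:
                best[0] = acc
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", acc + score(a[i], b[j]))
        if i < len(a):
            cost = gap_extend if prev == "A" else gap_open + gap_extend
            rec(i + 1, j, "A", acc - cost)
        if j < len(b):
            cost = gap_extend if prev == "B" else gap_open + gap_extend
            rec(i, j + 1, "B", acc - cost)

    rec(0, 0, None, 0.0)
    return best[0]


def brute_force_local(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Maximum local score: best global score over all substring pairs,
    floored at 0 (the empty alignment)."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = brute_force_global(a[i1:i2], b[j1:j2], score, gap_open, gap_extend)
                    if s > best:
                        best = s
    return best
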