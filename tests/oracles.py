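"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's algorithms: the scanner oracle
enumerates tandem runs from every start position, the consensus oracle counts
exact key occurrences, the left-alignment oracle searches shifts
exhaustively, and the rank-sum oracle enumerates group assignments.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def primitive(motif: str) -> str:
    for d in range(1, len(motif) + 1):
        if len(motif) % d == 0 and motif[:d] * (len(motif) // d) == motif:
            return motif[:d]
    return motif


def brute_force_tandem_runs(seq: str, min_repeats: dict[int, int]) -> list[tuple[int, int, int]]:
    """All maximal tandem runs as (start, end, unit_len), overlap-resolved.

    For every start and unit length, count full motif copies by direct string
    comparison; keep runs that meet the minimum, are primitive, and cannot be
    extended by a full copy on either side; resolve overlaps by total length,
    then smaller unit, then smaller start (the documented tie-break).
    """
    n = len(seq)
    cands = set()
    for u, min_rep in min_repeats.items():
        for s in range(n - u * min_rep + 1):
            motif = seq[s : s + u]
            if len(motif) < u or "N" in motif or primitive(motif) != motif:
                continue
            k = 1
            while seq[s + k * u : s + (k + 1) * u] == motif:
                k += 1
            if k < min_rep:
                continue
            # maximality: no full copy immediately left or right
            if s >= u and seq[s - u : s] == motif:
                continue
            cands.add((s, s + k * u, u))
    chosen: list[tuple[int, int, int]] = []
    for c in sorted(cands, key=lambda c: (-(c[1] - c[0]), c[2], c[0])):
        if all(c[1] <= k[0] or c[0] >= k[1] for k in chosen):
            chosen.append(c)
    return sorted(chosen)


def brute_force_consensus(callsets: dict[str, list], min_callers: int = 2) -> set:
    """Variant keys supported by >= min_callers callers, by direct counting."""
    counts: dict[tuple, set] = {}
    for caller, variants in callsets.items():
        for v in variants:
            counts.setdefault(v.key, set()).add(caller)
    return {k for k, callers in counts.items() if len(callers) >= min_callers}


def leftmost_indel_shift(chrom: str, pos: int, ref: str, alt: str, seq: str) -> tuple[int, str, str]:
    """Exhaustive search for the leftmost minimal equivalent representation.

    ``seq`` is the full chromosome (1-based positions).  Reconstructs the
    alternate chromosome implied by the edit, then tries every candidate
    (pos', ref', alt') with minimal trimmed alleles from position 1 upward
    and returns the first that reproduces the same alternate sequence.
    """
    altered = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
    d = len(ref) - len(alt)
    for p in range(1, len(seq) + 1):
        if d > 0:  # deletion: ref' = anchor + deleted bases, alt' = anchor
            r = seq[p - 1 : p + d]
            a = seq[p - 1]
            if len(r) != d + 1:
                continue
        elif d < 0:  # insertion: ref' = anchor, alt' read from altered seq
            r = seq[p - 1]
            a = altered[p - 1 : p - d]
            if len(a) != 1 - d:
                continue
        else:  # SNV: no shifting possible
            if p != pos:
                continue
            r, a = seq[p - 1], alt
        cand = seq[: p - 1] + a + seq[p - 1 + len(r) :]
        if cand == altered and r != a:
            return p, r, a
    raise AssertionError("no equivalent representation found")


def exact_mannwhitney_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments.

    p = P(|U - n1 n2 / 2| >= |U_obs - n1 n2 / 2|) over all C(n, n1) splits of
    the pooled sample (valid for tie-free data).
    """
    pooled = sorted(x + y)
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0

    def u_stat(xs: tuple[float, ...]) -> float:
        ys = list(pooled)
        for v in xs:
            ys.remove(v)
        return sum(1 for a in xs for b in ys if a > b)

    obs = abs(u_stat(tuple(x)) - mu)
    hits = sum(
        1 for xs in combinations(pooled, n1) if abs(u_stat(xs) - mu) >= obs - 1e-12
    )
    return hits / comb(n1 + n2, n1)
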