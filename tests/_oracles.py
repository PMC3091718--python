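"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plain per-position string checking, with no
reuse of the package's vectorized machinery.
"""

from __future__ import annotations

import math


def primitive(motif: str) -> bool:
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def brute_force_ssrs(seq: str, min_period=2, max_period=8, min_units=3,
                     min_len=None) -> set[tuple[int, int, str, int]]:
    """All maximal perfect tandem repeats by exhaustive (start, period) checks.

    Returns {(start_1based, end_1based, motif, units)}.  A candidate starts
    at `a` for period `p` only when position a-1 does not also match a-1+p
    (leftmost alignment of its tract); units are complete copies only;
    non-primitive motifs are skipped; a candidate fully inside an accepted
    smaller-period candidate is dropped.
    """
    if min_len is None:
        min_len = {2: 12, 3: 12, 4: 12, 5: 15, 6: 18, 7: 21, 8: 24}
    seq = seq.upper()
    n = len(seq)

    def match(j: int, p: int) -> bool:
        return (0 <= j and j + p < n and seq[j] in "ACGT"
                and seq[j + p] in "ACGT" and seq[j] == seq[j + p])

    accepted: list[tuple[int, int, str, int]] = []
    for p in range(min_period, max_period + 1):
        for a in range(n):
            if not match(a, p):
                continue
            if match(a - 1, p):
                continue  # not the leftmost alignment of this tract
            m = 0
            while match(a + m, p):
                m += 1
            units = (m + p) // p
            length = units * p
            motif = seq[a : a + p]
            if units < min_units or length < min_len[p] or not primitive(motif):
                continue
            accepted.append((a + 1, a + length, motif, units))
    # drop larger-period candidates nested in smaller-period ones
    out = set()
    for s, e, motif, units in accepted:
        nested = any(
            s >= s2 and e <= e2 and len(motif) > len(m2)
            for s2, e2, m2, _ in accepted
            if (s2, e2, m2) != (s, e, motif)
        )
        if not nested:
            out.add((s, e, motif, units))
    return out


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_RC[b] for b in reversed(s))


def brute_force_binding_sites(primer: str, seq: str, window=5, max_mm=5,
                              min_identity=0.8) -> set[tuple[str, int, int, int]]:
    """All admissible primer sites by direct per-position comparison.

    Returns {(strand, start_1based, end_1based, n_mismatch)}.  Mismatches
    (counted from the primer's 5' end) are only allowed at indices < window;
    total mismatches respect both the window cap and the identity floor.
    """
    primer = primer.upper()
    seq = seq.upper()
    L = len(primer)
    limit = min(max_mm, window, math.floor((1 - min_identity) * L + 1e-9))
    out = set()
    for strand in "+-":
        for pos in range(len(seq) - L + 1):
            window_seq = seq[pos : pos + L]
            if strand == "-":
                window_seq = revcomp(window_seq)
            mism = [i for i in range(L)
                    if window_seq[i] not in "ACGT" or window_seq[i] != primer[i]]
            if len(mism) <= limit and all(i < window for i in mism):
                out.add((strand, pos + 1, pos + L, len(mism)))
    return out


def t_two_sided_p(t: float, df: int, n_grid: int = 200_001) -> float:
    """Two-sided Student-t tail probability by numerical integration."""
    t = abs(t)
    lognorm = (math.lgamma((df + 1) / 2) - math.lgamma(df / 2)
               - 0.5 * math.log(df * math.pi))

    def pdf(x: float) -> float:
        return math.exp(lognorm - (df + 1) / 2 * math.log1p(x * x / df))

    # integrate the density over [-t, t] with the trapezoid rule
    h = 2 * t / (n_grid - 1)
    total = 0.0
    for i in range(n_grid):
        x = -t + i * h
        w = 0.5 if i in (0, n_grid - 1) else 1.0
        total += w * pdf(x)
    central = total * h
    return max(0.0, 1.0 - central)


def pooled_t_statistic(a, b) -> float:
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
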