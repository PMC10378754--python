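"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain Python loops and exact rational
arithmetic where feasible, deliberately avoiding the vectorised code paths
of the package so the two routes cannot share a bug.
"""

from __future__ import annotations

import math
from fractions import Fraction

from rohscape.genotypes import HET, MISSING


def brute_force_window_qualifies(window, max_het, max_missing) -> bool:
    n_het = sum(1 for c in window if c == HET)
    n_mis = sum(1 for c in window if c == MISSING)
    return n_het <= max_het and n_mis <= max_missing


def brute_force_hit_fractions(codes, params) -> list[float]:
    """Per-SNP qualifying-window fraction by explicit window enumeration."""
    m = len(codes)
    w = params.window_snps
    if m < w:
        return [0.0] * m
    quals = [
        brute_force_window_qualifies(
            codes[k : k + w], params.max_het_per_window, params.max_missing_per_window
        )
        for k in range(m - w + 1)
    ]
    fracs = []
    for j in range(m):
        windows = [k for k in range(m - w + 1) if k <= j < k + w]
        fracs.append(sum(quals[k] for k in windows) / len(windows))
    return fracs


def brute_force_roh(codes, bp, params) -> list[tuple[int, int, int]]:
    """ROH on one chromosome of one individual: (start_bp, end_bp, n_snps)."""
    m = len(codes)
    fracs = brute_force_hit_fractions(codes, params)
    marked = [
        fracs[j] >= params.hit_fraction_threshold and codes[j] != HET
        for j in range(m)
    ]
    runs = []
    j = 0
    while j < m:
        if marked[j]:
            s = j
            while j < m and marked[j]:
                j += 1
            runs.append((s, j - 1))
        else:
            j += 1
    segments = []
    for s, e in runs:
        while s <= e and codes[s] == MISSING:
            s += 1
        while e >= s and codes[e] == MISSING:
            e -= 1
        if s > e:
            continue
        pieces = []
        cur = s
        for t in range(s, e):
            if bp[t + 1] - bp[t] > params.max_gap_kb * 1000.0:
                pieces.append((cur, t))
                cur = t + 1
        pieces.append((cur, e))
        for ps, pe in pieces:
            while ps <= pe and codes[ps] == MISSING:
                ps += 1
            while pe >= ps and codes[pe] == MISSING:
                pe -= 1
            if ps > pe:
                continue
            n = pe - ps + 1
            length_kb = (bp[pe] - bp[ps] + 1) / 1000.0
            if (
                n >= params.min_snps_per_roh
                and length_kb >= params.min_length_kb
                and length_kb / n <= params.min_density_kb_per_snp
            ):
                segments.append((int(bp[ps]), int(bp[pe]), n))
    return segments


def hwe_exact_oracle(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Exact-rational two-sided conditional HWE p-value by full enumeration."""
    n = n_AA + n_AB + n_BB
    n_a = 2 * n_AA + n_AB
    n_b = 2 * n_BB + n_AB
    assert n_a > 0 and n_b > 0, "oracle needs a polymorphic marker"

    def weight(h: int) -> Fraction:
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        return Fraction(
            math.factorial(n) * 2**h,
            math.factorial(naa) * math.factorial(h) * math.factorial(nbb),
        )

    hets = [h for h in range(min(n_a, n_b) + 1) if (n_a - h) % 2 == 0]
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    w_obs = weights[n_AB]
    return float(sum(w for w in weights.values() if w <= w_obs) / total)


def pooled_t_oracle(a, b) -> tuple[float, int, float]:
    """Textbook pooled-variance two-sample t (p from scipy's t survival)."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, df, 2 * float(tdist.sf(abs(t), df))


def brute_force_incidence(segments, markers) -> list[int]:
    """Per-SNP carrier count by direct interval-stabbing per individual."""
    counts = [0] * len(markers)
    samples = {s.sample_id for s in segments}
    chrom = markers.chromosome
    bp = markers.position_bp
    for sid in samples:
        segs = [s for s in segments if s.sample_id == sid]
        for j in range(len(markers)):
            if any(
                s.chromosome == chrom[j] and s.start_bp <= bp[j] <= s.end_bp
                for s in segs
            ):
                counts[j] += 1
    return counts
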