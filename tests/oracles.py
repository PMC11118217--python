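"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: alignment scores come from
exhaustive enumeration of all global alignments, ward.D2 cluster distances
from a from-scratch recursive Lance–Williams evaluation with greedy merge
selection, and SASA from Monte-Carlo point sampling.
"""

from __future__ import annotations

import math

import numpy as np


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (row_a, row_b)."""
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for ra, rb in enumerate_alignments(a[:-1], b[:-1]):
            yield ra + a[-1], rb + b[-1]
    if a:
        for ra, rb in enumerate_alignments(a[:-1], b):
            yield ra + a[-1], rb + "-"
    if b:
        for ra, rb in enumerate_alignments(a, b[:-1]):
            yield ra + "-", rb + b[-1]


def score_alignment(ra: str, rb: str, sub, gap_open: float,
                    gap_extend: float) -> float:
    """Affine-gap score of an explicit alignment: a gap run of length L
    costs gap_open + gap_extend * (L - 1)."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(ra, rb):
        if x == "-":
            score -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += sub[(x, y)]
            in_gap_a = in_gap_b = False
    return score


def best_alignment_score(a: str, b: str, sub, gap_open: float,
                         gap_extend: float) -> float:
    return max(
        score_alignment(ra, rb, sub, gap_open, gap_extend)
        for ra, rb in enumerate_alignments(a, b)
    )


def ward_d2_reference(labels, values):
    """Greedy ward.D2 agglomeration with cluster distances computed from
    scratch by recursive Lance–Williams evaluation (no incremental matrix).

    Returns the sorted list of merge heights.
    """
    n = len(labels)
    base = {(i, j): float(values[i, j]) ** 2 for i in range(n)
            for j in range(n)}
    # Each cluster: (members frozenset, formation = None | (left, right))
    clusters = {i: (frozenset([i]), None) for i in range(n)}

    def d2(ca, cb, memo):
        key = (id(ca), id(cb))
        if key in memo:
            return memo[key]
        ma, fa = ca
        mb, fb = cb
        if len(ma) == 1 and len(mb) == 1:
            (i,), (j,) = ma, mb
            out = base[(i, j)]
        elif fa is not None:
            left, right = fa
            ni, nj = len(left[0]), len(right[0])
            nk = len(mb)
            out = ((ni + nk) * d2(left, cb, memo) + (nj + nk) * d2(right, cb, memo)
                   - nk * d2(left, right, memo)) / (ni + nj + nk)
        else:
            out = d2(cb, ca, memo)
        memo[key] = out
        return out

    heights = []
    next_id = n
    while len(clusters) > 1:
        memo = {}
        keys = sorted(clusters)
        best = None
        for x in range(len(keys)):
            for y in range(x + 1, len(keys)):
                v = d2(clusters[keys[x]], clusters[keys[y]], memo)
                if best is None or v < best[0] - 1e-12:
                    best = (v, keys[x], keys[y])
        v, i, j = best
        heights.append(math.sqrt(v))
        ca, cb = clusters.pop(i), clusters.pop(j)
        clusters[next_id] = (ca[0] | cb[0], (ca, cb))
        next_id += 1
    return sorted(heights)


def monte_carlo_sasa(coords, radii, probe: float, n_samples: int,
                     seed: int) -> float:
    """Total SASA by Monte-Carlo sampling of each atom's extended sphere."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    ext = np.asarray(radii, dtype=float) + probe
    total = 0.0
    for i in range(len(coords)):
        pts = rng.normal(size=(n_samples, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = coords[i] + ext[i] * pts
        exposed = np.ones(n_samples, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > ext[j] ** 2
        total += exposed.mean() * 4 * math.pi * ext[i] ** 2
    return total


def shannon_information(column: str) -> float:
    """log2(20) minus Shannon entropy of non-gap residue frequencies."""
    residues = [c for c in column if c != "-"]
    if not residues:
        return 0.0
    freqs = {}
    for c in residues:
        freqs[c] = freqs.get(c, 0) + 1
    total = len(residues)
    h = -sum((n / total) * math.log2(n / total) for n in freqs.values())
    return math.log2(20) - h
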