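"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written from first principles — naive
window scans, exhaustive enumeration, literal textbook formulas — and
shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math
import statistics

from Bio.Seq import Seq

SITE_ORDER = ["8mer", "7mer-m8", "7mer-A1", "6mer"]  # most specific first


def oracle_motifs(seed_rna: str) -> dict[str, str]:
    """Site motifs via Biopython's reverse complement (independent route)."""
    core7 = str(Seq(seed_rna).back_transcribe().reverse_complement())
    # drop the m8 pairing position: the 6mer core covers seed bases 1..6
    # (mature positions 2-7), i.e. the last seed base is excluded
    core6 = str(Seq(seed_rna[:6]).back_transcribe().reverse_complement())
    return {
        "8mer": core7 + "A",
        "7mer-m8": core7,
        "7mer-A1": core6 + "A",
        "6mer": core6,
    }


def oracle_scan(utr_seq: str, seed_rna: str, site_types) -> list[tuple[int, int, str]]:
    """Naive scan of every window, with per-core-anchor precedence.

    Returns sorted (start, end, site_type) triples.  The core anchor of a
    site is the position where the reverse complement of seed 2-7 begins
    (one base into 8mer/7mer-m8 motifs).
    """
    motifs = oracle_motifs(seed_rna)
    hits = []
    for site_type in site_types:
        motif = motifs[site_type]
        for start in range(len(utr_seq) - len(motif) + 1):
            if utr_seq[start : start + len(motif)] == motif:
                anchor = start + 1 if site_type in ("8mer", "7mer-m8") else start
                hits.append((anchor, start, site_type))
    best: dict[int, tuple[int, str]] = {}
    for anchor, start, site_type in hits:
        held = best.get(anchor)
        if held is None or SITE_ORDER.index(site_type) < SITE_ORDER.index(held[1]):
            best[anchor] = (start, site_type)
    out = [
        (start, start + len(motifs[site_type]), site_type)
        for start, site_type in best.values()
    ]
    return sorted(out)


def oracle_classify(
    utr_seq: str, pos: int, ref: str, alt: str, seed_rna: str, site_types
):
    """Full-rescan pair decision: which allele (if exactly one) forms a site
    overlapping pos?  Returns (target_allele, start, end, site_type) or None."""
    decisions = {}
    for allele in (ref, alt):
        seq = utr_seq[:pos] + allele + utr_seq[pos + 1 :]
        overlapping = [
            (s, e, t) for s, e, t in oracle_scan(seq, seed_rna, site_types)
            if s <= pos < e
        ]
        decisions[allele] = overlapping
    has_ref, has_alt = bool(decisions[ref]), bool(decisions[alt])
    if has_ref == has_alt:
        return None
    target = ref if has_ref else alt
    sites = decisions[target]
    best = min(sites, key=lambda s: (SITE_ORDER.index(s[2]), s[0]))
    return target, best[0], best[1], best[2]


# ---------------------------------------------------------------------------
# Fst oracles

def oracle_fst_wright(freqs) -> float:
    pbar = sum(freqs) / len(freqs)
    var = sum((p - pbar) ** 2 for p in freqs) / len(freqs)
    denom = pbar * (1 - pbar)
    return 0.0 if denom == 0 else var / denom


def oracle_fst_hudson_pair(c1, n1, c2, n2) -> float:
    """Direct evaluation of 1 - Hw/Hb with sample-size correction."""
    p1, p2 = c1 / n1, c2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num / den


def oracle_fst_weir_cockerham(counts) -> float:
    """Literal transcription of the 1984 variance components, allele form,
    written with plain loops (no numpy)."""
    r = len(counts)
    n = [t for _, t in counts]
    p = [c / t for c, t in counts]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    h = pbar * (1 - pbar)
    a = (nbar / nc) * (s2 - (h - s2 * (r - 1) / r) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (h - s2 * (r - 1) / r)
    return a / (a + b)


# ---------------------------------------------------------------------------
# Signed-rank oracles

def oracle_signed_rank_exact_p(diffs) -> float:
    """Two-sided exact p by enumerating all 2^n sign assignments.

    p = min(1, 2 * min(P(W+ <= w_obs), P(W+ >= w_obs))).
    """
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = _rank(list(map(abs, d)))
    w_obs = sum(r for x, r in zip(d, ranks) if x > 0)
    le = ge = 0
    total = 2**n
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        le += w <= w_obs
        ge += w >= w_obs
    return min(1.0, 2.0 * min(le / total, ge / total))


def _rank(values):
    """Midranks of |d| (handles ties)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_hodges_lehmann(diffs) -> float:
    """Median of all Walsh averages (i <= j), by explicit double loop."""
    d = [x for x in diffs if x != 0]
    walsh = [
        (d[i] + d[j]) / 2.0 for i in range(len(d)) for j in range(i, len(d))
    ]
    return statistics.median(walsh)


# ---------------------------------------------------------------------------
# OLS oracle

def oracle_ols(x, y):
    """Simple-regression normal equations plus adjusted R^2 and slope t-test."""
    n = len(x)
    xbar, ybar = sum(x) / n, sum(y) / n
    sxx = sum((xi - xbar) ** 2 for xi in x)
    sxy = sum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_res = sum((yi - intercept - slope * xi) ** 2 for xi, yi in zip(x, y))
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    se = math.sqrt(ss_res / (n - 2) / sxx) if n > 2 else float("nan")
    from scipy.stats import t as tdist

    tval = slope / se if se > 0 else float("inf")
    p = 2.0 * tdist.sf(abs(tval), n - 2)
    return slope, intercept, r2, r2_adj, p, se
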