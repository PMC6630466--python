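"""Allele-frequency aggregation and Fst estimation.

Fst measures the fraction of allele-frequency variance attributable to
differences among populations.  Three estimators are provided:

``wright_variance``
    The textbook parametric form var(p) / (p_bar (1 - p_bar)) computed
    directly on a vector of subpopulation frequencies (plain mean,
    population variance).  No sample-size correction; useful on printed
    frequency tables.

``hudson``
    The two-population allele-count estimator 1 - Hw/Hb with
    sample-size correction,

        N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        D = p1(1-p2) + p2(1-p1),

    extended to k populations as a ratio of averages of N and D over
    all population pairs (the recommended way to combine Fst across
    pairs and loci).

``weir_cockerham``
    The Weir & Cockerham (1984) variance-component estimator theta-hat
    in its allele-frequency (haploid-sample) form, for k populations
    with unequal sample sizes; multi-locus values are ratios of summed
    variance components.

Negative estimates are preserved (the unbiased estimators fluctuate
below zero when true differentiation is small); clamping happens only in
human-readable reports.  The empirical percentile ``P_Fst`` ranks an
observed Fst against a genome-wide or simulated null distribution with
the add-one convention P = (1 + #{null >= observed}) / (N + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidInputError

SUPER_POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")
FST_ESTIMATORS = ("hudson", "weir_cockerham", "wright_variance")


@dataclass(frozen=True)
class PopFreqTable:
    """Per-super-population target-allele counts and frequencies for one SNP.

    ``counts`` maps super-population -> (target allele count, total allele
    count); the global frequency is the pooled-count ratio, never the mean
    of the per-group frequencies.
    """

    snp_id: str
    counts: Mapping[str, tuple[int, int]]

    def frequency(self, group: str) -> float | None:
        c, t = self.counts.get(group, (0, 0))
        return None if t == 0 else c / t

    @property
    def frequencies(self) -> dict[str, float | None]:
        return {g: self.frequency(g) for g in self.counts}

    @property
    def global_frequency(self) -> float:
        num = sum(c for c, _ in self.counts.values())
        den = sum(t for _, t in self.counts.values())
        if den == 0:
            raise InvalidInputError(f"{self.snp_id}: zero total allele count")
        return num / den


@dataclass(frozen=True)
class FstResult:
    estimator: str
    value: float
    p_fst: float | None = None
    snp_id: str = ""

    @property
    def value_clamped(self) -> float:
        """Non-negative value for human-readable reports."""
        return max(0.0, self.value)


def pop_frequencies(
    genotypes: Mapping[str, tuple[int, int]],
    panel: Mapping[str, str],
    snp_id: str = "",
    *,
    target_is_alt: bool = True,
    strict: bool = False,
) -> PopFreqTable:
    """Aggregate per-sample genotypes to super-population target-allele counts.

    ``genotypes`` maps sample -> (a1, a2) with alleles coded 0 (REF),
    1 (ALT) or -1 (missing); ``panel`` maps sample -> super-population.
    Missing allele calls are excluded from numerator and denominator.
    Samples absent from the panel are dropped with a warning (or raise in
    ``strict`` mode).  With ``target_is_alt=False`` the counts are for
    the REF allele instead.
    """
    import logging

    counts: dict[str, list[int]] = {}
    for sample, (a1, a2) in genotypes.items():
        group = panel.get(sample)
        if group is None:
            if strict:
                raise InvalidInputError(f"sample {sample} absent from panel")
            logging.getLogger(__name__).warning(
                "sample %s absent from panel; dropped", sample
            )
            continue
        bucket = counts.setdefault(group, [0, 0])
        for a in (a1, a2):
            if a < 0:
                continue
            bucket[1] += 1
            hit = a == 1 if target_is_alt else a == 0
            if hit:
                bucket[0] += 1
    return PopFreqTable(snp_id, {g: (c, t) for g, (c, t) in counts.items()})


def fst_wright(freqs: Sequence[float]) -> float:
    """Wright's variance Fst on a vector of subpopulation frequencies.

    var(p) / (p_bar (1 - p_bar)) with equal population weights; returns
    0 by convention when the mean frequency is 0 or 1.
    """
    p = np.asarray([f for f in freqs if f is not None], dtype=float)
    if p.size < 2:
        raise InvalidInputError("need >= 2 defined frequencies")
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("frequencies must lie in [0, 1]")
    pbar = p.mean()
    denom = pbar * (1.0 - pbar)
    if denom == 0.0:
        return 0.0
    return float(p.var() / denom)


def _hudson_pair_components(
    c1: int, n1: int, c2: int, n2: int
) -> tuple[float, float]:
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("each population needs a total allele count >= 2")
    p1, p2 = c1 / n1, c2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst_hudson(counts: Sequence[tuple[int, int]]) -> float:
    """Hudson-style Fst (1 - Hw/Hb) from per-population allele counts.

    For more than two populations the estimate is the ratio of the
    averaged pair numerators to the averaged pair denominators over all
    population pairs.  Negative estimates are preserved.
    """
    if len(counts) < 2:
        raise InvalidInputError("need >= 2 populations")
    num = den = 0.0
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):
            n, d = _hudson_pair_components(*counts[i], *counts[j])
            num += n
            den += d
    if den == 0.0:
        return 0.0
    return num / den


def fst_hudson_multilocus(
    loci: Iterable[Sequence[tuple[int, int]]],
) -> float:
    """Genome-wide Hudson Fst: ratio of summed N to summed D over loci and pairs."""
    num = den = 0.0
    n_loci = 0
    for counts in loci:
        n_loci += 1
        for i in range(len(counts)):
            for j in range(i + 1, len(counts)):
                n, d = _hudson_pair_components(*counts[i], *counts[j])
                num += n
                den += d
    if n_loci == 0 or den == 0.0:
        raise InvalidInputError("no informative loci")
    return num / den


def _wc_components(counts: Sequence[tuple[int, int]]) -> tuple[float, float]:
    """Weir-Cockerham (1984) among/total variance components (a, a+b) for one
    biallelic locus, allele-frequency (haploid-sample) form.

    Returns (among-population component, total), such that theta = a / total.
    """
    r = len(counts)
    if r < 2:
        raise InvalidInputError("need >= 2 populations")
    n = np.array([t for _, t in counts], dtype=float)
    if np.any(n < 2):
        raise InvalidInputError("each population needs a total allele count >= 2")
    p = np.array([c for c, _ in counts], dtype=float) / n
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    h = pbar * (1 - pbar)
    a = (nbar / nc) * (s2 - (h - s2 * (r - 1) / r) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (h - s2 * (r - 1) / r)
    return a, a + b


def fst_weir_cockerham(counts: Sequence[tuple[int, int]]) -> float:
    """Weir & Cockerham theta-hat for one biallelic locus across k populations."""
    a, total = _wc_components(counts)
    if total == 0.0:
        return 0.0
    return a / total


def fst_weir_cockerham_multilocus(
    loci: Iterable[Sequence[tuple[int, int]]],
) -> float:
    """Genome-wide Weir-Cockerham theta: ratio of summed variance components."""
    num = den = 0.0
    n_loci = 0
    for counts in loci:
        n_loci += 1
        a, total = _wc_components(counts)
        num += a
        den += total
    if n_loci == 0 or den == 0.0:
        raise InvalidInputError("no informative loci")
    return num / den


def fst(
    counts: Sequence[tuple[int, int]],
    estimator: str = "hudson",
    snp_id: str = "",
) -> FstResult:
    """Single-locus Fst under a named estimator."""
    if estimator == "hudson":
        value = fst_hudson(counts)
    elif estimator == "weir_cockerham":
        value = fst_weir_cockerham(counts)
    elif estimator == "wright_variance":
        value = fst_wright([c / t for c, t in counts])
    else:
        raise InvalidInputError(f"unknown estimator {estimator!r}; choose from {FST_ESTIMATORS}")
    return FstResult(estimator=estimator, value=value, snp_id=snp_id)


def empirical_pfst(observed: float, null_values: Sequence[float]) -> float:
    """Add-one upper-tail empirical percentile of an observed Fst.

    P = (1 + #{null >= observed}) / (N + 1); always in (0, 1] and
    monotone non-increasing in the observed value.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise InvalidInputError("empty null distribution")
    return float((1 + (null >= observed).sum()) / (null.size + 1))


def differentiation_filter(
    results: Sequence[FstResult], fst_threshold: float
) -> list[FstResult]:
    """Keep results with Fst strictly above the threshold, sorted descending.

    Ties are broken by SNP id (lexicographic) for a stable report order.
    """
    kept = [r for r in results if r.value > fst_threshold]
    kept.sort(key=lambda r: (-r.value, r.snp_id))
    return kept
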