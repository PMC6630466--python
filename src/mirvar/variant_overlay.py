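"""Target/near-target SNP pairs and their polarization.

A biallelic SNP inside a 3'UTR forms a *target/near-target pair* for a
microRNA family when exactly one of its two alleles completes a seed-match
site overlapping the SNP position and the other allele does not.  The
site-forming allele is the *target allele*.

Each pair is polarized against two references:

* the ancestral allele (1000 Genomes style ``AA`` annotation) — is the
  target allele ancestral or derived?
* the reference genome — does the reference carry the target allele?

giving four classes (plus ``unpolarized`` when the ancestral state is
unknown)::

    ancestral = target,     target not in ref  ->  ancestral_target_lost
    ancestral = non-target, target in ref      ->  derived_target_gained
    ancestral = target,     target in ref      ->  ancestral_target_in_ref
    ancestral = non-target, target not in ref  ->  derived_nontarget_in_ref

``ancestral_target_lost`` sites are invisible to target prediction run on
the reference sequence although the target allele predates the human
expansion — the reference-genome bias this package quantifies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .errors import InvalidInputError, ReferenceMismatchError
from .seed_match import (
    DEFAULT_TARGET_SITE_TYPES,
    SITE_TYPE_PRECEDENCE,
    MatureMiRNA,
    SeedSite,
    UTRSequence,
    find_seed_sites,
)

logger = logging.getLogger(__name__)

POLARIZATION_CLASSES = (
    "ancestral_target_lost",
    "derived_target_gained",
    "ancestral_target_in_ref",
    "derived_nontarget_in_ref",
    "unpolarized",
)

HIGH_THROUGHPUT_EVIDENCE = frozenset({"PAR-CLIP", "HITS-CLIP"})


@dataclass(frozen=True)
class BiallelicSNP:
    """A biallelic SNV located on a UTR (0-based offset, sense strand).

    ``counts`` maps sampled population -> (target-relevant allele count,
    total allele count); populations aggregate to super-populations via
    the sample panel.  ``ancestral_allele`` is a single base or
    ``"unknown"``.
    """

    snp_id: str
    utr_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    ancestral_allele: str = "unknown"
    counts: Mapping[str, tuple[int, int]] | None = None

    def __post_init__(self):
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise InvalidInputError(f"{self.snp_id}: alleles must be single bases (SNV)")
        if self.ref_allele == self.alt_allele:
            raise InvalidInputError(f"{self.snp_id}: REF and ALT are identical")
        aa = self.ancestral_allele
        if aa != "unknown" and aa not in (self.ref_allele, self.alt_allele):
            object.__setattr__(self, "ancestral_allele", "unknown")


@dataclass(frozen=True)
class TargetPair:
    """A SNP whose alleles differ in target-site status for one family."""

    snp: BiallelicSNP
    family_key: str
    site_type: str
    site_start: int
    site_end: int
    target_allele: str
    nontarget_allele: str
    gene: str = ""
    mirnas: tuple[str, ...] = ()
    polarization: str = "unpolarized"
    target_in_reference: bool = False
    experimentally_detected: bool = False


def apply_allele(utr: UTRSequence, snp: BiallelicSNP, allele: str) -> str:
    """Return the UTR sequence with ``allele`` substituted at the SNP position.

    The UTR base at the SNP offset must equal the REF allele; a mismatch
    raises :class:`ReferenceMismatchError` naming the SNP.
    """
    if allele not in (snp.ref_allele, snp.alt_allele):
        raise InvalidInputError(f"{snp.snp_id}: allele {allele!r} is neither REF nor ALT")
    if not 0 <= snp.pos < len(utr.seq):
        raise InvalidInputError(f"{snp.snp_id}: position {snp.pos} outside UTR {utr.utr_id}")
    found = utr.seq[snp.pos]
    if found != snp.ref_allele:
        raise ReferenceMismatchError(snp.snp_id, snp.pos, snp.ref_allele, found)
    return utr.seq[: snp.pos] + allele + utr.seq[snp.pos + 1 :]


def _overlapping_sites(
    utr: UTRSequence,
    seq: str,
    snp_pos: int,
    mirna: MatureMiRNA,
    site_types: Iterable[str],
    members: Sequence[str] | None,
) -> list[SeedSite]:
    """Sites of the family on ``seq`` whose half-open interval contains snp_pos."""
    variant_utr = UTRSequence(utr.utr_id, utr.gene, seq)
    sites = find_seed_sites(variant_utr, mirna, site_types, family_members=members)
    return [s for s in sites if s.start <= snp_pos < s.end]


def classify_pair(
    utr: UTRSequence,
    snp: BiallelicSNP,
    mirna: MatureMiRNA,
    target_site_types: Iterable[str] = DEFAULT_TARGET_SITE_TYPES,
    family_members: Sequence[str] | None = None,
) -> TargetPair | None:
    """Decide whether a SNP toggles a site of this microRNA family.

    Both allele-substituted sequences are scanned for sites overlapping
    the SNP position.  A :class:`TargetPair` is returned iff exactly one
    allele carries at least one overlapping site of an allowed type; the
    target allele's most specific overlapping site (leftmost on ties)
    supplies the coordinates.  ``None`` means the SNP is site-neutral for
    this family (neither or both alleles form a site).
    """
    ref_seq = apply_allele(utr, snp, snp.ref_allele)
    alt_seq = apply_allele(utr, snp, snp.alt_allele)
    ref_sites = _overlapping_sites(utr, ref_seq, snp.pos, mirna, target_site_types, family_members)
    alt_sites = _overlapping_sites(utr, alt_seq, snp.pos, mirna, target_site_types, family_members)

    if bool(ref_sites) == bool(alt_sites):
        if ref_sites and alt_sites:
            logger.info(
                "%s: both alleles retain a %s-family site; not a target/near-target pair",
                snp.snp_id,
                mirna.family_key,
            )
        return None

    if ref_sites:
        target_allele, nontarget_allele, sites = snp.ref_allele, snp.alt_allele, ref_sites
    else:
        target_allele, nontarget_allele, sites = snp.alt_allele, snp.ref_allele, alt_sites
    best = min(sites, key=lambda s: (SITE_TYPE_PRECEDENCE[s.site_type], s.start))

    pair = TargetPair(
        snp=snp,
        family_key=mirna.family_key,
        site_type=best.site_type,
        site_start=best.start,
        site_end=best.end,
        target_allele=target_allele,
        nontarget_allele=nontarget_allele,
        gene=utr.gene,
        mirnas=best.mirnas,
        target_in_reference=(target_allele == snp.ref_allele),
    )
    return replace(pair, polarization=polarize(pair))


def polarize(pair: TargetPair) -> str:
    """Polarization class of a pair from ancestral state and reference status."""
    aa = pair.snp.ancestral_allele
    if aa == "unknown":
        return "unpolarized"
    target_is_ancestral = aa == pair.target_allele
    if target_is_ancestral and not pair.target_in_reference:
        return "ancestral_target_lost"
    if not target_is_ancestral and pair.target_in_reference:
        return "derived_target_gained"
    if target_is_ancestral and pair.target_in_reference:
        return "ancestral_target_in_ref"
    return "derived_nontarget_in_ref"


def global_target_frequency(pair: TargetPair) -> float:
    """Pooled target-allele frequency over all sampled populations."""
    if not pair.snp.counts:
        raise InvalidInputError(f"{pair.snp.snp_id}: no allele counts attached")
    num = sum(c for c, _ in pair.snp.counts.values())
    den = sum(t for _, t in pair.snp.counts.values())
    if den == 0:
        raise InvalidInputError(f"{pair.snp.snp_id}: zero total allele count")
    freq = num / den
    # counts are stored for the ALT allele; express for the target allele
    if pair.target_allele == pair.snp.ref_allele:
        freq = 1.0 - freq
    return freq


def frequency_filter(
    pairs: Iterable[TargetPair], lower: float = 0.01, upper: float = 0.99
) -> list[TargetPair]:
    """Keep pairs whose global target-allele frequency is in [lower, upper].

    Both boundaries are inclusive: the analysis window covers segregating
    alleles between 1% and 99%.
    """
    kept = []
    for pair in pairs:
        f = global_target_frequency(pair)
        if lower <= f <= upper:
            kept.append(pair)
        else:
            logger.info("%s: global target frequency %.4f outside [%g, %g]",
                        pair.snp.snp_id, f, lower, upper)
    return kept


def join_interactions(
    pairs: Iterable[TargetPair],
    interactions: Iterable[tuple[str, str, set[str]]],
    evidence_whitelist: frozenset[str] = HIGH_THROUGHPUT_EVIDENCE,
) -> list[TargetPair]:
    """Flag pairs supported by high-throughput interaction evidence.

    ``interactions`` rows are (mature name, gene, evidence-method set).
    A pair is flagged iff some family member's name and the pair's gene
    co-occur in a row whose evidence intersects the whitelist (default
    PAR-CLIP / HITS-CLIP).
    """
    supported: set[tuple[str, str]] = set()
    for mirna, gene, evidence in interactions:
        if evidence & evidence_whitelist:
            supported.add((mirna, gene))
    out = []
    for pair in pairs:
        flagged = any((m, pair.gene) in supported for m in pair.mirnas)
        out.append(replace(pair, experimentally_detected=flagged))
    return out
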