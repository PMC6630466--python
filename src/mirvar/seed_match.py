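"""Canonical microRNA seed-match detection in 3'UTR sequences.

A mature microRNA recognises its targets chiefly through its *seed*,
nucleotides 2-8 counted from the 5' end of the mature sequence.  A
transcript carries a canonical site when it contains the DNA reverse
complement of (part of) the seed.  Four site classes are distinguished,
in decreasing order of specificity:

========  =======================================================
8mer      reverse complement of seed 2-8 followed by a literal A
7mer-m8   reverse complement of seed 2-8
7mer-A1   reverse complement of seed 2-7 followed by a literal A
6mer      reverse complement of seed 2-7
========  =======================================================

The trailing A sits opposite mature position 1 and is matched as a
literal adenosine in the UTR, never as a complementary base.  Mature
microRNAs that share a seed form a *family*: they hit the same sites and
are interchangeable for site accounting.

UTRs are held in the DNA alphabet in transcript (mRNA-sense) orientation;
microRNA sequences are RNA.  All matching happens after mapping U->T on
the motifs.  ``N`` never matches.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import AlphabetError, DuplicateIdentifierError, InvalidInputError

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGTN")

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
#: most specific first; scanning reports only the top requested type per anchor
SITE_TYPE_PRECEDENCE = {t: i for i, t in enumerate(SITE_TYPES)}
#: default "target" classes; 6mer sites are opt-in
DEFAULT_TARGET_SITE_TYPES = frozenset({"8mer", "7mer-m8", "7mer-A1"})

_RC_DNA = str.maketrans("ACGT", "TGCA")


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_RC_DNA)[::-1]


def derive_seed(mature_seq: str) -> str:
    """Return the 7-nt seed: positions 2-8 (1-based) of a mature RNA sequence.

    Raises
    ------
    InvalidInputError
        If the mature sequence is shorter than 8 nt.
    AlphabetError
        If the sequence contains characters outside A/C/G/U.
    """
    seq = mature_seq.upper()
    if not set(seq) <= RNA_ALPHABET:
        bad = sorted(set(seq) - RNA_ALPHABET)
        raise AlphabetError(f"non-RNA characters in mature sequence: {bad}")
    if len(seq) < 8:
        raise InvalidInputError(
            f"mature sequence must be >= 8 nt to define a seed, got {len(seq)}"
        )
    return seq[1:8]


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature microRNA with its derived seed.

    ``family_key`` is the seed itself: two matures belong to the same
    family exactly when their seeds are identical.
    """

    name: str
    mature_seq: str
    seed: str = field(init=False)
    family_key: str = field(init=False)

    def __post_init__(self):
        seq = self.mature_seq.upper()
        object.__setattr__(self, "mature_seq", seq)
        seed = derive_seed(seq)
        object.__setattr__(self, "seed", seed)
        object.__setattr__(self, "family_key", seed)


@dataclass(frozen=True)
class UTRSequence:
    """A 3'UTR in transcript sense, DNA alphabet (A/C/G/T/N)."""

    utr_id: str
    gene: str
    seq: str

    def __post_init__(self):
        seq = self.seq.upper()
        if not set(seq) <= DNA_ALPHABET:
            bad = sorted(set(seq) - DNA_ALPHABET)
            raise AlphabetError(f"non-DNA characters in UTR {self.utr_id}: {bad}")
        object.__setattr__(self, "seq", seq)


@dataclass(frozen=True)
class SeedSite:
    """One canonical seed-match occurrence on a UTR (0-based half-open)."""

    utr_id: str
    start: int
    end: int
    site_type: str
    family_key: str
    mirnas: tuple[str, ...] = ()


def site_motifs(seed: str) -> dict[str, str]:
    """DNA motifs recognised by a 7-nt seed, one per canonical site type.

    The 7mer-m8 motif is the DNA reverse complement of the full seed;
    the 6mer motif drops its 5'-most base (the m8 pairing position);
    7mer-A1 and 8mer append a literal ``A``.
    """
    s = seed.upper()
    if len(s) != 7:
        raise InvalidInputError(f"seed must be 7 nt, got {len(s)}")
    if not set(s) <= RNA_ALPHABET:
        raise AlphabetError(f"non-RNA characters in seed: {sorted(set(s) - RNA_ALPHABET)}")
    core7 = _revcomp_dna(s.replace("U", "T"))
    core6 = core7[1:]
    return {
        "8mer": core7 + "A",
        "7mer-m8": core7,
        "7mer-A1": core6 + "A",
        "6mer": core6,
    }


def _anchor(start: int, site_type: str) -> int:
    """Start of the shared seed-2..7 core match for a site of this type.

    All four site types contain the reverse complement of seed positions
    2-7; 8mer and 7mer-m8 carry one extra 5' base, so their core begins
    one position into the motif.  Precedence is resolved per core anchor.
    """
    return start + 1 if site_type in ("8mer", "7mer-m8") else start


def find_seed_sites(
    utr: UTRSequence,
    mirna: MatureMiRNA,
    site_types: Iterable[str] = DEFAULT_TARGET_SITE_TYPES,
    family_members: Sequence[str] | None = None,
) -> list[SeedSite]:
    """Find every canonical site for a microRNA (family) in one UTR.

    Every exact occurrence of each requested motif is located (overlaps
    allowed); where one locus supports several site types, only the most
    specific requested type is reported per core anchor
    (8mer > 7mer-m8 > 7mer-A1 > 6mer).  ``N`` never matches.  The result
    is sorted by (start, site_type).
    """
    requested = set(site_types)
    unknown = requested - set(SITE_TYPES)
    if unknown:
        raise InvalidInputError(f"unknown site types: {sorted(unknown)}")
    motifs = site_motifs(mirna.seed)
    seq = utr.seq
    best_at_anchor: dict[int, tuple[int, int, str]] = {}
    for site_type in SITE_TYPES:  # most specific first
        if site_type not in requested:
            continue
        motif = motifs[site_type]
        rank = SITE_TYPE_PRECEDENCE[site_type]
        start = seq.find(motif)
        while start != -1:
            a = _anchor(start, site_type)
            held = best_at_anchor.get(a)
            if held is None or rank < held[1]:
                best_at_anchor[a] = (start, rank, site_type)
            start = seq.find(motif, start + 1)
    members = tuple(family_members) if family_members is not None else (mirna.name,)
    sites = [
        SeedSite(
            utr_id=utr.utr_id,
            start=start,
            end=start + len(motifs[site_type]),
            site_type=site_type,
            family_key=mirna.family_key,
            mirnas=members,
        )
        for start, _rank, site_type in best_at_anchor.values()
    ]
    sites.sort(key=lambda s: (s.start, s.site_type))
    return sites


def group_families(mirnas: Sequence[MatureMiRNA]) -> dict[str, list[str]]:
    """Partition mature microRNAs into seed families.

    Returns a mapping family_key (= seed) -> mature names, preserving
    input order within each family.  Duplicate mature names are an error.
    """
    seen: set[str] = set()
    families: dict[str, list[str]] = {}
    for m in mirnas:
        if m.name in seen:
            raise DuplicateIdentifierError(f"duplicate mature microRNA name: {m.name}")
        seen.add(m.name)
        families.setdefault(m.family_key, []).append(m.name)
    return families


def expression_threshold_top_fraction(
    expression: Mapping[str, float], fraction: float = 0.5
) -> float:
    """Expression cut-off retaining the top ``fraction`` of the table.

    The default notion of "highly expressed" is the upper half of the
    provided expression table (median threshold).
    """
    if not expression:
        raise InvalidInputError("empty expression table")
    import numpy as np

    values = np.asarray(sorted(expression.values()))
    return float(np.quantile(values, 1.0 - fraction))


def filter_expressed(
    mirnas: Sequence[MatureMiRNA],
    expression: Mapping[str, float],
    threshold: float,
) -> list[MatureMiRNA]:
    """Keep microRNAs whose expression is at or above ``threshold``.

    Matures absent from the expression table are dropped with a warning;
    negative expression values are rejected.
    """
    for name, value in expression.items():
        if value < 0:
            raise InvalidInputError(f"negative expression for {name}: {value}")
    kept = []
    for m in mirnas:
        if m.name not in expression:
            logger.warning("microRNA %s absent from expression table; dropped", m.name)
            continue
        if expression[m.name] >= threshold:
            kept.append(m)
    return kept


def sites_to_bed(sites: Iterable[SeedSite]) -> str:
    """Render sites as BED6 text (name = family_key:site_type, strand +)."""
    lines = [
        f"{s.utr_id}\t{s.start}\t{s.end}\t{s.family_key}:{s.site_type}\t0\t+"
        for s in sites
    ]
    return "\n".join(lines) + ("\n" if lines else "")
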