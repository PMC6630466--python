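"""Ground-truthed synthetic cohorts for every pipeline stage.

The generator emulates the data a population-scale resequencing project
provides around polymorphic microRNA target sites:

* random 3'UTR sequences with seed-match motifs planted at recorded,
  non-overlapping positions;
* biallelic SNPs of three classes — *site-disrupting* (the reference
  carries the site, the alternative allele abolishes it), *site-creating*
  (the reference carries a broken site, the alternative allele completes
  it) and *site-neutral* (neither allele touches any family's site);
  every planted SNP is verified against the scanner itself, run in
  reverse, before it is accepted;
* population structure under the Balding-Nichols model: each sampled
  population's allele frequency is an independent Beta draw around an
  ancestral frequency, parameterised by F (the expected Fst);
* Hardy-Weinberg diploid genotypes sampled binomially within populations;
* ancestral-allele annotations assigned by a configurable rule, and a
  configurable latitude gradient in the target-allele frequency for
  designated SNPs.

Everything is deterministic under ``rng_seed``: the same configuration
produces byte-identical fixture files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .errors import CapacityError, InvalidInputError
from .seed_match import (
    DEFAULT_TARGET_SITE_TYPES,
    MatureMiRNA,
    UTRSequence,
    site_motifs,
)
from .variant_overlay import BiallelicSNP, classify_pair
from .popgen import SUPER_POPULATIONS

BASES = "ACGT"
_SITE_PADDING = 12  # keep planted loci independent of each other


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort."""

    rng_seed: int = 0
    n_utrs: int = 20
    utr_length: int = 400
    n_mirnas: int = 8
    mirna_length: int = 22
    n_decoy_mirnas: int = 0  # low-expression matures, removed by the filter
    n_pops: int = 10
    samples_per_pop: int = 30
    F: float = 0.15
    n_disrupting: int = 20
    n_creating: int = 10
    n_neutral: int = 20
    n_latitude_snps: int = 0
    lat_intercept: float = 0.8
    lat_slope: float = -0.01
    lat_noise_sd: float = 0.02
    #: probability that the ancestral allele is the target allele
    ancestral_target_prob: float = 0.5
    #: probability that the ancestral state is emitted as unknown
    ancestral_unknown_prob: float = 0.0
    #: probability that the recorded ancestral allele is flipped (mislabeled)
    ancestral_mislabel_prob: float = 0.0
    #: ancestral-frequency prior: Beta(0.8, 0.8) truncated to this window
    p_bar_bounds: tuple[float, float] = (0.05, 0.95)
    #: fraction of planted pairs given a high-throughput interaction row
    interaction_fraction: float = 0.5
    #: AFR-skewed frequency profile for site-creating, ancestral-target SNPs
    afr_skew: bool = False
    target_site_types: frozenset = DEFAULT_TARGET_SITE_TYPES

    def __post_init__(self):
        if not 0.0 < self.F < 1.0:
            raise InvalidInputError(f"F must be in (0, 1), got {self.F}")
        lo, hi = self.p_bar_bounds
        if not 0.0 < lo < hi < 1.0:
            raise InvalidInputError(f"bad ancestral-frequency bounds {self.p_bar_bounds}")


@dataclass(frozen=True)
class PopulationInfo:
    name: str
    super_pop: str
    latitude: float
    longitude: float
    samples: tuple[str, ...]


@dataclass
class Simulation:
    """In-memory synthetic cohort plus its ground truth."""

    config: SimConfig
    utrs: list[UTRSequence]
    mirnas: list[MatureMiRNA]
    decoys: list[MatureMiRNA]
    populations: list[PopulationInfo]
    records: list[mio.SNPRecord]
    truth: pd.DataFrame
    expression: dict[str, float]
    interactions: list[tuple[str, str, set[str]]]

    @property
    def samples(self) -> list[str]:
        return [s for p in self.populations for s in p.samples]


def simulate_frequencies(
    p_bar: float, F: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies around an ancestral p_bar.

    Each population's frequency is an independent draw from
    Beta(p_bar (1-F)/F, (1-p_bar)(1-F)/F): expectation p_bar, variance
    F p_bar (1-p_bar), expected Fst approximately F.
    """
    if not 0.0 < p_bar < 1.0:
        raise InvalidInputError(f"p_bar must be in (0, 1), got {p_bar}")
    if not 0.0 < F < 1.0:
        raise InvalidInputError(f"F must be in (0, 1), got {F}")
    scale = (1.0 - F) / F
    return rng.beta(p_bar * scale, (1.0 - p_bar) * scale, size=n_pops)


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _invent_mirnas(rng: np.random.Generator, n: int, length: int, prefix: str) -> list[MatureMiRNA]:
    """Random mature sequences with pairwise distinct seeds."""
    mirnas: list[MatureMiRNA] = []
    seeds: set[str] = set()
    attempts = 0
    while len(mirnas) < n:
        attempts += 1
        if attempts > 100 * n:
            raise CapacityError("cannot invent enough distinct-seed microRNAs")
        seq = _random_seq(rng, length, "ACGU")
        m = MatureMiRNA(name=f"{prefix}-{len(mirnas) + 1}-5p", mature_seq=seq)
        if m.seed in seeds:
            continue
        seeds.add(m.seed)
        mirnas.append(m)
    return mirnas


def _make_populations(config: SimConfig, rng: np.random.Generator) -> list[PopulationInfo]:
    """Sampled populations round-robin over the five super-populations."""
    pops = []
    counter = {sp: 0 for sp in SUPER_POPULATIONS}
    for i in range(config.n_pops):
        sp = SUPER_POPULATIONS[i % len(SUPER_POPULATIONS)]
        counter[sp] += 1
        name = f"{sp}{counter[sp]}"
        lat = float(np.round(rng.uniform(-35.0, 55.0), 2))
        lon = float(np.round(rng.uniform(-120.0, 120.0), 2))
        samples = tuple(
            f"{name}_S{j:03d}" for j in range(config.samples_per_pop)
        )
        pops.append(PopulationInfo(name, sp, lat, lon, samples))
    return pops


def _verify_snp(
    utr: UTRSequence,
    snp: BiallelicSNP,
    mirnas: Sequence[MatureMiRNA],
    planted_family: str | None,
    target_allele: str | None,
    site_types,
) -> bool:
    """Check a candidate SNP against the scanner used in reverse.

    A planted pair SNP must toggle a site for exactly its family (with
    the intended target allele) and for no other family; a neutral SNP
    must toggle no family's site.
    """
    for m in mirnas:
        pair = classify_pair(utr, snp, m, site_types)
        if m.family_key == planted_family:
            if pair is None or pair.target_allele != target_allele:
                return False
        elif pair is not None:
            return False
    return planted_family is None or any(
        m.family_key == planted_family for m in mirnas
    )


class _Placer:
    """Tracks occupied intervals per UTR to keep planted loci apart."""

    def __init__(self, utrs: Sequence[UTRSequence]):
        self.seqs = {u.utr_id: list(u.seq) for u in utrs}
        self.genes = {u.utr_id: u.gene for u in utrs}
        self.occupied: dict[str, list[tuple[int, int]]] = {u.utr_id: [] for u in utrs}

    def free_slot(self, utr_id: str, start: int, width: int) -> bool:
        lo, hi = start - _SITE_PADDING, start + width + _SITE_PADDING
        return all(e <= lo or s >= hi for s, e in self.occupied[utr_id])

    def reserve(self, utr_id: str, start: int, width: int) -> None:
        self.occupied[utr_id].append((start, start + width))

    def write(self, utr_id: str, start: int, text: str) -> None:
        self.seqs[utr_id][start : start + len(text)] = list(text)

    def utr(self, utr_id: str) -> UTRSequence:
        return UTRSequence(utr_id, self.genes[utr_id], "".join(self.seqs[utr_id]))


def plant_target_pairs(
    utrs: Sequence[UTRSequence],
    mirnas: Sequence[MatureMiRNA],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[UTRSequence], list[dict]]:
    """Embed motifs and SNP specs; every spec is scanner-verified.

    Returns the modified UTRs and one spec dict per SNP with keys
    ``utr_id, pos, ref, alt, true_class, family_key, target_allele,
    target_in_reference``.  Site-creating SNPs leave the broken motif in
    the emitted (reference) UTR, so their target allele is the ALT
    allele and absent from the reference sequence.
    """
    placer = _Placer(utrs)
    utr_ids = [u.utr_id for u in utrs]
    site_types = config.target_site_types
    specs: list[dict] = []

    def plant_pair(true_class: str, max_attempts: int = 4000) -> dict:
        creating = true_class in ("creating", "latitude")
        for _ in range(max_attempts):
            mirna = mirnas[rng.integers(0, len(mirnas))]
            motifs = site_motifs(mirna.seed)
            allowed = sorted(site_types & set(motifs))
            site_type = allowed[rng.integers(0, len(allowed))]
            motif = motifs[site_type]
            utr_id = utr_ids[rng.integers(0, len(utr_ids))]
            max_start = len(placer.seqs[utr_id]) - len(motif) - _SITE_PADDING
            if max_start <= _SITE_PADDING:
                continue
            start = int(rng.integers(_SITE_PADDING, max_start))
            if not placer.free_slot(utr_id, start, len(motif)):
                continue
            offset = int(rng.integers(0, len(motif)))
            pos = start + offset
            site_base = motif[offset]
            other = [b for b in BASES if b != site_base]
            broken_base = other[rng.integers(0, len(other))]
            # reference sequence carries the intact motif for disrupting
            # SNPs and the broken one for creating SNPs
            snapshot = placer.seqs[utr_id][start : start + len(motif)]
            ref_window = list(motif)
            if creating:
                ref_window[offset] = broken_base
            placer.write(utr_id, start, "".join(ref_window))
            ref, alt = (site_base, broken_base) if not creating else (broken_base, site_base)
            snp = BiallelicSNP(
                snp_id="pending", utr_id=utr_id, pos=pos, ref_allele=ref, alt_allele=alt
            )
            if _verify_snp(
                placer.utr(utr_id), snp, mirnas, mirna.family_key, site_base, site_types
            ):
                placer.reserve(utr_id, start, len(motif))
                return {
                    "utr_id": utr_id,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "true_class": true_class,
                    "family_key": mirna.family_key,
                    "site_type": site_type,
                    "target_allele": site_base,
                    "target_in_reference": not creating,
                }
            placer.seqs[utr_id][start : start + len(motif)] = snapshot  # undo
        raise CapacityError(f"cannot place a {true_class} SNP after {max_attempts} attempts")

    def plant_neutral(max_attempts: int = 4000) -> dict:
        for _ in range(max_attempts):
            utr_id = utr_ids[rng.integers(0, len(utr_ids))]
            seq = placer.seqs[utr_id]
            pos = int(rng.integers(_SITE_PADDING, len(seq) - _SITE_PADDING))
            if not placer.free_slot(utr_id, pos, 1):
                continue
            ref = seq[pos]
            alt = [b for b in BASES if b != ref][rng.integers(0, 3)]
            snp = BiallelicSNP(
                snp_id="pending", utr_id=utr_id, pos=pos, ref_allele=ref, alt_allele=alt
            )
            if _verify_snp(placer.utr(utr_id), snp, mirnas, None, None, site_types):
                placer.reserve(utr_id, pos, 1)
                return {
                    "utr_id": utr_id,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "true_class": "neutral",
                    "family_key": "",
                    "site_type": "",
                    "target_allele": "",
                    "target_in_reference": False,
                }
        raise CapacityError(f"cannot place a neutral SNP after {max_attempts} attempts")

    for _ in range(config.n_disrupting):
        specs.append(plant_pair("disrupting"))
    for _ in range(config.n_creating):
        specs.append(plant_pair("creating"))
    for _ in range(config.n_latitude_snps):
        specs.append(plant_pair("latitude"))
    for _ in range(config.n_neutral):
        specs.append(plant_neutral())

    return [placer.utr(uid) for uid in utr_ids], specs


def _truncated_beta(rng: np.random.Generator, a: float, b: float,
                    lo: float, hi: float) -> float:
    while True:
        x = rng.beta(a, b)
        if lo <= x <= hi:
            return float(x)


def _draw_frequencies(
    spec: dict,
    config: SimConfig,
    populations: Sequence[PopulationInfo],
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """Per-population target-allele frequencies for one SNP spec."""
    lo, hi = config.p_bar_bounds
    if spec["true_class"] == "latitude":
        freqs = np.array(
            [
                np.clip(
                    config.lat_intercept
                    + config.lat_slope * abs(p.latitude)
                    + rng.normal(0.0, config.lat_noise_sd),
                    0.02,
                    0.98,
                )
                for p in populations
            ]
        )
        return float(freqs.mean()), freqs
    if config.afr_skew and spec["true_class"] == "creating":
        # high target frequency in African populations, low elsewhere —
        # the profile of an ancestral site lost outside Africa
        freqs = np.array(
            [
                np.clip(
                    rng.normal(0.75 if p.super_pop == "AFR" else 0.08, 0.04),
                    0.02,
                    0.98,
                )
                for p in populations
            ]
        )
        return float(freqs.mean()), freqs
    p_bar = _truncated_beta(rng, 0.8, 0.8, lo, hi)
    return p_bar, simulate_frequencies(p_bar, config.F, len(populations), rng)


def _assign_ancestral(spec: dict, config: SimConfig, rng: np.random.Generator) -> str:
    if spec["true_class"] == "neutral" or rng.random() < config.ancestral_unknown_prob:
        return "unknown"
    target, nontarget = spec["target_allele"], (
        spec["alt"] if spec["target_allele"] == spec["ref"] else spec["ref"]
    )
    if spec["true_class"] in ("creating", "latitude") and config.afr_skew:
        aa = target  # ancestral target lost out of Africa, by construction
    else:
        aa = target if rng.random() < config.ancestral_target_prob else nontarget
    if config.ancestral_mislabel_prob and rng.random() < config.ancestral_mislabel_prob:
        aa = nontarget if aa == target else target
    return aa


def simulate(config: SimConfig) -> Simulation:
    """Build a complete synthetic cohort under one configuration."""
    rng = np.random.default_rng(config.rng_seed)
    mirnas = _invent_mirnas(rng, config.n_mirnas, config.mirna_length, "mir-sim")
    decoys = _invent_mirnas(rng, config.n_decoy_mirnas, config.mirna_length, "mir-decoy")
    base_utrs = [
        UTRSequence(f"UTR{i + 1:03d}", f"GENE{i + 1:03d}", _random_seq(rng, config.utr_length))
        for i in range(config.n_utrs)
    ]
    utrs, specs = plant_target_pairs(base_utrs, mirnas, config, rng)
    populations = _make_populations(config, rng)

    records: list[mio.SNPRecord] = []
    truth_rows: list[dict] = []
    for idx, spec in enumerate(specs):
        snp_id = f"rs{1000000 + idx}"
        p_bar, target_freqs = _draw_frequencies(spec, config, populations, rng)
        if spec["true_class"] == "neutral":
            target_for_freq = spec["alt"]  # bookkeeping: frequencies follow ALT
        else:
            target_for_freq = spec["target_allele"]
        alt_freqs = (
            target_freqs
            if target_for_freq == spec["alt"]
            else 1.0 - target_freqs
        )
        aa = _assign_ancestral(spec, config, rng)
        genotypes: dict[str, tuple[int, int]] = {}
        for p, af in zip(populations, alt_freqs):
            draws = rng.random((len(p.samples), 2)) < af
            for s, (a1, a2) in zip(p.samples, draws):
                genotypes[s] = (int(a1), int(a2))
        snp = BiallelicSNP(
            snp_id=snp_id,
            utr_id=spec["utr_id"],
            pos=spec["pos"],
            ref_allele=spec["ref"],
            alt_allele=spec["alt"],
            ancestral_allele=aa,
        )
        records.append(mio.SNPRecord(snp=snp, genotypes=genotypes))

        if spec["true_class"] == "neutral":
            true_pol = ""
        elif aa == "unknown":
            true_pol = "unpolarized"
        else:
            tir = spec["target_in_reference"]
            if aa == spec["target_allele"]:
                true_pol = "ancestral_target_in_ref" if tir else "ancestral_target_lost"
            else:
                true_pol = "derived_target_gained" if tir else "derived_nontarget_in_ref"
        row = {
            "snp_id": snp_id,
            "utr_id": spec["utr_id"],
            "pos": spec["pos"],
            "ref": spec["ref"],
            "alt": spec["alt"],
            "true_class": "pair" if spec["true_class"] != "neutral" else "neutral",
            "planted_as": spec["true_class"],
            "family_key": spec["family_key"],
            "site_type": spec["site_type"],
            "target_allele": spec["target_allele"],
            "target_in_reference": spec["target_in_reference"],
            "ancestral_allele": aa,
            "true_polarization": true_pol,
            "p_bar": round(p_bar, 6),
        }
        for p, f in zip(populations, target_freqs):
            row[f"freq_{p.name}"] = round(float(f), 6)
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)

    expression = {m.name: float(np.round(rng.uniform(10.0, 100.0), 3)) for m in mirnas}
    expression.update(
        {m.name: float(np.round(rng.uniform(0.001, 0.01), 6)) for m in decoys}
    )

    by_family: dict[str, str] = {m.family_key: m.name for m in mirnas}
    gene_of = {u.utr_id: u.gene for u in utrs}
    interactions: list[tuple[str, str, set[str]]] = []
    for row in truth_rows:
        if row["true_class"] != "pair":
            continue
        if rng.random() < config.interaction_fraction:
            name = by_family[row["family_key"]]
            evidence = {"HITS-CLIP"} if rng.random() < 0.5 else {"PAR-CLIP", "HITS-CLIP"}
            interactions.append((name, gene_of[row["utr_id"]], evidence))
        elif rng.random() < 0.2:
            interactions.append(
                (by_family[row["family_key"]], gene_of[row["utr_id"]], {"luciferase"})
            )

    return Simulation(
        config=config,
        utrs=utrs,
        mirnas=mirnas,
        decoys=decoys,
        populations=populations,
        records=records,
        truth=truth,
        expression=expression,
        interactions=interactions,
    )


def emit_fixtures(sim: Simulation, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as the text fixtures the parsers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirnas": out / "mirnas.fa",
        "utrs": out / "utrs.fa",
        "vcf": out / "snps.vcf",
        "panel": out / "panel.tsv",
        "latitude": out / "latitude.tsv",
        "expression": out / "expression.tsv",
        "interactions": out / "interactions.tsv",
        "truth": out / "truth.tsv",
    }
    mio.write_mirna_fasta(sim.mirnas + sim.decoys, paths["mirnas"])
    mio.write_utr_fasta(sim.utrs, paths["utrs"])
    mio.write_vcf(
        sim.records,
        sim.samples,
        {u.utr_id: len(u.seq) for u in sim.utrs},
        paths["vcf"],
    )
    panel = pd.DataFrame(
        [
            {"sample": s, "pop": p.name, "super_pop": p.super_pop}
            for p in sim.populations
            for s in p.samples
        ]
    )
    panel.to_csv(paths["panel"], sep="\t", index=False)
    lat_rows = []
    for p in sim.populations:
        # two collection points symmetric about the true centroid
        lat_rows.append({"population": p.name, "latitude": p.latitude + 2.0,
                         "longitude": p.longitude - 2.0})
        lat_rows.append({"population": p.name, "latitude": p.latitude - 2.0,
                         "longitude": p.longitude + 2.0})
    pd.DataFrame(lat_rows).to_csv(paths["latitude"], sep="\t", index=False)
    with open(paths["expression"], "w") as fh:
        for name, value in sim.expression.items():
            fh.write(f"{name}\t{value}\n")
    with open(paths["interactions"], "w") as fh:
        fh.write("mirna\tgene\tevidence\n")
        for mirna, gene, evidence in sim.interactions:
            fh.write(f"{mirna}\t{gene}\t{','.join(sorted(evidence))}\n")
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
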