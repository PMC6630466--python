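"""Readers and writers for the file dialects the pipeline consumes.

Conventions
-----------
* microRNA FASTA: miRBase mature style — header is the mature name,
  sequence in the RNA alphabet.
* UTR FASTA: header ``utr_id|gene``, sequence is the transcript sense
  strand in the DNA alphabet.
* VCF 4.x: one UTR per CHROM, 1-based POS (converted to 0-based offsets
  exactly once, here), biallelic SNVs only, ancestral allele in INFO/AA,
  diploid GT fields.
* panel TSV: columns ``sample``, ``pop``, ``super_pop`` (1000 Genomes
  panel dialect; super_pop in AFR/AMR/EAS/EUR/SAS).
* latitude TSV: columns ``population``, ``latitude``, ``longitude``;
  multiple rows per population are collection points for the centroid.
* expression TSV: two columns, mature name and expression value.
* interaction TSV: columns ``mirna``, ``gene``, ``evidence`` where
  evidence is a comma/semicolon separated method set.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .association import PopulationGeoRecord
from .errors import InvalidInputError
from .seed_match import MatureMiRNA, UTRSequence
from .variant_overlay import BiallelicSNP

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA

def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Read mature microRNAs from a miRBase-style FASTA file."""
    return [
        MatureMiRNA(name=rec.id, mature_seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_utr_fasta(path: str | Path) -> list[UTRSequence]:
    """Read UTR sequences; headers are ``utr_id|gene``."""
    utrs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        utr_id, _, gene = rec.id.partition("|")
        utrs.append(UTRSequence(utr_id=utr_id, gene=gene or utr_id, seq=str(rec.seq)))
    return utrs


def write_mirna_fasta(mirnas: Sequence[MatureMiRNA], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(m.mature_seq), id=m.name, description="") for m in mirnas
    ]
    SeqIO.write(records, str(path), "fasta")


def write_utr_fasta(utrs: Sequence[UTRSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(u.seq), id=f"{u.utr_id}|{u.gene}", description="") for u in utrs
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF

@dataclass(frozen=True)
class SNPRecord:
    """A parsed biallelic SNV plus its per-sample genotypes (0/1/-1 coded)."""

    snp: BiallelicSNP
    genotypes: dict[str, tuple[int, int]]


def read_snps_vcf(path: str | Path) -> tuple[list[SNPRecord], Counter]:
    """Parse biallelic SNVs with genotypes from a VCF file.

    Indels and multi-allelic records are excluded at this boundary; the
    returned counter reports how many records were dropped and why.
    1-based VCF POS becomes a 0-based UTR offset here and nowhere else.
    The ancestral allele is INFO/AA upper-cased; values that are neither
    REF nor ALT become ``unknown``.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[SNPRecord] = []
    dropped: Counter = Counter()
    for v in vcf:
        if len(v.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or {ref, alt} - set("ACGT"):
            dropped["not_snv"] += 1
            continue
        aa = v.INFO.get("AA")
        aa = str(aa).upper() if aa is not None else "unknown"
        if aa not in (ref, alt):
            aa = "unknown"
        genotypes = {
            s: (int(g[0]), int(g[1])) for s, g in zip(samples, v.genotypes)
        }
        snp = BiallelicSNP(
            snp_id=v.ID or f"{v.CHROM}:{v.POS}",
            utr_id=v.CHROM,
            pos=v.POS - 1,
            ref_allele=ref,
            alt_allele=alt,
            ancestral_allele=aa,
        )
        records.append(SNPRecord(snp=snp, genotypes=genotypes))
    if dropped:
        logger.info("VCF exclusions: %s", dict(dropped))
    return records, dropped


def write_vcf(
    records: Sequence[SNPRecord],
    samples: Sequence[str],
    utr_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write biallelic SNVs with diploid GT fields and INFO/AA as VCF 4.2."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for utr_id in sorted(utr_lengths):
        lines.append(f"##contig=<ID={utr_id},length={utr_lengths[utr_id]}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    ordered = sorted(records, key=lambda r: (r.snp.utr_id, r.snp.pos))
    for rec in ordered:
        snp = rec.snp
        aa = snp.ancestral_allele if snp.ancestral_allele != "unknown" else "."
        gts = []
        for s in samples:
            a1, a2 = rec.genotypes.get(s, (-1, -1))
            gts.append("./." if a1 < 0 or a2 < 0 else f"{a1}|{a2}")
        lines.append(
            f"{snp.utr_id}\t{snp.pos + 1}\t{snp.snp_id}\t{snp.ref_allele}\t"
            f"{snp.alt_allele}\t.\tPASS\tAA={aa}\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV tables

def read_panel(path: str | Path) -> pd.DataFrame:
    """Sample panel with columns sample, pop, super_pop."""
    panel = pd.read_csv(path, sep="\t")
    required = {"sample", "pop", "super_pop"}
    missing = required - set(panel.columns)
    if missing:
        raise InvalidInputError(f"panel missing columns: {sorted(missing)}")
    return panel


def panel_maps(panel: pd.DataFrame) -> tuple[dict[str, str], dict[str, str]]:
    """(sample -> sampled population, sample -> super-population) lookups."""
    return (
        dict(zip(panel["sample"], panel["pop"])),
        dict(zip(panel["sample"], panel["super_pop"])),
    )


def read_latitude_table(
    path: str | Path, excluded: Iterable[str] = ()
) -> dict[str, PopulationGeoRecord]:
    """Latitude metadata: one record per population, rows are collection points."""
    df = pd.read_csv(path, sep="\t")
    required = {"population", "latitude", "longitude"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"latitude table missing columns: {sorted(missing)}")
    excluded = set(excluded)
    out = {}
    for pop, grp in df.groupby("population", sort=False):
        points = tuple(zip(grp["latitude"].astype(float), grp["longitude"].astype(float)))
        out[str(pop)] = PopulationGeoRecord(
            population=str(pop), points=points, excluded=str(pop) in excluded
        )
    return out


def read_expression_table(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", header=None, names=["mature_name", "expression"],
                     comment="#")
    return dict(zip(df["mature_name"], df["expression"].astype(float)))


def read_interaction_table(path: str | Path) -> list[tuple[str, str, set[str]]]:
    """Experimentally supported interactions: (mirna, gene, evidence set) rows."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["mirna", "gene", "evidence"]:
            raise InvalidInputError(
                f"interaction table header must be mirna/gene/evidence, got {header[:3]}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidInputError(
                    f"{path}: malformed interaction row at line {lineno}: {line!r}"
                )
            evidence = {
                e.strip() for e in fields[2].replace(";", ",").split(",") if e.strip()
            }
            rows.append((fields[0], fields[1], evidence))
    return rows


def read_null_fst(path: str | Path) -> list[float]:
    """Genome-wide null Fst values, one per line."""
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                values.append(float(line))
    return values
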