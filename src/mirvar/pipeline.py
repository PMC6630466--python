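"""Full analysis pipeline: scan -> classify -> Fst -> filters -> reports.

Outputs mirror the shape of the study's result tables:

``pairs.tsv``
    every target/near-target pair surviving the frequency window, with
    per-super-population target-allele frequencies, Fst and P_Fst;
``table1.tsv``
    pairs with Fst strictly above the differentiation threshold, sorted
    by descending Fst (ties by SNP id);
``table2.tsv``
    pairs supported by high-throughput interaction evidence whose
    empirical P_Fst is below the significance threshold;
``fig1_data.tsv``
    long-format target-allele frequencies per polarization class and
    super-population (violin/box plot data);
``fig3_data.tsv``
    Fst histogram data plus the at-or-above-threshold count;
``latitude_fits.tsv``
    per-SNP OLS fits of target-allele frequency on absolute latitude of
    the sampled (non-migrated) populations;
``shift_test.tsv``
    paired signed-rank EUR-minus-AFR frequency-shift test over all pairs;
``run_config.txt`` and ``run.log``
    provenance copy of the configuration and the exclusion accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .association import (
    fit_latitude_model,
    fst_distribution_report,
    paired_shift_test,
)
from .config import RunConfig, write_config
from .errors import MirvarError
from .popgen import (
    SUPER_POPULATIONS,
    empirical_pfst,
    fst,
    pop_frequencies,
)
from .seed_match import (
    expression_threshold_top_fraction,
    filter_expressed,
    group_families,
)
from .simulate import simulate_frequencies
from .variant_overlay import (
    TargetPair,
    classify_pair,
    frequency_filter,
    global_target_frequency,
    join_interactions,
)

logger = logging.getLogger(__name__)

PAIR_COLUMNS = [
    "mirnas", "gene", "snp_id", "site_type", "target_allele", "polarization",
    "target_in_reference", "EAS", "AMR", "AFR", "EUR", "SAS",
    "global_freq", "fst", "p_fst", "experimentally_detected",
]


@dataclass
class PipelineResult:
    pairs: list[TargetPair]
    pairs_table: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    fig1_data: pd.DataFrame
    fig3_data: pd.DataFrame
    latitude_fits: pd.DataFrame
    shift_test: pd.DataFrame
    exclusions: dict[str, int]


def classify_all(
    utrs, records, mirnas, target_site_types, pop_of_sample
) -> tuple[list[TargetPair], dict[str, dict]]:
    """Run pair classification for every SNP against every seed family.

    Returns the pairs plus a per-SNP genotype lookup for the frequency
    stage.  SNPs on unknown UTRs are skipped with a warning; a SNP can
    yield one pair per family it toggles.
    """
    utr_by_id = {u.utr_id: u for u in utrs}
    families = group_families(mirnas)
    representative = {}
    for m in mirnas:
        representative.setdefault(m.family_key, m)
    pairs: list[TargetPair] = []
    genotype_lookup: dict[str, dict] = {}
    for rec in records:
        utr = utr_by_id.get(rec.snp.utr_id)
        if utr is None:
            logger.warning("SNP %s on unknown UTR %s; skipped", rec.snp.snp_id, rec.snp.utr_id)
            continue
        genotype_lookup[rec.snp.snp_id] = rec.genotypes
        # per sampled population ALT-allele counts, attached to the SNP
        counts: dict[str, list[int]] = {}
        for sample, (a1, a2) in rec.genotypes.items():
            pop = pop_of_sample.get(sample)
            if pop is None:
                continue
            bucket = counts.setdefault(pop, [0, 0])
            for a in (a1, a2):
                if a >= 0:
                    bucket[1] += 1
                    bucket[0] += a
        snp = replace(rec.snp, counts={p: (c, t) for p, (c, t) in counts.items()})
        for family_key, members in families.items():
            pair = classify_pair(
                utr,
                snp,
                representative[family_key],
                target_site_types,
                family_members=members,
            )
            if pair is not None:
                pairs.append(pair)
    return pairs, genotype_lookup


def _pairs_dataframe(pairs, freq_tables, fst_results) -> pd.DataFrame:
    rows = []
    for pair, table, res in zip(pairs, freq_tables, fst_results):
        row = {
            "mirnas": ",".join(pair.mirnas),
            "gene": pair.gene,
            "snp_id": pair.snp.snp_id,
            "site_type": pair.site_type,
            "target_allele": pair.target_allele,
            "polarization": pair.polarization,
            "target_in_reference": pair.target_in_reference,
        }
        for sp in SUPER_POPULATIONS:
            f = table.frequency(sp)
            row[sp] = round(f, 4) if f is not None else float("nan")
        row["global_freq"] = round(global_target_frequency(pair), 6)
        row["fst"] = res.value
        row["p_fst"] = res.p_fst
        row["experimentally_detected"] = pair.experimentally_detected
        rows.append(row)
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def summarize_classes(pairs_table: pd.DataFrame) -> pd.DataFrame:
    """Long-format frequency vectors per polarization class and super-population."""
    if pairs_table.empty:
        logger.warning("no polarized pairs to summarise")
        return pd.DataFrame(columns=["polarization", "super_pop", "snp_id", "frequency"])
    rows = []
    for _, r in pairs_table.iterrows():
        for sp in SUPER_POPULATIONS:
            if pd.notna(r[sp]):
                rows.append(
                    {
                        "polarization": r["polarization"],
                        "super_pop": sp,
                        "snp_id": r["snp_id"],
                        "frequency": r[sp],
                    }
                )
    return pd.DataFrame(rows)


def _null_distribution(config: RunConfig, sizes: list[int]) -> np.ndarray:
    """Genome-wide null Fst: from file if provided, else Balding-Nichols."""
    if config.null_fst:
        return np.asarray(mio.read_null_fst(config.null_fst))
    rng = np.random.default_rng(config.rng_seed + 7)
    if not sizes:
        sizes = [100] * 5
    values = []
    for _ in range(config.null_size):
        p_bar = rng.uniform(0.05, 0.95)
        freqs = simulate_frequencies(p_bar, config.null_F, len(sizes), rng)
        counts = [
            (int(rng.binomial(n, f)), int(n)) for n, f in zip(sizes, freqs)
        ]
        try:
            values.append(fst(counts, config.fst_estimator).value)
        except MirvarError:
            continue
    return np.asarray(values)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full cascade and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exclusions: dict[str, int] = {}
    log_lines: list[str] = []

    utrs = mio.read_utr_fasta(config.utr_fasta)
    mirnas = mio.read_mirna_fasta(config.mirna_fasta)
    records, dropped = mio.read_snps_vcf(config.vcf)
    panel = mio.read_panel(config.panel)
    pop_of_sample, super_of_sample = mio.panel_maps(panel)
    for reason, n in dropped.items():
        exclusions[f"vcf_{reason}"] = n
        log_lines.append(f"excluded {n} VCF records: {reason}")

    if config.expression:
        expression = mio.read_expression_table(config.expression)
        threshold = (
            config.expression_threshold
            if config.expression_threshold >= 0
            else expression_threshold_top_fraction(expression)
        )
        n_before = len(mirnas)
        mirnas = filter_expressed(mirnas, expression, threshold)
        exclusions["mirna_low_expression"] = n_before - len(mirnas)
        log_lines.append(
            f"expression filter (threshold {threshold:g}): kept {len(mirnas)}/{n_before} matures"
        )

    if not records or not mirnas:
        logger.warning("no usable SNPs or microRNAs; emitting empty tables")
        empty = pd.DataFrame(columns=PAIR_COLUMNS)
        result = PipelineResult(
            pairs=[], pairs_table=empty, table1=empty, table2=empty,
            fig1_data=pd.DataFrame(), fig3_data=pd.DataFrame(),
            latitude_fits=pd.DataFrame(), shift_test=pd.DataFrame(),
            exclusions=exclusions,
        )
        _write_bundle(result, config, out, log_lines)
        return result

    pairs, genotype_lookup = classify_all(
        utrs, records, mirnas, set(config.target_site_types), pop_of_sample
    )
    log_lines.append(f"classified {len(pairs)} target/near-target pairs")

    n_before = len(pairs)
    pairs = frequency_filter(pairs, config.freq_lower, config.freq_upper)
    exclusions["pairs_outside_frequency_window"] = n_before - len(pairs)
    log_lines.append(
        f"frequency window [{config.freq_lower}, {config.freq_upper}]: "
        f"kept {len(pairs)}/{n_before} pairs"
    )

    if config.interactions:
        interactions = mio.read_interaction_table(config.interactions)
        pairs = join_interactions(pairs, interactions)

    freq_tables = []
    fst_results = []
    sizes_example: list[int] = []
    for pair in pairs:
        table = pop_frequencies(
            genotype_lookup[pair.snp.snp_id],
            super_of_sample,
            snp_id=pair.snp.snp_id,
            target_is_alt=(pair.target_allele == pair.snp.alt_allele),
        )
        counts = [table.counts[g] for g in SUPER_POPULATIONS if table.counts.get(g, (0, 0))[1] >= 2]
        if not sizes_example and counts:
            sizes_example = [t for _, t in counts]
        freq_tables.append(table)
        fst_results.append(fst(counts, config.fst_estimator, snp_id=pair.snp.snp_id))

    null = _null_distribution(config, sizes_example)
    fst_results = [
        replace(r, p_fst=empirical_pfst(r.value, null)) if null.size else r
        for r in fst_results
    ]

    pairs_table = _pairs_dataframe(pairs, freq_tables, fst_results)

    table1 = pairs_table[pairs_table["fst"] > config.fst_threshold].copy()
    table1.sort_values(["fst", "snp_id"], ascending=[False, True], inplace=True)
    table2 = pairs_table[
        pairs_table["experimentally_detected"]
        & (pairs_table["p_fst"] < config.pfst_threshold)
    ].copy()
    table2.sort_values(["fst", "snp_id"], ascending=[False, True], inplace=True)

    polarized = pairs_table[pairs_table["polarization"] != "unpolarized"]
    fig1_data = summarize_classes(polarized)

    report = fst_distribution_report(pairs_table["fst"].to_numpy(), threshold=0.3)
    fig3_data = pd.DataFrame(
        {
            "bin_left": report.histogram_edges[:-1],
            "bin_right": report.histogram_edges[1:],
            "count": report.histogram_counts,
        }
    )
    log_lines.append(
        f"Fst >= {report.threshold}: {report.n_at_or_above}/{report.n_total} "
        f"({report.fraction:.4f})"
    )

    latitude_fits = _latitude_analysis(config, pairs, freq_tables, genotype_lookup, pop_of_sample)
    shift = _shift_analysis(pairs_table)

    result = PipelineResult(
        pairs=pairs,
        pairs_table=pairs_table,
        table1=table1,
        table2=table2,
        fig1_data=fig1_data,
        fig3_data=fig3_data,
        latitude_fits=latitude_fits,
        shift_test=shift,
        exclusions=exclusions,
    )
    _write_bundle(result, config, out, log_lines)
    return result


def _latitude_analysis(config, pairs, freq_tables, genotype_lookup, pop_of_sample):
    """Per-SNP OLS of target frequency on |latitude| over sampled populations."""
    if not config.latitude or not pairs:
        return pd.DataFrame(
            columns=["snp_id", "slope", "intercept", "r2_adjusted", "p_value", "n"]
        )
    geo = mio.read_latitude_table(config.latitude, excluded=config.excluded_populations)
    rows = []
    for pair in pairs:
        table = pop_frequencies(
            genotype_lookup[pair.snp.snp_id],
            pop_of_sample,
            snp_id=pair.snp.snp_id,
            target_is_alt=(pair.target_allele == pair.snp.alt_allele),
        )
        records = []
        for pop_name, rec in geo.items():
            if rec.excluded:
                continue
            f = table.frequency(pop_name)
            if f is not None:
                records.append((rec.effective_latitude, f))
        if len(records) < 3:
            continue
        try:
            fit = fit_latitude_model(records)
        except MirvarError:
            continue
        rows.append(
            {
                "snp_id": pair.snp.snp_id,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2_adjusted": fit.r2_adjusted,
                "p_value": fit.p_value,
                "n": fit.n,
            }
        )
    return pd.DataFrame(
        rows, columns=["snp_id", "slope", "intercept", "r2_adjusted", "p_value", "n"]
    )


def _shift_analysis(pairs_table: pd.DataFrame) -> pd.DataFrame:
    """Paired EUR-minus-AFR signed-rank shift over all pairs with both groups."""
    cols = ["n_pairs", "p_value", "shift_median", "ci_low", "ci_high", "n_zero_dropped"]
    if pairs_table.empty:
        return pd.DataFrame(columns=cols)
    sub = pairs_table.dropna(subset=["AFR", "EUR"])
    if len(sub) < 1:
        return pd.DataFrame(columns=cols)
    try:
        res = paired_shift_test(sub["AFR"].to_numpy(), sub["EUR"].to_numpy())
    except MirvarError:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(
        [
            {
                "n_pairs": res.n_pairs,
                "p_value": res.p_value,
                "shift_median": res.shift_median,
                "ci_low": res.ci95[0],
                "ci_high": res.ci95[1],
                "n_zero_dropped": res.n_zero_dropped,
            }
        ]
    )


def _write_bundle(result: PipelineResult, config: RunConfig, out: Path, log_lines):
    for name, df in [
        ("pairs.tsv", result.pairs_table),
        ("table1.tsv", result.table1),
        ("table2.tsv", result.table2),
        ("fig1_data.tsv", result.fig1_data),
        ("fig3_data.tsv", result.fig3_data),
        ("latitude_fits.tsv", result.latitude_fits),
        ("shift_test.tsv", result.shift_test),
    ]:
        df.to_csv(out / name, sep="\t", index=False)
    write_config(config, out / "run_config.txt")
    for key, n in result.exclusions.items():
        log_lines.append(f"exclusion_count\t{key}\t{n}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
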