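"""Allele substitution, pair classification and polarization."""

import numpy as np
import pytest

from conftest import random_seed_rna, random_utr
from oracles import oracle_classify

from mirvar import (
    BiallelicSNP,
    MatureMiRNA,
    TargetPair,
    UTRSequence,
    apply_allele,
    classify_pair,
    frequency_filter,
    global_target_frequency,
    join_interactions,
    polarize,
)
from mirvar.errors import InvalidInputError, ReferenceMismatchError
from mirvar.seed_match import DEFAULT_TARGET_SITE_TYPES, site_motifs


def snp(pos, ref, alt, aa="unknown", counts=None, utr_id="u1"):
    return BiallelicSNP(
        snp_id="rs1", utr_id=utr_id, pos=pos, ref_allele=ref, alt_allele=alt,
        ancestral_allele=aa, counts=counts,
    )


class TestApplyAllele:
    def test_substitution(self, let7_utr):
        assert apply_allele(let7_utr, snp(6, "C", "G"), "G") == "AAACTAGCTCAAAA"

    def test_identity_for_ref(self, let7_utr):
        assert apply_allele(let7_utr, snp(6, "C", "G"), "C") == let7_utr.seq

    def test_reference_mismatch_raises_with_snp_id(self, let7_utr):
        with pytest.raises(ReferenceMismatchError, match="rs1"):
            apply_allele(let7_utr, snp(6, "T", "G"), "G")


class TestClassifyPair:
    def test_site_disrupting_snp(self, let7, let7_utr):
        pair = classify_pair(let7_utr, snp(6, "C", "G"), let7)
        assert pair is not None
        assert pair.target_allele == "C"
        assert pair.nontarget_allele == "G"
        assert (pair.site_start, pair.site_end, pair.site_type) == (3, 11, "8mer")
        assert pair.target_in_reference

    def test_snp_outside_windows_is_none(self, let7):
        utr = UTRSequence("u1", "G1", "AAACTACCTCAAAAGGGGG")
        assert classify_pair(utr, snp(15, "G", "A"), let7) is None

    def test_both_alleles_target_is_none(self, let7):
        """When both alleles carry a site overlapping the SNP, it is no pair.

        Found by brute-force search over substitutions in tandem planted
        motifs: the reference allele closes an 8mer at 2..10 while the
        alternative allele opens a second let-7 site starting at the SNP.
        """
        utr = UTRSequence("u1", "G1", "AACTACCTCATACCTCAAA")
        assert classify_pair(utr, snp(9, "A", "C"), let7) is None
        # sanity: each allele on its own does carry an overlapping site
        from oracles import oracle_classify

        assert oracle_classify(utr.seq, 9, "A", "C", let7.seed,
                               DEFAULT_TARGET_SITE_TYPES) is None

    def test_site_creating_snp_target_not_in_reference(self, let7):
        utr = UTRSequence("u1", "G1", "AAACTAGCTCAAAA")  # broken 8mer
        pair = classify_pair(utr, snp(6, "G", "C"), let7)
        assert pair is not None
        assert pair.target_allele == "C"
        assert not pair.target_in_reference

    def test_ref_alt_relabeling_symmetry(self, let7, let7_utr):
        """Swapping REF/ALT flips reference status but not the target base."""
        pair_ref = classify_pair(let7_utr, snp(6, "C", "G"), let7)
        broken = UTRSequence("u1", "G1", apply_allele(let7_utr, snp(6, "C", "G"), "G"))
        pair_alt = classify_pair(broken, snp(6, "G", "C"), let7)
        assert pair_ref.target_allele == pair_alt.target_allele == "C"
        assert pair_ref.target_in_reference and not pair_alt.target_in_reference

    def test_equivalent_to_full_rescan_oracle(self):
        """Random planted-motif fixtures: classification matches the oracle."""
        rng = np.random.default_rng(202)
        n_checked = 0
        for _ in range(400):
            seed = random_seed_rna(rng)
            mirna = MatureMiRNA("m", "A" + seed + "GUUAGG")
            motifs = site_motifs(mirna.seed)
            site_type = list(DEFAULT_TARGET_SITE_TYPES)[rng.integers(0, 3)]
            motif = motifs[site_type]
            flank_l = random_utr(rng, int(rng.integers(5, 40)))
            flank_r = random_utr(rng, int(rng.integers(5, 40)))
            seq = flank_l + motif + flank_r
            pos = int(rng.integers(0, len(seq)))
            ref = seq[pos]
            alt = "ACGT"[rng.integers(0, 4)]
            if alt == ref:
                continue
            utr = UTRSequence("u1", "G1", seq)
            pair = classify_pair(utr, snp(pos, ref, alt), mirna)
            expected = oracle_classify(seq, pos, ref, alt, seed, DEFAULT_TARGET_SITE_TYPES)
            if expected is None:
                assert pair is None
            else:
                target, start, end, stype = expected
                assert pair is not None
                assert (pair.target_allele, pair.site_start, pair.site_end,
                        pair.site_type) == (target, start, end, stype)
                n_checked += 1
        assert n_checked > 20  # the fixture family produced real pairs


class TestPolarize:
    def _pair(self, target, nontarget, ref, aa):
        s = snp(6, ref, target if ref != target else nontarget, aa=aa)
        return TargetPair(
            snp=s, family_key="GAGGUAG", site_type="8mer", site_start=3,
            site_end=11, target_allele=target, nontarget_allele=nontarget,
            target_in_reference=(target == ref),
        )

    @pytest.mark.parametrize(
        "aa_is_target, target_in_ref, expected",
        [
            (True, False, "ancestral_target_lost"),
            (False, True, "derived_target_gained"),
            (True, True, "ancestral_target_in_ref"),
            (False, False, "derived_nontarget_in_ref"),
        ],
    )
    def test_truth_table_exhaustive(self, aa_is_target, target_in_ref, expected):
        target, nontarget = "C", "G"
        ref = target if target_in_ref else nontarget
        aa = target if aa_is_target else nontarget
        assert polarize(self._pair(target, nontarget, ref, aa)) == expected

    def test_unknown_ancestral_is_unpolarized(self):
        assert polarize(self._pair("C", "G", "C", "unknown")) == "unpolarized"

    def test_classes_partition_the_grid(self):
        seen = {
            polarize(self._pair("C", "G", ref, aa))
            for ref in "CG"
            for aa in "CG"
        }
        assert seen == {
            "ancestral_target_lost", "derived_target_gained",
            "ancestral_target_in_ref", "derived_nontarget_in_ref",
        }


class TestFrequencyFilter:
    def _pair_with_freq(self, alt_count, total, target_is_alt=True):
        s = snp(6, "C", "G", counts={"P1": (alt_count, total)})
        target = "G" if target_is_alt else "C"
        nontarget = "C" if target_is_alt else "G"
        return TargetPair(
            snp=s, family_key="k", site_type="8mer", site_start=3, site_end=11,
            target_allele=target, nontarget_allele=nontarget,
        )

    @pytest.mark.parametrize(
        "count, total, kept",
        [
            (50, 100, True),     # 0.50 inside window
            (1, 200, False),     # 0.005 below
            (1, 100, True),      # exactly 0.01: inclusive bound
            (99, 100, True),     # exactly 0.99: inclusive bound
            (199, 200, False),   # 0.995 above
        ],
    )
    def test_window_inclusive(self, count, total, kept):
        pairs = frequency_filter([self._pair_with_freq(count, total)])
        assert bool(pairs) is kept

    def test_target_on_ref_uses_complement_frequency(self):
        pair = self._pair_with_freq(199, 200, target_is_alt=False)
        assert global_target_frequency(pair) == pytest.approx(0.005)
        assert frequency_filter([pair]) == []

    def test_zero_total_rejected(self):
        with pytest.raises(InvalidInputError):
            frequency_filter([self._pair_with_freq(0, 0)])


class TestJoinInteractions:
    def _pair(self, gene="CASP10", mirnas=("miR-24-3p",)):
        s = snp(6, "C", "G")
        return TargetPair(
            snp=s, family_key="k", site_type="8mer", site_start=3, site_end=11,
            target_allele="C", nontarget_allele="G", gene=gene, mirnas=mirnas,
        )

    def test_hits_clip_evidence_flags_pair(self):
        (out,) = join_interactions(
            [self._pair()], [("miR-24-3p", "CASP10", {"HITS-CLIP"})]
        )
        assert out.experimentally_detected

    def test_luciferase_only_not_flagged(self):
        (out,) = join_interactions(
            [self._pair()], [("miR-24-3p", "CASP10", {"luciferase"})]
        )
        assert not out.experimentally_detected

    def test_gene_absent_not_flagged(self):
        (out,) = join_interactions(
            [self._pair(gene="OTHER")], [("miR-24-3p", "CASP10", {"HITS-CLIP"})]
        )
        assert not out.experimentally_detected

    def test_any_family_member_matches(self):
        (out,) = join_interactions(
            [self._pair(mirnas=("miR-151a-5p", "miR-24-3p"))],
            [("miR-24-3p", "CASP10", {"PAR-CLIP"})],
        )
        assert out.experimentally_detected


def test_snp_invariants():
    with pytest.raises(InvalidInputError):
        snp(3, "C", "C")
    with pytest.raises(InvalidInputError):
        snp(3, "CT", "C")
    # ancestral allele outside {ref, alt} collapses to unknown
    assert snp(3, "C", "G", aa="T").ancestral_allele == "unknown"
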