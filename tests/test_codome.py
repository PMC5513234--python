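import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

from barcodevar import (
    AlignedSeqSet,
    GeneTable,
    RegionSpec,
    call_variant_sites,
    classify_variant,
    evenness_test,
    representativeness,
    translate_codon,
    variant_codon_fraction,
    window_profile,
)
from barcodevar.codome import MIXED, NONCODING, NONSYNONYMOUS, SYNONYMOUS
from barcodevar.errors import InsufficientDataError, ParameterError
from barcodevar.mitogenome import concatenated_gene_table, default_barcode
from barcodevar.seqio import Gene
from barcodevar import synth

from conftest import oracle_chisquare


def make_set(seqs):
    return AlignedSeqSet(names=[f"s{i}" for i in range(len(seqs))], seqs=list(seqs))


class TestTranslateCodon:
    @pytest.mark.parametrize(
        "codon,aa",
        [("TGA", "W"), ("ATA", "M"), ("AGA", "*"), ("AGG", "*"), ("GCT", "A")],
    )
    def test_mitochondrial_code_deviations(self, codon, aa):
        assert translate_codon(codon) == aa

    def test_all_codons_match_biopython_table2(self):
        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    codon = a + b + c
                    expected = str(Seq(codon).translate(table=2))
                    assert translate_codon(codon) == expected

    def test_gapped_codon_untranslatable(self):
        assert translate_codon("A-G") == "?"
        assert translate_codon("ANG") == "?"


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "ref,pos,alt,expected",
        [
            ("TTA", 3, "G", SYNONYMOUS),  # Leu -> Leu
            ("GCT", 2, "T", NONSYNONYMOUS),  # Ala -> Val
            ("TGG", 3, "A", SYNONYMOUS),  # TGA is Trp under table 2
            ("CGA", 1, "A", NONSYNONYMOUS),  # Arg -> stop (AGA, table 2)
            ("AGA", 3, "G", SYNONYMOUS),  # stop -> stop: translation unchanged
        ],
    )
    def test_examples(self, ref, pos, alt, expected):
        assert classify_variant(ref, pos, alt) == expected

    def test_symmetric_when_both_codons_translate(self):
        # swapping which allele is the reference never flips the class
        rng = np.random.default_rng(0)
        for _ in range(200):
            ref = "".join(rng.choice(list("ACGT"), size=3))
            pos = int(rng.integers(1, 4))
            alt = rng.choice([b for b in "ACGT" if b != ref[pos - 1]])
            swapped = ref[: pos - 1] + alt + ref[pos:]
            assert classify_variant(ref, pos, alt) == classify_variant(
                swapped, pos, ref[pos - 1]
            )

    def test_untranslatable_reference(self):
        assert classify_variant("A-A", 1, "G") == "unknown"


def two_gene_table():
    # two 9-bp genes with a 3-bp noncoding spacer
    return GeneTable(
        genes=[
            Gene("g1", RegionSpec("g1", 1, 9)),
            Gene("g2", RegionSpec("g2", 13, 21)),
        ]
    )


class TestCallVariantSites:
    def test_invariant_alignment_empty(self):
        sites = call_variant_sites(make_set(["ATGAAATAA" * 2] * 4))
        assert sites == []

    def test_minor_allele_classified_against_consensus(self):
        # col 6 = codon 2 pos 3 of gene 1; TTA -> TTG is Leu -> Leu
        base = "ATGTTAAAATAA"
        alt = "ATGTTGAAATAA"
        genes = GeneTable(genes=[Gene("g", RegionSpec("g", 1, 12))])
        sites = call_variant_sites(make_set([base] * 9 + [alt]), genes)
        assert len(sites) == 1
        v = sites[0]
        assert (v.column, v.gene, v.codon_index, v.codon_pos) == (6, "g", 2, 3)
        assert v.alleles == {"A": 9, "G": 1}
        assert v.classification == SYNONYMOUS

    def test_ambiguity_never_makes_a_variant(self):
        sites = call_variant_sites(make_set(["AAAA", "AANA", "AAAA"]))
        assert sites == []

    def test_noncoding_and_min_count(self):
        seqs = ["ATGAAATAA" + "CCC" + "ATGAAATAA" for _ in range(4)]
        seqs[0] = seqs[0][:10] + "T" + seqs[0][11:]  # spacer column 11
        sites = call_variant_sites(make_set(seqs), two_gene_table())
        assert [v.classification for v in sites] == [NONCODING]
        assert call_variant_sites(make_set(seqs), two_gene_table(), min_count=2) == []

    def test_minus_strand_gene(self):
        # gene on minus strand: coding sequence is the revcomp, ATG GCA TAA.
        # plus-strand alignment shows TTA TGC CAT; a plus-strand G->A at
        # column 5 is coding C->T at codon 2 pos 2 (Ala -> Val).
        plus = "TTATGCCAT"
        mutant = plus[:4] + "A" + plus[5:]
        genes = GeneTable(genes=[Gene("g", RegionSpec("g", 1, 9, "-"))])
        sites = call_variant_sites(make_set([plus] * 5 + [mutant]), genes)
        assert len(sites) == 1
        v = sites[0]
        assert (v.codon_index, v.codon_pos) == (2, 2)
        assert v.classification == NONSYNONYMOUS

    def test_mixed_site(self):
        # consensus codon GCT (Ala): pos-3 T->C is synonymous, T->A still Ala
        # => use pos 1: G->A (Thr) nonsyn, G->C (Pro) nonsyn; craft mixed via
        # pos 3 (syn) vs pos-3 stop-adjacent is impossible in one column, so
        # use TTA: pos 3 A->G Leu->Leu (syn) and A->T Leu->Phe (nonsyn)
        base = "ATG" + "TTA" + "TAA"
        s1 = "ATG" + "TTG" + "TAA"
        s2 = "ATG" + "TTT" + "TAA"
        genes = GeneTable(genes=[Gene("g", RegionSpec("g", 1, 9))])
        sites = call_variant_sites(make_set([base] * 6 + [s1, s2]), genes)
        assert len(sites) == 1
        assert sites[0].classification == MIXED

    def test_selection_off_generator_yields_only_synonymous(self):
        r = synth.simulate_set(
            synth.SimParams(n_seqs=30, d=2e-3, p_ns=0.0, seed=11)
        )
        sites = call_variant_sites(r.seqs, r.genes)
        assert sites
        assert {v.classification for v in sites} == {SYNONYMOUS}

    def test_per_gene_counts_conserve_total(self, human_like_sim):
        sites = call_variant_sites(human_like_sim.seqs, human_like_sim.genes)
        genic = [v for v in sites if v.gene is not None]
        per_gene: dict = {}
        for v in genic:
            per_gene[v.gene] = per_gene.get(v.gene, 0) + 1
        assert sum(per_gene.values()) == len(genic)
        assert len(genic) == len(sites)  # codome model has no noncoding columns


class TestEvennessTest:
    def test_counts_proportional_to_length_give_zero(self):
        genes = GeneTable(
            genes=[
                Gene("a", RegionSpec("a", 1, 300)),
                Gene("b", RegionSpec("b", 301, 900)),
            ]
        )
        sites = [_stub_site(i, "a") for i in range(10)] + [
            _stub_site(400 + i, "b") for i in range(20)
        ]
        chi2, df, p = evenness_test(sites, genes)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_hand_computed_statistic(self):
        genes = GeneTable(
            genes=[
                Gene("a", RegionSpec("a", 1, 300)),
                Gene("b", RegionSpec("b", 301, 600)),
            ]
        )
        sites = [_stub_site(i + 1, "a") for i in range(15)] + [
            _stub_site(301 + i, "b") for i in range(5)
        ]
        chi2, df, p = evenness_test(sites, genes)
        assert chi2 == pytest.approx(5.0)  # (25/10) + (25/10)
        assert df == 1
        assert p == pytest.approx(float(stats.chi2.sf(5.0, 1)))

    def test_matches_independent_pearson_oracle(self, human_like_sim):
        sites = call_variant_sites(human_like_sim.seqs, human_like_sim.genes)
        genes = human_like_sim.genes
        chi2, df, _ = evenness_test(sites, genes)
        counts = {g.name: 0 for g in genes}
        for v in sites:
            if v.gene:
                counts[v.gene] += 1
        total = sum(counts.values())
        total_len = sum(g.region.width for g in genes)
        exp = [total * g.region.width / total_len for g in genes]
        # no pooling expected here: every gene's expectation is >= 5
        assert all(e >= 5 for e in exp)
        oracle = oracle_chisquare([counts[g.name] for g in genes], exp)
        assert chi2 == pytest.approx(oracle, abs=1e-9)
        assert df == len(genes) - 1

    def test_zero_sites_rejected(self):
        with pytest.raises(InsufficientDataError):
            evenness_test([], two_gene_table())


def _stub_site(column, gene):
    from barcodevar.codome import VariantSite

    return VariantSite(column, gene, 1, 1, {"A": 1, "G": 1}, SYNONYMOUS)


class TestWindowProfile:
    def test_invariant_alignment_all_zero(self):
        s = make_set(["ATGAAATAA" * 80] * 4)
        prof = window_profile(s, window=180)
        assert prof.apd_percent == [0.0] * len(prof.starts)

    def test_localized_variation_hits_only_overlapping_windows(self):
        L, W = 720, 180
        base = "A" * L
        mutant = "C" * 90 + "A" * (L - 90)  # variation confined to window 1
        prof = window_profile(make_set([base, mutant]), window=W)
        assert prof.apd_percent[0] > 0
        assert prof.apd_percent[1:] == [0.0] * (len(prof.starts) - 1)

    def test_window_larger_than_alignment(self):
        with pytest.raises(ParameterError):
            window_profile(make_set(["ACGT"] * 2), window=10)

    def test_uniform_mutation_windows_within_binomial_bounds(self):
        r = synth.simulate_set(synth.SimParams(n_seqs=40, d=2e-3, p_ns=1.0, seed=4))
        whole = 0.01 * np.mean(
            [w for w in window_profile(r.seqs, window=r.seqs.length).apd_percent]
        )
        prof = window_profile(r.seqs, window=648)
        p = whole  # per-site mismatch probability
        se = np.sqrt(p * (1 - p) / 648)
        for w in prof.apd_percent:
            assert abs(w / 100 - p) < 5 * se


class TestRepresentativeness:
    def test_all_variation_inside_barcode(self):
        genes = concatenated_gene_table()
        barcode = default_barcode(genes)
        anc, _ = synth.make_ancestor(genes, seed=0)
        mutant = list(anc)
        rng = np.random.default_rng(1)
        cols = rng.choice(
            np.arange(barcode.start - 1, barcode.end), size=30, replace=False
        )
        for c in cols:
            mutant[c] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutant[c]]
        s = make_set([anc, "".join(mutant), anc])
        rep = representativeness(s, barcode)
        assert rep.percentile > 95
        assert rep.ratio > 5

    def test_all_variation_outside_barcode(self):
        genes = concatenated_gene_table()
        barcode = default_barcode(genes)
        anc, _ = synth.make_ancestor(genes, seed=0)
        mutant = list(anc)
        rng = np.random.default_rng(2)
        outside = np.setdiff1d(
            np.arange(len(anc)), np.arange(barcode.start - 1, barcode.end)
        )
        for c in rng.choice(outside, size=60, replace=False):
            mutant[c] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutant[c]]
        s = make_set([anc, "".join(mutant)])
        rep = representativeness(s, barcode)
        assert rep.percentile < 5
        assert rep.barcode_apd == 0.0

    def test_barcode_is_one_of_the_tiled_windows(self, human_like_sim):
        genes = human_like_sim.genes
        barcode = default_barcode(genes)
        rep = representativeness(human_like_sim.seqs, barcode)
        assert barcode.start in rep.profile.starts
        i = rep.profile.starts.index(barcode.start)
        assert rep.profile.apd_percent[i] == pytest.approx(rep.barcode_apd)

    def test_width_mismatch_rejected(self, human_like_sim):
        bad = RegionSpec("b", 1, 100)
        with pytest.raises(ParameterError):
            representativeness(human_like_sim.seqs, bad)


class TestVariantCodonFraction:
    def test_extremes(self):
        genes = GeneTable(genes=[Gene("g", RegionSpec("g", 1, 9))])
        assert variant_codon_fraction([], genes) == 0.0
        sites = [_stub_site(1, "g"), _stub_site(4, "g"), _stub_site(7, "g")]
        sites[0].codon_index, sites[1].codon_index, sites[2].codon_index = 1, 2, 3
        assert variant_codon_fraction(sites, genes) == 1.0

    def test_counts_codons_not_sites(self):
        genes = GeneTable(genes=[Gene("g", RegionSpec("g", 1, 9))])
        a = _stub_site(1, "g")
        b = _stub_site(2, "g")
        a.codon_index = b.codon_index = 1  # two sites, same codon
        assert variant_codon_fraction([a, b], genes) == pytest.approx(1 / 3)
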