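"""Masking, filtering, fourfold-site extraction and T92 distances."""

import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hybridbracket.errors import (
    DegenerateCompositionError,
    InputError,
    SaturationError,
)
from hybridbracket.seqdist import (
    CodonAlignment,
    SiteMatrix,
    extract_ffd_sites,
    filter_and_concatenate,
    fourfold_prefixes,
    mask_dicodon_variation,
    t92_distance,
    t92_distance_matrix,
)
from hybridbracket.synthetic_data import CodonSimModel, simulate_codon_alignment

# Closed-form T92 at P=0.1, Q=0.05, theta=0.5:
#   -0.5*ln(1 - 0.1/0.5 - 0.05) - 0.25*ln(1 - 0.1)
# cross-checked against ape::dist.dna(model="T92") on sequences constructed
# with exactly these substitution proportions.
T92_SPOT_CHECK = -0.5 * math.log(0.75) - 0.25 * math.log(0.9)  # 0.17018116...


def two_seq(a: str, b: str) -> CodonAlignment:
    return CodonAlignment({"s1": a, "s2": b})


class TestMasking:
    def test_identical_codons_unchanged(self):
        aln = two_seq("AAAAAA", "AAAAAA")
        out = mask_dicodon_variation(aln)
        assert out.sequences == aln.sequences

    def test_two_differences_in_one_window_mask_both_codons(self):
        # differences at positions 1 and 4 fall inside the same 6 nt window
        aln = two_seq("AAAAAA", "ACAAGA")
        out = mask_dicodon_variation(aln)
        assert out.sequences["s1"] == "NNNNNN"
        assert out.sequences["s2"] == "NNNNNN"

    def test_single_differences_in_separated_codons_not_masked(self):
        # one difference each in codons 0 and 2, codon 1 identical: every
        # two-codon window contains at most one variable position
        aln = two_seq("AAA" "CCC" "GGG", "AAC" "CCC" "GGT")
        out = mask_dicodon_variation(aln)
        assert out.sequences == aln.sequences

    def test_window_brute_force_enumeration(self):
        # brute-force oracle: enumerate every adjacent codon pair, mark both
        # codons when its window has > 1 variable position
        seqs = {"s1": "AAACCCGGGTTTAAA", "s2": "AATCCAGGGTTTAAA"}
        aln = CodonAlignment(seqs)
        n_cod = 5
        masked = set()
        for i in range(n_cod - 1):
            window_cols = range(3 * i, 3 * i + 6)
            variants = sum(
                len({seqs[s][c] for s in seqs}) > 1 for c in window_cols)
            if variants > 1:
                masked.update((i, i + 1))
        out = mask_dicodon_variation(aln)
        for i in range(n_cod):
            expected = "NNN" if i in masked else seqs["s1"][3 * i: 3 * i + 3]
            assert out.sequences["s1"][3 * i: 3 * i + 3] == expected

    @given(st.lists(st.sampled_from("ACGT"), min_size=12, max_size=30))
    def test_masking_idempotent(self, bases):
        n = 3 * (len(bases) // 3)
        s1 = "".join(bases[:n])
        # derive a second sequence by deterministic perturbation
        s2 = "".join("ACGT"[("ACGT".index(c) + (i % 3 == 0)) % 4]
                     for i, c in enumerate(s1))
        once = mask_dicodon_variation(two_seq(s1, s2))
        twice = mask_dicodon_variation(once)
        assert once.sequences == twice.sequences


class TestFilterConcatenate:
    @staticmethod
    def gene(n_clean_codons: int, n_missing_codons: int, gid: str) -> CodonAlignment:
        seq = "GCA" * n_clean_codons + "NNN" * n_missing_codons
        return CodonAlignment({"s1": seq, "s2": seq}, gene_id=gid)

    def test_toy_lengths_arithmetic(self):
        genes = [self.gene(30, 2, "g90"), self.gene(40, 0, "g120"),
                 self.gene(100, 5, "g300")]
        out = filter_and_concatenate(genes, min_len=100)
        assert out.n_nt == 420  # 90 is below the cutoff; 120 + 300 survive
        assert [g[0] for g in out.gene_boundaries] == ["g120", "g300"]

    def test_min_len_boundary_is_inclusive(self):
        out99 = filter_and_concatenate([self.gene(33, 0, "g99")], min_len=100)
        assert out99.n_nt == 0
        out100 = filter_and_concatenate([self.gene(34, 0, "g102")], min_len=100)
        assert out100.n_nt == 102

    def test_no_missing_data_preserves_total_length(self):
        genes = [self.gene(40, 0, "a"), self.gene(50, 0, "b")]
        assert filter_and_concatenate(genes).n_nt == 270

    def test_species_mismatch_rejected(self):
        g1 = CodonAlignment({"s1": "GCA", "s2": "GCA"}, gene_id="a")
        g2 = CodonAlignment({"s1": "GCA", "s3": "GCA"}, gene_id="b")
        with pytest.raises(InputError):
            filter_and_concatenate([g1, g2], min_len=1)

    def test_whole_codon_removal_keeps_frame(self):
        # missing base in one species removes the whole codon for all
        aln = CodonAlignment({"s1": "GCAGCTGCC", "s2": "GCAGNTGCC"}, gene_id="g")
        out = filter_and_concatenate([aln], min_len=6)
        assert out.sequences["s1"] == "GCAGCC"


class TestFfdExtraction:
    def test_standard_code_has_eight_fourfold_families(self):
        assert fourfold_prefixes() == frozenset(
            {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"})

    def test_alanine_column_retained_with_third_bases(self):
        aln = two_seq("GCT", "GCA")
        sites = extract_ffd_sites(aln)
        assert sites.n_sites == 1
        assert sites.sequence("s1") == "T" and sites.sequence("s2") == "A"

    def test_isoleucine_column_excluded(self):
        assert extract_ffd_sites(two_seq("ATT", "ATC")).n_sites == 0

    def test_toy_alignment_counts_fourfold_columns(self):
        # hand-enumerated: GCx (Ala, ffd), AAx (Lys/Asn, not), GGx (Gly, ffd),
        # ATx (not), CTx (Leu, ffd), TGx (not), CCx (Pro, ffd), AGx (not),
        # TAx (not), ACx (Thr, ffd) -> but make one species non-ffd at one col
        s1 = "GCA" "AAA" "GGT" "ATT" "CTG" "TGG" "CCA" "AGA" "TAT" "ACC"
        s2 = "GCC" "AAG" "GGA" "ATC" "CTT" "TGC" "CCG" "AGG" "TAC" "ATC"
        # final column: s1=ACC (Thr, ffd) but s2=ATC (Ile, not) -> excluded
        sites = extract_ffd_sites(two_seq(s1, s2))
        assert sites.n_sites == 4
        assert list(sites.provenance["codon_index"]) == [0, 2, 4, 6]

    def test_mode_third_keeps_all_clean_columns(self):
        aln = two_seq("GCAATT", "GCAATC")
        assert extract_ffd_sites(aln, mode="third").n_sites == 2


class TestT92:
    @staticmethod
    def constructed_pair(n=1000):
        """P=0.1, Q=0.05, theta=0.5 by construction (GC-neutral changes)."""
        s1 = list("A" * 250 + "C" * 250 + "G" * 250 + "T" * 250)
        s2 = s1.copy()
        for i in range(50):
            s2[i] = "G"        # A->G transitions
        for i in range(500, 550):
            s2[i] = "A"        # G->A transitions
        for i in range(50, 75):
            s2[i] = "T"        # A->T transversions
        for i in range(750, 775):
            s2[i] = "A"        # T->A transversions
        return "".join(s1), "".join(s2)

    def test_identical_sequences_zero_distance(self):
        stats = t92_distance("GCAT" * 100, "GCAT" * 100)
        assert stats["d"] == 0.0

    def test_closed_form_spot_check(self):
        s1, s2 = self.constructed_pair()
        stats = t92_distance(s1, s2)
        assert stats["P"] == pytest.approx(0.1)
        assert stats["Q"] == pytest.approx(0.05)
        assert stats["theta"] == pytest.approx(0.5)
        assert stats["d"] == pytest.approx(T92_SPOT_CHECK, abs=1e-12)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_against_ape_reference_implementation(self, tmp_path):
        s1, s2 = self.constructed_pair()
        fasta = tmp_path / "pair.fa"
        fasta.write_text(f">s1\n{s1}\n>s2\n{s2}\n")
        script = (
            'suppressMessages(library(ape));'
            f'd <- dist.dna(read.dna("{fasta}", format="fasta"), model="T92");'
            'cat(sprintf("%.10f", as.numeric(d)))'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        ape_d = float(out.stdout.strip())
        ours = t92_distance(s1, s2)["d"]
        assert ours == pytest.approx(ape_d, abs=1e-8)

    def test_symmetry(self):
        s1, s2 = self.constructed_pair()
        assert t92_distance(s1, s2)["d"] == t92_distance(s2, s1)["d"]

    def test_monotone_in_transitions(self):
        # more transitions at fixed transversions and composition -> larger d
        s1, s2 = self.constructed_pair()
        s2_more = list(s2)
        for i in range(250, 270):
            s2_more[i] = "T"   # C->T transitions (GC drop negligible for order)
        d1 = t92_distance(s1, s2)["d"]
        d2 = t92_distance(s1, "".join(s2_more))["d"]
        assert d2 > d1

    def test_estimator_consistency_on_simulated_data(self):
        aln = simulate_codon_alignment(
            CodonSimModel(n_codons=50_000, d_true=0.10, gc=0.5, seed=0))
        dm = t92_distance_matrix(extract_ffd_sites(aln))
        assert dm.pair_stats["d"].iloc[0] == pytest.approx(0.10, abs=0.005)

    def test_saturation_raises(self):
        s1 = "A" * 500 + "C" * 500
        s2 = "G" * 500 + "T" * 500  # every site a transition
        with pytest.raises(SaturationError):
            t92_distance(s1, s2)

    def test_degenerate_composition_raises(self):
        with pytest.raises(DegenerateCompositionError):
            t92_distance("AAAA", "AATA")

    def test_distance_matrix_ratios(self):
        bases = np.array([list("ACGTACGTAC"), list("ACGTACGTAC"),
                          list("ACGAACGTTC")])
        sites = SiteMatrix(["a", "b", "c"],
                           bases, provenance=__import__("pandas").DataFrame())
        dm = t92_distance_matrix(sites, reference_pair=("a", "c"))
        assert dm.distances.loc["a", "b"] == 0.0
        assert dm.distances.equals(dm.distances.T)
        ref = dm.distances.loc["a", "c"]
        assert dm.ratios.loc[("b", "c"), "ratio_to_reference"] == pytest.approx(
            dm.distances.loc["b", "c"] / ref)
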