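import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoscreen import actin
from isoscreen.divergence import split_codons, translate_codon
from isoscreen.recode import (
    ENZYMES,
    DigestResult,
    count_substitutions,
    digest_fragments,
    find_restriction_sites,
    minimal_recode,
    parse_constraint,
    reverse_complement,
)

SENSE_CODONS = [
    c
    for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
    if c not in {"TAA", "TAG", "TGA"}
]


def oracle_min_substitutions(source_cds, target_protein):
    """Exhaustive scan: per codon, min Hamming distance over all synonymous
    codons of the target residue (codons are independent, so the per-codon
    minimum sums to the global minimum)."""
    total = 0
    codons = [source_cds[i : i + 3] for i in range(0, len(source_cds), 3)]
    for codon, aa in zip(codons, target_protein):
        options = [c for c in SENSE_CODONS if translate_codon(c) == aa]
        total += min(
            sum(1 for x, y in zip(codon, o) if x != y) for o in options
        )
    return total


class TestMinimalRecode:
    def test_identity_target_no_edits(self):
        src = "ATGGATGACTAA"
        protein = "".join(translate_codon(c) for c in split_codons(src))
        plan = minimal_recode(src, protein)
        assert plan.n_substitutions == 0
        assert plan.edited_cds == src

    def test_asp_to_glu_single_edit(self):
        # oracle: Glu codons are GAA/GAG; GAT->GAA and GAT->GAG are both
        # distance 1; lexicographic tie-break picks GAA
        plan = minimal_recode("GAT", "E")
        assert plan.n_substitutions == 1
        assert plan.edited_cds == "GAA"

    def test_beta_to_gamma_nterminus_is_four_edits(self):
        plan = minimal_recode(
            actin.ACTB_CDS_FIRST10_CODONS, actin.ACTG1_NTERM_DECAPEPTIDE
        )
        assert plan.n_substitutions == 4
        translated = "".join(
            translate_codon(c) for c in split_codons(plan.edited_cds)
        )
        assert translated == actin.ACTG1_NTERM_DECAPEPTIDE
        # one fewer than the realized five-edit knock-in design
        assert plan.n_substitutions == count_substitutions(
            actin.donor_first10_codons(), actin.ACTB_CDS_FIRST10_CODONS
        ) - 1

    def test_translation_correctness_random(self):
        rng = random.Random(7)
        for _ in range(50):
            n = rng.randint(1, 10)
            src = "".join(rng.choice(SENSE_CODONS) for _ in range(n))
            tgt = "".join(
                translate_codon(rng.choice(SENSE_CODONS)) for _ in range(n)
            )
            plan = minimal_recode(src, tgt)
            translated = "".join(
                translate_codon(c) for c in split_codons(plan.edited_cds)
            )
            assert translated == tgt
            assert plan.n_substitutions == oracle_min_substitutions(src, tgt)
            # every substitution changes exactly one base, positions increasing
            positions = [s.cds_position for s in plan.substitutions]
            assert positions == sorted(positions)
            assert len(set(positions)) == len(positions)

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError, match="length"):
            minimal_recode("ATGGAT", "M")

    def test_stop_codon_preserved(self):
        plan = minimal_recode("GATTAA", "E")
        assert plan.edited_cds.endswith("TAA")

    def test_disrupt_constraint_forces_extra_window_edit(self):
        # WT N-terminal 13 codons; the guide window spans codons 6-12.  The
        # minimal plan already places one edit there (codon 10); requiring two
        # forces one additional synonymous edit, mimicking a re-cut-avoiding
        # design that exceeds the minimum.
        src = actin.ACTB_CDS_FIRST10_CODONS + "GACAACGGC"
        tgt = actin.ACTG1_NTERM_DECAPEPTIDE + "DNG"
        minimal = minimal_recode(src, tgt)
        assert minimal.n_substitutions == 4
        constrained = minimal_recode(
            src, tgt, constraints=[f"disrupt:{actin.ACTBCG_GUIDE}:2"]
        )
        assert constrained.n_substitutions == 5
        translated = "".join(
            translate_codon(c) for c in split_codons(constrained.edited_cds)
        )
        assert translated == tgt
        # at least two mismatches to the guide within its window now
        window = src.index(actin.ACTBCG_GUIDE)
        diffs = sum(
            1
            for i in range(window, window + len(actin.ACTBCG_GUIDE))
            if constrained.edited_cds[i] != src[i]
        )
        assert diffs >= 2

    def test_parse_constraint(self):
        assert parse_constraint("disrupt:GATATC") == ("disrupt", "GATATC", 1)
        assert parse_constraint("disrupt:gatatc:2") == ("disrupt", "GATATC", 2)
        with pytest.raises(ValueError):
            parse_constraint("mangle:GATATC")


class TestCountSubstitutions:
    def test_identical(self):
        assert count_substitutions("ACGT", "ACGT") == 0

    def test_single_difference(self):
        assert count_substitutions("ACGT", "ACGA") == 1

    def test_donor_vs_wildtype_first_ten_codons_is_five(self):
        assert (
            count_substitutions(
                actin.donor_first10_codons(), actin.ACTB_CDS_FIRST10_CODONS
            )
            == 5
        )

    def test_window(self):
        assert count_substitutions("AAAACC", "AAAAGG", window=(0, 4)) == 0
        assert count_substitutions("AAAACC", "AAAAGG", window=(4, 6)) == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            count_substitutions("AAA", "AAAA")


class TestRestrictionSites:
    def test_trivial_position(self):
        sites = find_restriction_sites("AAGATATCAA", "GATATC")
        assert [s.position for s in sites] == [2]

    def test_donor_template_has_no_ecorv_site(self):
        assert find_restriction_sites(actin.ACTBCG_DONOR_TEMPLATE, "GATATC") == []

    def test_wildtype_nterminus_has_ecorv_site(self):
        sites = find_restriction_sites(actin.ACTB_CDS_FIRST10_CODONS, "GATATC")
        assert [s.position for s in sites] == [9]

    def test_nonpalindromic_scanned_both_strands(self):
        # oracle: naive double scan of the sequence and its reverse complement
        motif = "GACGTC"[:5] + "A"  # GACGTA, non-palindromic
        seq = "TTGACGTATT" + reverse_complement("GACGTA") + "TT"
        sites = find_restriction_sites(seq, "GACGTA")
        expected_plus = [
            i for i in range(len(seq) - 5) if seq[i : i + 6] == "GACGTA"
        ]
        rc = reverse_complement("GACGTA")
        expected_minus = [
            i for i in range(len(seq) - 5) if seq[i : i + 6] == rc
        ]
        assert [s.position for s in sites if s.strand == "+"] == expected_plus
        assert [s.position for s in sites if s.strand == "-"] == expected_minus

    def test_palindromic_single_scan(self):
        sites = find_restriction_sites("GATATCGATATC", "GATATC")
        assert all(s.strand == "+" for s in sites)
        assert [s.position for s in sites] == [0, 6]


class TestDigest:
    def _amplicon_with_site_at(self, cut_at, total=900):
        motif, offset = ENZYMES["EcoRV"]
        start = cut_at - offset
        left = "A" * start
        right = "A" * (total - start - len(motif))
        return left + motif + right

    def test_wildtype_genotype_bands(self):
        # synthetic 900-bp amplicon, one EcoRV site cutting at 600 -> 600+300
        amp = self._amplicon_with_site_at(600)
        result = digest_fragments(amp, enzyme="EcoRV")
        assert result.fragment_lengths == (600, 300)
        assert result.cut_positions == (600,)

    def test_edited_allele_single_band(self):
        result = digest_fragments("A" * 900, enzyme="EcoRV")
        assert result.fragment_lengths == (900,)
        assert result.cut_positions == ()

    def test_two_sites_three_fragments(self):
        motif, offset = ENZYMES["EcoRV"]
        amp = "A" * 100 + motif + "C" * 100 + motif + "G" * 100
        result = digest_fragments(amp, enzyme="EcoRV")
        assert len(result.fragment_lengths) == 3
        assert sum(result.fragment_lengths) == len(amp)
        # oracle: manual split at site_start + 3
        cuts = [100 + offset, 100 + 6 + 100 + offset]
        assert list(result.cut_positions) == cuts

    @given(st.text(alphabet="ACGT", min_size=10, max_size=300))
    @settings(max_examples=80, deadline=None)
    def test_fragments_sum_to_length(self, seq):
        try:
            result = digest_fragments(seq, enzyme="EcoRV")
        except ValueError:
            return  # cut at the very edge of the sequence
        assert sum(result.fragment_lengths) == len(seq)

    def test_invariant_cut_count(self):
        with pytest.raises(ValueError):
            DigestResult("E", "GATATC", (1, 2), (3,))

    def test_unknown_enzyme(self):
        with pytest.raises(ValueError, match="unknown enzyme"):
            digest_fragments("ACGT", enzyme="NoSuchEnzyme")

    def test_custom_motif(self):
        result = digest_fragments("AAGGCCAA", motif="GGCC", cut_offset=2)
        assert result.fragment_lengths == (4, 4)
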