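"""Recognition-site scanning, in-silico PCR, digestion, and marker design."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import capskit as ck
from capskit.caps import (
    PrimerParams,
    design_caps,
    digest,
    find_discriminating_enzymes,
    in_silico_pcr,
    scan_recognition_sites,
)
from capskit.enzymes import Enzyme, load_enzymes
from capskit.exceptions import (
    AmbiguousPrimerError,
    CoordinateError,
    NoProductError,
)
from capskit.iupac import reverse_complement

BSPHI = Enzyme("BspHI", "TCATGA", 1)
ECORI = Enzyme("EcoRI", "GAATTC", 1)
#: non-palindromic cutter for strand-symmetry checks
ASYM = Enzyme("FakeI", "GACGTG", 2)


class TestScan:
    def test_bsphi_single_site(self) -> None:
        assert scan_recognition_sites("TCATGA", BSPHI) == [1]

    def test_no_site(self) -> None:
        assert scan_recognition_sites("TTTTTT", BSPHI) == []
        assert scan_recognition_sites("", BSPHI) == []

    def test_both_orientations_for_asymmetric_enzyme(self) -> None:
        # forward match at 2 cuts at 4; reverse-complement match at 10
        # (CACGTC) cuts at the mirrored offset 10 + 6 - 2 = 14
        seq = "AA" + "GACGTG" + "TT" + "CACGTC" + "AA"
        assert scan_recognition_sites(seq, ASYM) == [4, 14]

    def test_palindrome_reports_one_cut_per_occurrence(self) -> None:
        seq = "AAATCATGAAAA"
        assert scan_recognition_sites(seq, BSPHI) == [4]

    def test_strand_symmetry_nonpalindromic(self) -> None:
        """Cut positions of seq and revcomp(seq) are mirror images."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            fwd = scan_recognition_sites(seq, ASYM)
            rev = scan_recognition_sites(reverse_complement(seq), ASYM)
            assert sorted(len(seq) - c for c in fwd) == rev

    def test_strand_symmetry_palindromic_match_positions(self) -> None:
        """Palindromic recognition sites are found at mirrored positions on
        the reverse complement (both orientations see the same occurrences)."""
        from capskit.caps import match_starts

        rng = np.random.default_rng(1)
        length = len(BSPHI.recognition)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=120))
            fwd = match_starts(seq, BSPHI)
            rev = match_starts(reverse_complement(seq), BSPHI)
            assert sorted(len(seq) - length - s for s in fwd) == rev

    def test_strand_symmetry_blunt_palindromic_fragments(self) -> None:
        """A centrally cutting palindromic enzyme (DraI, TTT^AAA) digests a
        sequence and its reverse complement into identical fragment sets."""
        drai = Enzyme("DraI", "TTTAAA", 3)
        rng = np.random.default_rng(2)
        for _ in range(50):
            seq = "".join(rng.choice(list("AT"), size=100))
            assert digest(seq, drai) == digest(reverse_complement(seq), drai)


class TestDigest:
    def test_fire_ant_marker_fragment_sizes(self) -> None:
        """One BspHI cut at position 441 of a 631 bp amplicon: 441 + 190;
        the allele destroying the site leaves the product undigested."""
        cut_seq = "A" * 440 + "TCATGA" + "A" * 185
        assert len(cut_seq) == 631
        assert digest(cut_seq, BSPHI) == [441, 190]
        uncut_seq = "A" * 440 + "CCATGA" + "A" * 185
        assert digest(uncut_seq, BSPHI) == [631]

    def test_minimal_recognition_site(self) -> None:
        assert digest("TCATGA", BSPHI) == [5, 1]

    def test_no_site_returns_full_length(self) -> None:
        assert digest("A" * 57, BSPHI) == [57]

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=200),
        st.sampled_from(load_enzymes()),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_fragment_length_conservation(self, seq: str, enzyme: Enzyme) -> None:
        fragments = digest(seq, enzyme)
        assert sum(fragments) == len(seq)
        assert fragments == sorted(fragments, reverse=True)
        assert all(f > 0 for f in fragments)

    def test_conservation_bulk_random(self) -> None:
        """10,000 random (sequence, enzyme) pairs conserve total length."""
        rng = np.random.default_rng(12345)
        enzymes = load_enzymes()
        for _ in range(10_000):
            n = int(rng.integers(1, 120))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            enz = enzymes[int(rng.integers(len(enzymes)))]
            assert sum(digest(seq, enz)) == n


class TestInSilicoPcr:
    REF = {"ctg": "ATGCGTACGTTAGCCGATCA" + "G" * 30 + "TTACGGATCGATCCAGGTAC"}

    def test_full_span_product(self) -> None:
        seq = self.REF["ctg"]
        amp = in_silico_pcr(self.REF, seq[:20], reverse_complement(seq[-20:]))
        assert amp.sequence == seq
        assert (amp.start, amp.end) == (1, len(seq))

    def test_internal_product_length(self) -> None:
        seq = self.REF["ctg"]
        fwd = seq[5:25]
        rev = reverse_complement(seq[40:60])
        amp = in_silico_pcr(self.REF, fwd, rev)
        assert len(amp) == 55
        assert amp.sequence.startswith(fwd)
        assert amp.sequence.endswith(reverse_complement(rev))

    def test_no_product(self) -> None:
        with pytest.raises(NoProductError):
            in_silico_pcr(self.REF, "T" * 20, "A" * 20)

    def test_duplicated_primer_site_is_ambiguous(self) -> None:
        ref = {"ctg": "ACGTACGTACGTACGTAAAA" + "C" * 20
               + "ACGTACGTACGTACGTAAAA" + "C" * 20}
        with pytest.raises(AmbiguousPrimerError):
            in_silico_pcr(ref, "ACGTACGTACGTACGTAAAA", "G" * 20)

    def test_short_primers_rejected(self) -> None:
        with pytest.raises(ck.exceptions.ParameterError):
            in_silico_pcr(self.REF, "ACGT", "ACGT")


class TestDiscriminatingEnzymes:
    def _reference(self, context: str) -> dict[str, str]:
        return {"ctg": "GGG" + context + "GGG"}

    def test_bsphi_t_c_site(self) -> None:
        """T at the first motif base completes TCATGA; C destroys it."""
        ref = self._reference("TCATGA")
        found = find_discriminating_enzymes(ref, "ctg", 4, ("T", "C"), [BSPHI])
        assert [(e.name, allele) for e, allele in found] == [("BspHI", "T")]

    def test_no_allele_dependence(self) -> None:
        ref = self._reference("AAAAAA")
        assert find_discriminating_enzymes(ref, "ctg", 4, ("T", "C"), [BSPHI]) == []

    def test_one_allele_creates_sites_for_two_enzymes(self) -> None:
        # G simultaneously completes CTGCAG (PstI, ending at the site) and
        # GAATTC (EcoRI, starting at the site)
        psti = Enzyme("PstI", "CTGCAG", 5)
        ref = {"ctg": "CCC" + "CTGCA" + "G" + "AATTC" + "CCC"}
        found = find_discriminating_enzymes(
            ref, "ctg", 9, ("G", "T"), [ECORI, psti]
        )
        names = sorted((e.name, a) for e, a in found)
        assert names == [("EcoRI", "G"), ("PstI", "G")]

    def test_out_of_bounds_position(self) -> None:
        with pytest.raises(CoordinateError):
            find_discriminating_enzymes({"c": "ACGT"}, "c", 99, ("A", "T"), [BSPHI])


class TestDesignCaps:
    def _synthetic_reference(self) -> dict[str, str]:
        """One T/C key site at pos 101 inside a BspHI motif; background free
        of BspHI sites."""
        rng = np.random.default_rng(8)
        left = "".join(rng.choice(list("ACG"), size=100))
        right = "".join(rng.choice(list("ACG"), size=100))
        # site at index 100 (pos 101) is the leading T of TCATGA
        return {"mt": left + "TCATGA" + right[5:]}

    def _key_site(self, pos: int, g_a: str = "TT", g_b: str = "CC"):
        return ck.SiteTestResult(
            seqid="mt", pos=pos, g_a=g_a, g_b=g_b, observed_a=38, observed_b=5,
            expected_a=38.0, expected_b=5.0, chi2=0.0, p_value=1.0, is_key=True,
        )

    def test_single_implanted_marker(self) -> None:
        ref = self._synthetic_reference()
        markers, _ = design_caps(
            ref, [self._key_site(101)], [BSPHI],
            primer_params=PrimerParams(primer_length=20, amplicon_radius=90),
        )
        assert len(markers) == 1
        m = markers[0]
        assert m.enzyme.name == "BspHI"
        assert m.discriminating_allele == "T"
        assert len(m.fragments_by_allele["T"]) == 2
        assert m.fragments_by_allele["C"] == [len(m.amplicon)]
        for frags in m.fragments_by_allele.values():
            assert sum(frags) == len(m.amplicon)

    def test_empty_enzyme_list(self) -> None:
        markers, warnings = design_caps(self._synthetic_reference(),
                                        [self._key_site(101)], [])
        assert markers == []
        assert warnings  # warning log mentions the empty result

    def test_site_cut_under_both_alleles_not_a_marker(self) -> None:
        # the key site sits at the W of an AvaII site (GGWCC) and the two
        # alleles are A and T: the motif matches under both, so the enzyme
        # does not discriminate and no marker is emitted
        avaii = Enzyme("AvaII", "GGWCC", 1)
        ref = {"mt": "G" * 100 + "GGACC" + "G" * 100}
        markers, _ = design_caps(ref, [self._key_site(103, "AA", "TT")], [avaii])
        assert markers == []

    def test_heterozygous_major_skipped_with_warning(self) -> None:
        markers, warnings = design_caps(
            self._synthetic_reference(), [self._key_site(101, "TC", "CC")],
            [BSPHI],
        )
        assert markers == []
        assert any("not distinct homozygotes" in w for w in warnings)
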