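"""Core-element and PWM scanners against naive independent matchers."""

import numpy as np
import pytest
from Bio import motifs as bio_motifs

from bdpscan.annotation_io import GenomicInterval, reverse_complement
from bdpscan.motif_scan import (
    CORE_ELEMENTS,
    JasparParseError,
    MotifHit,
    PositionFrequencyMatrix,
    motif_map,
    pfm_to_pwm,
    read_jaspar,
    scan_core_elements,
    scan_pwm,
)
from bdpscan.promoter_fragments import PromoterFragment
from conftest import naive_pwm_hits, regex_core_hits

BY_NAME = {p.name: p for p in CORE_ELEMENTS}


def random_pfm(rng, length, motif_id="MX0001", bias=None):
    counts = rng.integers(0, 30, size=(4, length)).astype(float)
    counts[:, counts.sum(axis=0) == 0] += 1.0
    if bias is not None:
        for j, b in enumerate(bias):
            counts["ACGT".index(b), j] += 200.0
    return PositionFrequencyMatrix(motif_id=motif_id, motif_name=motif_id, counts=counts)


class TestCoreElements:
    def test_pattern_lengths(self):
        assert {p.name: len(p) for p in CORE_ELEMENTS} == {
            "TATA": 6,
            "INR": 7,
            "BRE": 7,
            "DPE": 6,
            "CCAAT": 9,
        }

    @pytest.mark.parametrize(
        "seq,name,expected_plus",
        [
            ("TGTAAA", "TATA", set()),  # G breaks [AT] at position 2
            ("TTATAA", "TATA", {(1, 6)}),
            ("GCGCGCC", "BRE", {(1, 7)}),
            ("AGCCAATCA", "CCAAT", {(1, 9)}),
        ],
    )
    def test_known_matches(self, seq, name, expected_plus):
        hits = scan_core_elements(seq, patterns=(BY_NAME[name],), both_strands=False)
        assert {(h.start, h.end) for h in hits} == expected_plus

    def test_windows_with_n_never_match(self):
        hits = scan_core_elements("TTANAA", patterns=(BY_NAME["TATA"],))
        assert hits == []

    def test_non_iupac_characters_rejected(self):
        with pytest.raises(ValueError):
            scan_core_elements("ACGTX")

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 200))))
            got = {
                (h.name, h.start, h.end, h.strand, h.matched_seq)
                for h in scan_core_elements(seq)
            }
            want = set()
            for p in CORE_ELEMENTS:
                want |= regex_core_hits(seq, p.name, p.pattern)
            assert got == want

    def test_strand_mirror(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=150))
        fwd = scan_core_elements(seq)
        rev = scan_core_elements(reverse_complement(seq))
        n = len(seq)
        mirrored = {
            (h.name, n - h.end + 1, n - h.start + 1, "-" if h.strand == "+" else "+")
            for h in rev
        }
        assert {(h.name, h.start, h.end, h.strand) for h in fwd} == mirrored


class TestJaspar:
    def test_round_trip(self, jaspar_file):
        pfms = read_jaspar(jaspar_file)
        assert [(p.motif_id, p.length) for p in pfms] == [
            ("MA0001.1", 5),
            ("MA0002.1", 2),
        ]
        assert pfms[0].consensus == "ACGTC"

    def test_float_counts_accepted(self, jaspar_file):
        pfms = read_jaspar(jaspar_file)
        assert pfms[1].counts[0, 0] == pytest.approx(4.5)

    def test_missing_row_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.jaspar"
        path.write_text(">MA9999.1 BAD\nA [ 1 2 ]\nC [ 3 4 ]\nG [ 5 6 ]\n")
        with pytest.raises(JasparParseError, match="MA9999.1"):
            read_jaspar(path)

    def test_unequal_row_lengths_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.jaspar"
        path.write_text(
            ">MA9999.1 BAD\nA [ 1 2 ]\nC [ 3 4 ]\nG [ 5 6 ]\nT [ 7 8 9 ]\n"
        )
        with pytest.raises(JasparParseError, match="unequal"):
            read_jaspar(path)


class TestPfmToPwm:
    def test_single_column_formula(self):
        pfm = PositionFrequencyMatrix(
            "M1", "M1", np.array([[10.0], [0.0], [0.0], [0.0]])
        )
        pwm = pfm_to_pwm(pfm, pseudocount=0.8)
        # (10 + 0.8*0.25) / (10 + 0.8) / 0.25, log2
        assert pwm.weights[0, 0] == pytest.approx(np.log2((10.2 / 10.8) / 0.25))
        assert (pwm.weights[1:, 0] < 0).all()

    def test_uniform_counts_are_uninformative(self):
        pfm = PositionFrequencyMatrix("M1", "M1", np.full((4, 3), 5.0))
        pwm = pfm_to_pwm(pfm)
        assert np.allclose(pwm.weights, 0.0)

    def test_score_extrema_are_column_sums(self):
        rng = np.random.default_rng(2)
        pfm = random_pfm(rng, 5)
        pwm = pfm_to_pwm(pfm)
        assert pwm.score_max == pytest.approx(pwm.weights.max(axis=0).sum())
        assert pwm.score_min == pytest.approx(pwm.weights.min(axis=0).sum())
        assert pwm.score_min < pwm.score_max

    def test_matches_reference_pssm(self, jaspar_file):
        """Same log-odds as the Biopython PSSM with equivalent pseudocounts."""
        with open(jaspar_file) as fh:
            ref = bio_motifs.parse(fh, "jaspar")[0]
        pssm = ref.counts.normalize(pseudocounts={b: 0.2 for b in "ACGT"}).log_odds(
            {b: 0.25 for b in "ACGT"}
        )
        ref_weights = np.array([pssm[b] for b in "ACGT"])
        ours = pfm_to_pwm(read_jaspar(jaspar_file)[0], pseudocount=0.8)
        assert np.allclose(ours.weights, ref_weights, atol=1e-12)

    def test_invalid_inputs(self):
        pfm = PositionFrequencyMatrix("M1", "M1", np.full((4, 2), 1.0))
        with pytest.raises(ValueError):
            pfm_to_pwm(pfm, pseudocount=0.0)
        with pytest.raises(ValueError):
            pfm_to_pwm(pfm, background=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="all-zero"):
            PositionFrequencyMatrix("M2", "M2", np.zeros((4, 2)))


class TestScanPwm:
    def test_consensus_scores_one(self):
        rng = np.random.default_rng(3)
        pwm = pfm_to_pwm(random_pfm(rng, 6, bias="ACGTAC"))
        seq = "TT" + "ACGTAC" + "GG"
        hits = scan_pwm(seq, pwm, rel_threshold=1.0)
        assert any(
            h.start == 3 and h.strand == "+" and h.relative_score == pytest.approx(1.0)
            for h in hits
        )

    def test_threshold_one_excludes_non_consensus(self):
        rng = np.random.default_rng(3)
        pwm = pfm_to_pwm(random_pfm(rng, 6, bias="ACGTAC"))
        hits = scan_pwm("TTACGTTCGG", pwm, rel_threshold=1.0)
        assert [h for h in hits if h.strand == "+"] == []

    def test_windows_with_n_skipped(self):
        rng = np.random.default_rng(3)
        pwm = pfm_to_pwm(random_pfm(rng, 4, bias="ACGT"))
        assert scan_pwm("ANGT" * 3, pwm, rel_threshold=0.1) == []

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(44)
        for _ in range(20):
            pwm = pfm_to_pwm(random_pfm(rng, int(rng.integers(4, 10))))
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=200))
            got = {(h.start, h.end, h.strand) for h in scan_pwm(seq, pwm, 0.70)}
            assert got == naive_pwm_hits(seq, pwm, 0.70)

    def test_relative_scores_respect_threshold(self):
        rng = np.random.default_rng(9)
        pwm = pfm_to_pwm(random_pfm(rng, 8))
        seq = "".join(rng.choice(list("ACGT"), size=300))
        for h in scan_pwm(seq, pwm, 0.75):
            assert h.relative_score >= 0.75
            assert h.end - h.start + 1 == pwm.length

    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        pfm = random_pfm(rng, 7)
        seq = "".join(rng.choice(list("ACGT"), size=250))
        base = scan_pwm(seq, pfm_to_pwm(pfm, pseudocount=0.8), 0.70)
        scaled_pfm = PositionFrequencyMatrix("MX0001", "MX0001", pfm.counts * 3.5)
        scaled = scan_pwm(seq, pfm_to_pwm(scaled_pfm, pseudocount=0.8 * 3.5), 0.70)
        assert [(h.start, h.strand) for h in base] == [(h.start, h.strand) for h in scaled]
        for a, b in zip(base, scaled):
            assert a.relative_score == pytest.approx(b.relative_score, abs=1e-9)


class TestMotifMap:
    def _fragment(self, seq="ACGT" * 25):
        return PromoterFragment(
            fragment_id="f1",
            source="bdp",
            interval=GenomicInterval("chr1", 1, len(seq)),
            sequence=seq,
        )

    def test_sorted_by_start(self):
        frag = self._fragment()
        hits = [
            MotifHit("core_element", "TATA", 50, 55, "+", "TTATAA"),
            MotifHit("core_element", "DPE", 10, 15, "+", "ACATAC"),
            MotifHit("pwm", "NFY", 30, 37, "-", "ACGTACGT", score=3.0, relative_score=0.8),
        ]
        table = motif_map(frag, hits)
        assert list(table["start"]) == [10, 30, 50]

    def test_empty_hits_give_empty_table_with_headers(self):
        table = motif_map(self._fragment(), [])
        assert len(table) == 0
        assert "relative_score" in table.columns

    def test_out_of_range_hit_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            motif_map(
                self._fragment("ACGT"),
                [MotifHit("core_element", "TATA", 2, 7, "+", "TTATAA")],
            )
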