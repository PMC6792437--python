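import math

import numpy as np
import pytest

from diazoscan import synth
from diazoscan.io import ReadRecord, SequenceRecord, reverse_complement
from diazoscan.markers import (
    _BLOSUM62,
    PrositeSyntaxError,
    karlin_altschul_evalue,
    prosite_parse,
    prosite_scan,
    recruited_read_identity,
    screen_gene,
    six_frame_translate,
    smith_waterman,
)

from conftest import prosite_regex_oracle, random_prosite_pattern, sw_oracle


class TestSixFrame:
    def test_start_codon(self):
        assert six_frame_translate("ATG")[1] == "M"

    def test_six_frames_always(self):
        frames = six_frame_translate("ATGAAACCCGGG")
        assert set(frames) == {1, 2, 3, -1, -2, -3}

    def test_reverse_complement_symmetry(self):
        s = "ATGAAACCCGGGTTTACG"
        assert six_frame_translate(reverse_complement(s))[1] == six_frame_translate(s)[-1]

    def test_partial_codon_dropped(self):
        assert six_frame_translate("ATGA")[1] == "M"

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            six_frame_translate("AT")


class TestSmithWaterman:
    def test_self_alignment_is_diagonal_sum(self):
        seq = "MKVLAWHE"
        expected = sum(_BLOSUM62[a, a] for a in seq)
        assert smith_waterman(seq, seq, score_only=True) == expected

    def test_no_similarity_scores_zero(self):
        score, a_span, b_span = smith_waterman("PP", "GG")
        assert score == 0.0 and a_span == (0, 0)

    def test_bad_residue_errors(self):
        with pytest.raises(ValueError):
            smith_waterman("M@K", "MKK")

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        aas = synth.AMINO_ACIDS
        for _ in range(40):
            a = "".join(aas[i] for i in rng.integers(20, size=30))
            b = "".join(aas[i] for i in rng.integers(20, size=30))
            assert smith_waterman(a, b, score_only=True) == pytest.approx(sw_oracle(a, b))

    def test_score_monotone_under_extension(self):
        rng = np.random.default_rng(6)
        aas = synth.AMINO_ACIDS
        a = "".join(aas[i] for i in rng.integers(20, size=25))
        b = "".join(aas[i] for i in rng.integers(20, size=25))
        s0 = smith_waterman(a, b, score_only=True)
        assert smith_waterman(a + "WWW", b, score_only=True) >= s0


class TestEvalue:
    def test_decreasing_in_score(self):
        e = [karlin_altschul_evalue(s, 300, 100000) for s in (50, 100, 200)]
        assert e[0] > e[1] > e[2]

    def test_linear_in_db_size(self):
        assert karlin_altschul_evalue(100, 300, 2_000) == pytest.approx(
            2 * karlin_altschul_evalue(100, 300, 1_000)
        )

    def test_direct_formula(self):
        expected = 0.134 * 300 * 1e5 * math.exp(-0.3176 * 200)
        assert karlin_altschul_evalue(200, 300, 100_000) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            karlin_altschul_evalue(-1, 300, 1000)


class TestProsite:
    def test_parse_simple(self):
        pat = prosite_parse("C-x(2)-C")
        assert len(pat.elements) == 3
        assert pat.elements[1].min_count == 2 and pat.elements[1].max_count == 2

    def test_parse_variable_repeat_and_sets(self):
        pat = prosite_parse("[LIVM]-x(1,2)-D")
        assert pat.elements[0].residues == frozenset("LIVM")
        assert (pat.elements[1].min_count, pat.elements[1].max_count) == (1, 2)

    def test_round_trip(self):
        for text in ("C-x(2)-C", "<[AC]-{PG}(2,3)-x-W>", "M-x(4)-[DE]"):
            assert prosite_parse(prosite_parse(text).to_text()).to_text() == prosite_parse(text).to_text()

    @pytest.mark.parametrize("bad", ["C-x(", "C--C", "[]-C", "C-x(2,1)", ""])
    def test_malformed_patterns_error(self, bad):
        with pytest.raises(PrositeSyntaxError):
            prosite_parse(bad)

    def test_scan_worked_example(self):
        spans = prosite_scan("ACTTC", prosite_parse("C-x(2)-C"))
        assert spans == [(1, 5)]

    def test_n_anchor_only_matches_start(self):
        pat = prosite_parse("<A-x")
        assert prosite_scan("ACAC", pat) == [(0, 2)]

    def test_c_anchor_only_matches_end(self):
        pat = prosite_parse("A-C>")
        assert prosite_scan("ACAC", pat) == [(2, 4)]

    def test_negated_set(self):
        pat = prosite_parse("{AC}-W")
        assert prosite_scan("AWCWGW", pat) == [(4, 6)]

    def test_equals_regex_oracle_on_random_cases(self):
        rng = np.random.default_rng(9)
        aas = synth.AMINO_ACIDS
        for _ in range(300):
            text = random_prosite_pattern(rng)
            protein = "".join(aas[i] for i in rng.integers(20, size=int(rng.integers(5, 60))))
            got = prosite_scan(protein, prosite_parse(text))
            assert got == prosite_regex_oracle(protein, text), text


class TestScreenGene:
    def test_planted_gene_passes_all_three_filters(self, refdb, motif):
        gene = SequenceRecord("g", synth.reverse_translate(refdb[0].residues, 1))
        hit = screen_gene(gene, refdb, motif)
        assert hit.verdict and hit.evalue < 1e-50 and hit.top_hit_label_ok and hit.motif_ok
        assert hit.frame == 1 and hit.best_ref_id == refdb[0].id

    def test_motif_scramble_flips_motif_flag(self, refdb, motif):
        from diazoscan.markers import prosite_scan as scan

        prot = refdb[0].residues
        span = scan(prot, motif)[0]
        core = prot[span[0] : span[1]]
        scrambled = prot[: span[0]] + core[::-1].replace("C", "A") + prot[span[1] :]
        gene = SequenceRecord("g", synth.reverse_translate(scrambled, 2))
        hit = screen_gene(gene, refdb, motif)
        assert not hit.motif_ok and not hit.verdict

    def test_random_gene_fails_evalue(self, refdb, motif):
        gene = synth.generate_genome(870, 0.5, 77, genome_id="rand")
        hit = screen_gene(gene, refdb, motif)
        assert hit.evalue > 1e-50 and not hit.verdict

    def test_label_keyword_checked_case_insensitively(self, refdb, motif):
        plain = [SequenceRecord(r.id, r.residues, "hypothetical protein") for r in refdb]
        gene = SequenceRecord("g", synth.reverse_translate(refdb[0].residues, 1))
        hit = screen_gene(gene, plain, motif)
        assert not hit.top_hit_label_ok and not hit.verdict

    def test_short_gene_errors(self, refdb, motif):
        with pytest.raises(ValueError):
            screen_gene(SequenceRecord("g", "AT"), refdb, motif)


class TestReadIdentity:
    def _reads_at_error(self, gene, n, error_rate, seed, read_len=120):
        comm = synth.CommunitySpec(
            [gene], [("s", n, np.array([1.0]))], read_length=read_len,
            error_rate=error_rate, seed=seed,
        )
        return synth.simulate_reads(comm)[0]["s"]

    @pytest.fixture()
    def gene(self, refdb):
        return SequenceRecord("nifH", synth.reverse_translate(refdb[0].residues, 3))

    def test_error_free_reads_have_full_identity(self, gene):
        summary = recruited_read_identity(gene, self._reads_at_error(gene, 50, 0.0, 1))
        assert summary.mean_identity == pytest.approx(100.0)

    def test_mean_identity_tracks_error_rate(self, gene):
        summary = recruited_read_identity(gene, self._reads_at_error(gene, 200, 0.01, 2))
        assert 98.5 <= summary.mean_identity <= 99.5

    def test_short_alignments_excluded(self, gene):
        reads = [ReadRecord("r", gene.residues[10:90], "I" * 80)]
        summary = recruited_read_identity(gene, reads, min_align_len=100)
        assert summary.n_reads == 0 and summary.mean_identity is None
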