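import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diazoscan import recruitment, synth
from diazoscan.io import AlignmentRecord, SequenceRecord
from diazoscan.recruitment import (
    CoverageVector,
    cells_per_litre,
    coverage_from_alignments,
    detection,
    map_reads,
    q2q3_mean_coverage,
    relative_abundance,
    sqrt_normalize,
)

from conftest import make_read, quartile_trim_oracle


class TestMapReads:
    @pytest.fixture()
    def refs(self):
        return [synth.generate_genome(3000, 0.5, i, genome_id=f"ref{i}") for i in range(2)]

    def test_exact_substring_maps_with_zero_edits(self, refs):
        read = make_read(refs[0], 500, 100)
        aln = map_reads([read], refs, seed=0)[0]
        assert aln.is_mapped and aln.ref_id == "ref0"
        assert aln.ref_start == 500 and aln.edit_distance == 0 and aln.strand == "+"

    def test_reverse_strand_read_maps(self, refs):
        from diazoscan.io import ReadRecord, reverse_complement

        seq = reverse_complement(refs[1].residues[100:220])
        read = ReadRecord("rc", seq, "I" * len(seq))
        aln = map_reads([read], refs, seed=0)[0]
        assert aln.is_mapped and aln.ref_id == "ref1" and aln.strand == "-" and aln.ref_start == 100

    def test_tie_break_is_uniform(self, refs):
        # identical segment present in both references
        shared = refs[0].residues[1000:1120]
        doctored = SequenceRecord("ref1", refs[1].residues[:1000] + shared + refs[1].residues[1120:])
        reads = [make_read(refs[0], 1000, 120, read_id=f"r{i}") for i in range(10000)]
        alns = map_reads(reads, [refs[0], doctored], seed=123)
        n0 = sum(a.ref_id == "ref0" for a in alns)
        # binomial(10000, 0.5): 4 sigma is +/-200
        assert 4800 <= n0 <= 5200

    def test_foreign_read_unmapped(self, refs):
        foreign = synth.generate_genome(120, 0.5, 999, genome_id="x")
        read = make_read(foreign, 0, 120)
        assert not map_reads([read], refs, seed=0)[0].is_mapped

    def test_low_identity_read_unmapped(self, refs):
        g = refs[0]
        variant, _ = synth.mutate_genome(g, 0.10, 5)  # ~90% identity < 0.95 cutoff
        read = make_read(variant, 500, 100)
        aln = map_reads([read], refs, min_identity=0.95, seed=0)[0]
        assert not aln.is_mapped

    def test_empty_reference_set_errors(self):
        with pytest.raises(ValueError):
            recruitment.ReferenceIndex([])


class TestCoverage:
    def test_single_read_block(self):
        alns = [AlignmentRecord("r", "ref", 0, "+", 100, 0, True)]
        cov = coverage_from_alignments(alns, "ref", 1000)
        assert cov.values[:100].tolist() == [1] * 100
        assert cov.values[100:].sum() == 0
        assert cov.values.mean() == pytest.approx(0.1)

    def test_no_alignments_all_zero(self):
        assert coverage_from_alignments([], "ref", 50).values.sum() == 0

    def test_overlapping_reads_add(self):
        alns = [AlignmentRecord(f"r{i}", "ref", 10, "+", 20, 0, True) for i in range(2)]
        cov = coverage_from_alignments(alns, "ref", 100)
        assert set(cov.values[10:30]) == {2}

    def test_past_end_errors(self):
        alns = [AlignmentRecord("r", "ref", 95, "+", 10, 0, True)]
        with pytest.raises(ValueError):
            coverage_from_alignments(alns, "ref", 100)

    def test_conservation_across_references(self):
        refs = [synth.generate_genome(2000, 0.5, i, genome_id=f"ref{i}") for i in range(3)]
        reads = [make_read(refs[i % 3], 50 * i, 100, read_id=f"r{i}") for i in range(30)]
        alns = map_reads(reads, refs, seed=0)
        total_cov = sum(
            coverage_from_alignments(alns, r.id, len(r)).values.sum() for r in refs
        )
        assert total_cov == sum(a.aligned_length for a in alns if a.is_mapped)


class TestQ2Q3:
    def test_constant_vector_returns_plain_mean(self):
        assert q2q3_mean_coverage(np.array([5, 5, 5, 5])) == 5.0

    def test_small_vector_matches_oracle(self):
        v = np.array([1, 2, 3, 4, 5, 6, 7, 8])
        assert q2q3_mean_coverage(v) == pytest.approx(quartile_trim_oracle(v))

    def test_spike_suppressed(self):
        v = np.array([0, 0, 0, 0, 0, 0, 0, 1000])
        assert q2q3_mean_coverage(v) < v.mean()
        assert q2q3_mean_coverage(v) == pytest.approx(quartile_trim_oracle(v))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            q2q3_mean_coverage(np.array([]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=60))
    def test_equals_oracle_and_stays_bounded(self, values):
        v = np.array(values)
        got = q2q3_mean_coverage(v)
        assert got == pytest.approx(quartile_trim_oracle(v))
        assert v.min() <= got <= v.max()


class TestScalars:
    def test_detection(self):
        assert detection(np.array([0, 0, 1, 2])) == 0.5
        assert detection(np.zeros(10)) == 0.0

    def test_detection_monotone_in_alignments(self):
        base = [AlignmentRecord("a", "ref", 0, "+", 10, 0, True)]
        more = base + [AlignmentRecord("b", "ref", 50, "+", 10, 0, True)]
        d0 = detection(coverage_from_alignments(base, "ref", 100))
        d1 = detection(coverage_from_alignments(more, "ref", 100))
        assert d1 >= d0

    def test_relative_abundance(self):
        assert relative_abundance(70, 1000) == pytest.approx(0.07)
        assert relative_abundance(0, 1000) == 0.0
        with pytest.raises(ValueError):
            relative_abundance(1, 0)

    def test_cells_per_litre(self):
        assert cells_per_litre(0.0014) == pytest.approx(700_000)
        assert cells_per_litre(0.0) == 0.0
        assert cells_per_litre(0.2) == 2 * cells_per_litre(0.1)

    def test_sqrt_normalize(self):
        assert sqrt_normalize(0.04) == pytest.approx(0.2)
        assert sqrt_normalize(0) == 0
        with pytest.raises(ValueError):
            sqrt_normalize(-1)
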