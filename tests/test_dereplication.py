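import math

import numpy as np
import pytest

from diazoscan import synth
from diazoscan.dereplication import (
    AniResult,
    RedundancyGroup,
    fragment_ani,
    pearson_r,
    redundancy_graph,
    select_representative,
)
from diazoscan.mag_stats import MagRecord

from conftest import partition_closure_oracle


def _mag(mid, completion, redundancy, length=3_000_000):
    return MagRecord(
        mag_id=mid, total_length=length, n_contigs=1, n50=length, gc=50.0,
        completion=completion, redundancy=redundancy,
    )


class TestFragmentAni:
    def test_identical_genomes(self):
        from diazoscan.io import SequenceRecord

        g = synth.generate_genome(50_000, 0.5, 1, genome_id="a")
        other = SequenceRecord("b", g.residues)
        res = fragment_ani(g, other)
        assert res.ani == pytest.approx(100.0)
        assert res.aligned_fraction == pytest.approx(1.0)

    def test_ani_tracks_realized_divergence(self):
        g = synth.generate_genome(50_000, 0.5, 2, genome_id="a")
        v, div = synth.mutate_genome(g, 0.01, 3)
        res = fragment_ani(g, v)
        assert res.ani == pytest.approx(100 * (1 - div), abs=0.2)
        assert res.aligned_fraction > 0.95

    def test_unrelated_genomes_do_not_align(self):
        a = synth.generate_genome(30_000, 0.5, 4, genome_id="a")
        b = synth.generate_genome(30_000, 0.5, 5, genome_id="b")
        res = fragment_ani(a, b)
        assert res.aligned_fraction < 0.05

    def test_tiny_genome_single_fragment_fallback(self):
        g = synth.generate_genome(400, 0.5, 6, genome_id="a")
        from diazoscan.io import SequenceRecord

        res = fragment_ani(g, SequenceRecord("b", g.residues))
        assert res.ani == pytest.approx(100.0)
        assert res.n_fragments_aligned == 1


class TestPearson:
    def test_self_correlation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_closed_form(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        # independent direct-sum computation
        n = 3
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = math.sqrt(n * (x * x).sum() - x.sum() ** 2) * math.sqrt(n * (y * y).sum() - y.sum() ** 2)
        assert pearson_r(x, y) == pytest.approx(num / den)

    def test_constant_vector_is_undefined(self):
        assert pearson_r(np.ones(5), np.arange(5.0)) is None


class TestRedundancyGraph:
    def _graph(self, pair_specs, n=3):
        ids = [f"m{i}" for i in range(n)]
        ab = np.tile(np.arange(5.0), (n, 1)) + np.arange(n)[:, None]  # non-constant rows
        results = [AniResult(a, b, ani, frac, 1) for (a, b, ani, frac, _) in pair_specs]
        pair_r = {frozenset((a, b)): r for (a, b, _, _, r) in pair_specs}
        return redundancy_graph(ids, results, ab, {m: i for i, m in enumerate(ids)}, pair_r=pair_r)

    def test_passing_pair_merges(self):
        groups = self._graph([("m0", "m1", 99.5, 0.8, 0.95)])
        assert ["m0", "m1"] in [g.members for g in groups]

    def test_low_correlation_blocks_merge(self):
        groups = self._graph([("m0", "m1", 99.5, 0.8, 0.5)])
        assert all(len(g.members) == 1 for g in groups)

    @pytest.mark.parametrize(
        "ani,frac,r",
        [(98.9, 0.8, 0.95), (99.5, 0.75, 0.95), (99.5, 0.8, 0.9)],
        ids=["ani-below", "frac-at-threshold", "r-at-threshold"],
    )
    def test_threshold_edges_are_strict_where_quoted(self, ani, frac, r):
        # "reached 99%" is inclusive; ">75%" and "above 0.9" are strict
        groups = self._graph([("m0", "m1", ani, frac, r)])
        assert all(len(g.members) == 1 for g in groups)

    def test_ani_exactly_99_merges(self):
        groups = self._graph([("m0", "m1", 99.0, 0.8, 0.95)])
        assert ["m0", "m1"] in [g.members for g in groups]

    def test_chain_forms_one_group(self):
        groups = self._graph(
            [("m0", "m1", 99.5, 0.8, 0.95), ("m1", "m2", 99.5, 0.8, 0.95)]
        )
        assert [g.members for g in groups if len(g.members) > 1] == [["m0", "m1", "m2"]]

    def test_missing_abundance_row_errors(self):
        with pytest.raises(ValueError):
            redundancy_graph(["m0"], [], np.ones((0, 5)), {})

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 13))
            ids = [f"m{i}" for i in range(n)]
            table = {}
            for i in range(n):
                for j in range(i + 1, n):
                    table[(ids[i], ids[j])] = (
                        float(rng.uniform(97.5, 100)),
                        float(rng.uniform(0.5, 1.0)),
                        float(rng.uniform(-1, 1)),
                    )
            specs = [(a, b, ani, frac, r) for (a, b), (ani, frac, r) in table.items()]
            groups = self._graph(specs, n=n)
            got = {frozenset(g.members) for g in groups}

            def predicate(a, b):
                ani, frac, r = table[(a, b)] if (a, b) in table else table[(b, a)]
                return ani >= 99.0 and frac > 0.75 and r > 0.9

            assert got == partition_closure_oracle(ids, predicate)


class TestSelectRepresentative:
    def test_highest_completion_minus_redundancy_wins(self):
        # the four-member group whose printed reference row is 98.1/5.6:
        # 92.5 beats 81.2, 89.6 and 90.9
        stats = {
            "anw": _mag("anw", 98.1, 5.6),
            "pon": _mag("pon", 86.8, 5.6),
            "psw": _mag("psw", 98.3, 8.7),
            "pse": _mag("pse", 98.3, 7.4),
        }
        grp = RedundancyGroup(members=sorted(stats))
        assert select_representative(grp, stats) == "anw"

    def test_two_member_group(self):
        stats = {"a": _mag("a", 97.3, 4.6), "b": _mag("b", 83.0, 4.7)}
        assert select_representative(RedundancyGroup(members=["a", "b"]), stats) == "a"

    def test_single_member(self):
        stats = {"only": _mag("only", 50, 5)}
        assert select_representative(RedundancyGroup(members=["only"]), stats) == "only"

    def test_eukarya_by_length(self):
        stats = {"a": _mag("a", 90, 0, length=5_000_000), "b": _mag("b", 10, 0, length=9_000_000)}
        assert select_representative(RedundancyGroup(members=["a", "b"]), stats, domain="eukarya") == "b"

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            select_representative(RedundancyGroup(members=[]), {})
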