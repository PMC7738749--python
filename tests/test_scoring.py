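from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from ogbench import fixtures, scoring
from ogbench.model import IntegrityError, ValidationError, make_universe
from ogbench.scoring import PairCounts

from conftest import gid, gids, collection


class TestBuildGeneIndex:
    def test_direct_construction(self):
        c = collection("c", "predicted", G1=gids("A|a", "A|b"), G2=gids("A|c"))
        idx = scoring.build_gene_index(c)
        assert idx == {gid("A|a"): "G1", gid("A|b"): "G1", gid("A|c"): "G2"}

    def test_empty_collection(self):
        c = collection("c", "predicted")
        assert scoring.build_gene_index(c) == {}

    def test_overlap_strict_errors_first_wins_warns(self, caplog):
        c = collection("c", "predicted", G2=gids("A|a"), G1=gids("A|a", "A|b"))
        with pytest.raises(IntegrityError):
            scoring.build_gene_index(c, policy="strict")
        idx = scoring.build_gene_index(c, policy="first-wins")
        assert idx[gid("A|a")] == "G1"  # lexicographically first label wins


class TestCountPairs:
    def test_identity_prediction(self, small_universe, four_gene_refog):
        pred = collection("p", "predicted", P1=gids("A|a1", "A|a2", "A|a3", "A|a4"))
        (pc,) = scoring.count_pairs(four_gene_refog, pred, small_universe)
        assert (pc.tp_raw, pc.fp_raw, pc.fn_raw) == (comb(4, 2), 0, 0)

    def test_worked_five_gene_example(self, small_universe, four_gene_refog):
        """Split 3+1 with one contaminant: counts enumerated by hand/oracle."""
        pred = collection(
            "p", "predicted",
            P1=gids("A|a1", "A|a2", "A|a3"), P2=gids("A|a4", "A|x"),
        )
        (pc,) = scoring.count_pairs(four_gene_refog, pred, small_universe)
        assert (pc.tp_raw, pc.fn_raw, pc.fp_raw) == (3, 3, 1)
        assert (pc.tp_norm, pc.fn_norm, pc.fp_norm) == (
            Fraction(1), Fraction(1), Fraction(1, 3),
        )

    @pytest.mark.parametrize("n", [2, 5, 17])
    def test_single_missing_gene_costs_one_unit(self, n):
        """Removing one gene from a perfect prediction shifts normalized
        TP and FN by exactly 1.0, whatever the RefOG size."""
        members = [gid(f"A|g{i}") for i in range(n)]
        uni = make_universe(members)
        ref = collection("r", "reference", R=frozenset(members))
        perfect = collection("p", "predicted", P=frozenset(members))
        damaged = collection("p", "predicted", P=frozenset(members[1:]))
        (full,) = scoring.count_pairs(ref, perfect, uni)
        (part,) = scoring.count_pairs(ref, damaged, uni)
        assert full.tp_norm - part.tp_norm == 1
        assert part.fn_norm - full.fn_norm == 1
        assert full.tp_raw - part.tp_raw == n - 1

    def test_cross_refog_fp_attributed_to_both_sides(self):
        """A co-predicted pair spanning two RefOGs is an FP in each one's
        tally (each side's view of the same error)."""
        a = [gid("A|a1"), gid("A|a2")]
        b = [gid("A|b1"), gid("A|b2")]
        uni = make_universe(a + b)
        ref = collection("r", "reference", RA=frozenset(a), RB=frozenset(b))
        pred = collection(
            "p", "predicted",
            P1=frozenset([a[0], b[0]]), P2=frozenset([a[1], b[1]]),
        )
        counts = {c.refog_label: c for c in scoring.count_pairs(ref, pred, uni)}
        assert counts["RA"].fp_raw == 2
        assert counts["RB"].fp_raw == 2

    def test_refog_below_two_members_unscoreable(self, caplog):
        uni = make_universe([gid("A|a"), gid("A|b"), gid("A|c")])
        ref = collection("r", "reference", R1=gids("A|a", "A|b"), R2=gids("A|c"))
        pred = collection("p", "predicted", P=gids("A|a", "A|b", "A|c"))
        counts = scoring.count_pairs(ref, pred, uni)
        assert [c.refog_label for c in counts] == ["R1"]
        assert scoring.unscoreable_refogs(ref, uni) == ("R2",)

    def test_foreign_genes_dropped_before_counting(self, four_gene_refog):
        uni = make_universe([gid(f"A|a{i}") for i in range(1, 5)])
        pred = collection(
            "p", "predicted",
            P=gids("A|a1", "A|a2", "A|a3", "A|a4", "OUT|o1"),
        )
        (pc,) = scoring.count_pairs(four_gene_refog, pred, uni)
        assert (pc.tp_raw, pc.fp_raw) == (6, 0)

    def test_conservation_invariant(self, small_universe, four_gene_refog):
        pred = collection("p", "predicted", P1=gids("A|a1", "A|x"), P2=gids("A|a2"))
        (pc,) = scoring.count_pairs(four_gene_refog, pred, small_universe)
        assert pc.tp_raw + pc.fn_raw == comb(pc.n, 2)

    def test_pair_counts_rejects_broken_conservation(self):
        with pytest.raises(ValidationError):
            PairCounts("R", 4, tp_raw=3, fp_raw=0, fn_raw=1)


class TestAggregate:
    def test_all_perfect(self):
        counts = [PairCounts(f"R{i}", 4, 6, 0, 0) for i in range(3)]
        assert scoring.aggregate(counts) == (1.0, 1.0, 1.0)

    def test_hand_summed_example(self):
        """Two RefOGs with normalized (TP,FP,FN) = (1,0,1) and (2,1,0)
        aggregate to P = R = F = 3/4 (hand evaluation of the formulas:
        sums TP=3, FP=1, FN=1)."""
        a = PairCounts("A", 4, tp_raw=3, fp_raw=0, fn_raw=3)  # /3 -> (1, 0, 1)
        b = PairCounts("B", 4, tp_raw=6, fp_raw=3, fn_raw=0)  # /3 -> (2, 1, 0)
        assert (a.tp_norm, a.fp_norm, a.fn_norm) == (1, 0, 1)
        assert (b.tp_norm, b.fp_norm, b.fn_norm) == (2, 1, 0)
        got = scoring.aggregate([a, b])
        assert got == (0.75, 0.75, 0.75)

    def test_all_singleton_predictions_zero_recall(self):
        members = [gid(f"A|g{i}") for i in range(4)]
        uni = make_universe(members)
        ref = collection("r", "reference", R=frozenset(members))
        pred = collection(
            "p", "predicted", **{f"P{i}": frozenset([g]) for i, g in enumerate(members)}
        )
        counts = scoring.count_pairs(ref, pred, uni)
        agg = scoring.aggregate(counts)
        assert agg.recall == 0.0
        assert agg.f_score == 0.0
        assert agg.precision is None  # no predicted pair touches the RefOG

    def test_empty_counts_rejected(self):
        with pytest.raises(ValidationError):
            scoring.aggregate([])

    def test_sum_order_independent(self):
        counts = [
            PairCounts(f"R{i}", n, comb(n, 2) - i, i * 2, i)
            for i, n in enumerate([4, 7, 11, 30], start=1)
        ]
        fwd = scoring.aggregate(counts)
        rev = scoring.aggregate(list(reversed(counts)))
        assert fwd == rev

    def test_monotonicity(self):
        """Recovering one more correct pair never lowers recall; one more
        cross-RefOG pair never raises precision."""
        base = [PairCounts("R1", 4, 3, 1, 3)]
        more_tp = [PairCounts("R1", 4, 4, 1, 2)]
        more_fp = [PairCounts("R1", 4, 3, 2, 3)]
        assert scoring.aggregate(more_tp).recall >= scoring.aggregate(base).recall
        assert scoring.aggregate(more_fp).precision <= scoring.aggregate(base).precision

    def test_normalization_linear_in_refog_size(self):
        """Perfect RefOGs of sizes 4 and 40 contribute normalized TP of
        n/2 — linear, not quadratic, in n."""
        c4 = PairCounts("R4", 4, comb(4, 2), 0, 0)
        c40 = PairCounts("R40", 40, comb(40, 2), 0, 0)
        assert c4.tp_norm == 2
        assert c40.tp_norm == 20


class TestExactMatches:
    def test_identity(self, small_universe, four_gene_refog):
        pred = collection("p", "predicted", P=gids("A|a1", "A|a2", "A|a3", "A|a4"))
        count, flags = scoring.exact_matches(four_gene_refog, pred, small_universe)
        assert count == 1 and flags == {"R1": True}

    def test_moved_gene_breaks_both_groups(self):
        a = [gid(f"A|a{i}") for i in range(3)]
        b = [gid(f"A|b{i}") for i in range(3)]
        c = [gid(f"A|c{i}") for i in range(2)]
        uni = make_universe(a + b + c)
        ref = collection(
            "r", "reference",
            RA=frozenset(a), RB=frozenset(b), RC=frozenset(c),
        )
        pred = collection(
            "p", "predicted",
            PA=frozenset(a[:2] + [b[0]]), PB=frozenset(b[1:] + [a[2]]),
            PC=frozenset(c),
        )
        count, flags = scoring.exact_matches(ref, pred, uni)
        assert flags == {"RA": False, "RB": False, "RC": True}
        assert count == 1

    def test_foreign_rider_does_not_spoil_exactness(self, four_gene_refog):
        """A predicted group carrying an outgroup-species gene still counts
        as exact once restricted to the benchmark universe."""
        uni = make_universe([gid(f"A|a{i}") for i in range(1, 5)])
        pred = collection(
            "p", "predicted",
            P=gids("A|a1", "A|a2", "A|a3", "A|a4", "OUT|o1"),
        )
        count, _ = scoring.exact_matches(four_gene_refog, pred, uni)
        assert count == 1


class TestSplitDiagnostics:
    def test_perfect_prediction(self, small_universe, four_gene_refog):
        pred = collection("p", "predicted", P=gids("A|a1", "A|a2", "A|a3", "A|a4"))
        (d,) = scoring.split_diagnostics(four_gene_refog, pred, small_universe)
        assert (d.fragments, d.missing, d.extra, d.exact) == (1, 0, 0, True)

    def test_even_split(self):
        members = [gid(f"A|g{i}") for i in range(6)]
        uni = make_universe(members)
        ref = collection("r", "reference", R=frozenset(members))
        pred = collection(
            "p", "predicted", P1=frozenset(members[:3]), P2=frozenset(members[3:])
        )
        (d,) = scoring.split_diagnostics(ref, pred, uni)
        assert d.fragments == 2

    def test_unassigned_member_counts_missing(self, small_universe, four_gene_refog):
        pred = collection("p", "predicted", P=gids("A|a1", "A|a2", "A|a3"))
        (d,) = scoring.split_diagnostics(four_gene_refog, pred, small_universe)
        assert (d.fragments, d.missing) == (1, 1)

    def test_extra_counts_plurality_fragment_contaminants(
        self, small_universe, four_gene_refog
    ):
        pred = collection(
            "p", "predicted",
            P1=gids("A|a1", "A|a2", "A|a3", "A|x"), P2=gids("A|a4"),
        )
        (d,) = scoring.split_diagnostics(four_gene_refog, pred, small_universe)
        assert (d.fragments, d.extra) == (2, 1)


class TestExclusions:
    def test_exclusion_equals_physical_deletion(self):
        bundle = fixtures.random_bundle(11)
        excl = bundle.exclusions
        with_excl = scoring.benchmark(
            bundle.refogs, bundle.predicted, bundle.universe, excl
        )
        # physically delete the excluded genes from every input
        def purge(coll):
            groups = {
                lab: frozenset(m - excl)
                for lab, m in coll.groups.items()
                if m - excl
            }
            return collection(coll.name, coll.role, **groups)

        uni = make_universe(bundle.universe.all_genes() - excl)
        deleted = scoring.benchmark(
            purge(bundle.refogs), purge(bundle.predicted), uni
        )
        assert with_excl.per_refog == deleted.per_refog
        assert (with_excl.precision, with_excl.recall, with_excl.f_score) == (
            deleted.precision, deleted.recall, deleted.f_score,
        )
        assert with_excl.exact_count == deleted.exact_count


class TestAdjustedRand:
    def test_identical_partitions(self):
        members = [gid(f"A|g{i}") for i in range(6)]
        uni = make_universe(members)
        part = collection(
            "a", "predicted", G1=frozenset(members[:3]), G2=frozenset(members[3:])
        )
        assert scoring.adjusted_rand(part, part, uni) == 1.0

    def test_singletons_vs_one_block_not_positive(self):
        members = [gid(f"A|g{i}") for i in range(5)]
        uni = make_universe(members)
        singles = collection(
            "a", "predicted",
            **{f"S{i}": frozenset([g]) for i, g in enumerate(members)},
        )
        block = collection("b", "predicted", ALL=frozenset(members))
        assert scoring.adjusted_rand(singles, block, uni) <= 0.0

    def test_six_gene_longhand_value(self):
        """{ab|cd|ef} vs {abc|def}: contingency formula gives 8/33."""
        g = [gid(f"A|g{i}") for i in range(6)]
        uni = make_universe(g)
        pa = collection(
            "a", "predicted",
            G1=frozenset(g[0:2]), G2=frozenset(g[2:4]), G3=frozenset(g[4:6]),
        )
        pb = collection(
            "b", "predicted", H1=frozenset(g[0:3]), H2=frozenset(g[3:6])
        )
        assert scoring.adjusted_rand(pa, pb, uni) == pytest.approx(8 / 33, abs=1e-12)

    def test_symmetry_and_relabeling_invariance(self):
        g = [gid(f"A|g{i}") for i in range(8)]
        uni = make_universe(g)
        pa = collection(
            "a", "predicted", X=frozenset(g[:5]), Y=frozenset(g[5:7])
        )  # g7 completed as singleton
        pb = collection(
            "b", "predicted", Q=frozenset(g[1:4]), R=frozenset(g[4:])
        )
        ab = scoring.adjusted_rand(pa, pb, uni)
        ba = scoring.adjusted_rand(pb, pa, uni)
        assert ab == ba
        relabeled = collection(
            "a2", "predicted", ZZZ=frozenset(g[:5]), AAA=frozenset(g[5:7])
        )
        assert scoring.adjusted_rand(relabeled, pb, uni) == ab

    def test_matches_sklearn_on_random_partitions(self):
        import random

        rng = random.Random(202)
        for _ in range(25):
            n = rng.randint(3, 20)
            genes = [gid(f"A|g{i}") for i in range(n)]
            uni = make_universe(genes)
            la = [rng.randrange(4) for _ in range(n)]
            lb = [rng.randrange(4) for _ in range(n)]

            def coll(name, labels):
                groups = {}
                for g, lab in zip(genes, labels):
                    groups.setdefault(f"G{lab}", set()).add(g)
                return collection(name, "predicted", **groups)

            ours = scoring.adjusted_rand(coll("a", la), coll("b", lb), uni)
            theirs = adjusted_rand_score(la, lb)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_empty_universe_rejected(self):
        pa = collection("a", "predicted", G=gids("A|x"))
        with pytest.raises(ValidationError):
            scoring.adjusted_rand(pa, pa, make_universe([]))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_scoring_matches_oracle_on_random_scenarios(seed):
    """Property: the fast pair counter agrees exactly with literal
    all-pairs enumeration on randomized perturbed scenarios."""
    bundle = fixtures.random_bundle(seed)
    result = scoring.benchmark(
        bundle.refogs, bundle.predicted, bundle.universe, bundle.exclusions
    )
    got = {c.refog_label: (c.n, c.tp_raw, c.fp_raw, c.fn_raw) for c in result.per_refog}
    assert got == dict(bundle.expected.per_refog)
    assert result.precision == bundle.expected.precision
    assert result.recall == bundle.expected.recall
    assert result.f_score == bundle.expected.f_score
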