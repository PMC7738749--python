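"""Pair-based orthogroup benchmark statistics.

For each reference orthogroup (RefOG) every unordered gene pair within it
is classified: recovered pairs (both genes co-assigned to one predicted
orthogroup) are true positives, unrecovered pairs are false negatives, and
co-predicted pairs that straddle the RefOG boundary are false positives.
Raw counts are divided by (n - 1), where n is the RefOG size, so that a
single misplaced gene costs exactly one normalized unit regardless of RefOG
size: a missing gene breaks (n - 1) within-RefOG pairs, so (n - 1) — not
the pair count n(n - 1)/2 — is the normalization that makes RefOGs of
different sizes commensurable.  Normalized counts are summed over RefOGs
and precision, recall and F-score are computed from the sums.

FP attribution: a co-predicted pair {g, x} with g in RefOG r and x outside
r contributes one FP to r; if x belongs to a different RefOG s the pair
also contributes one FP to s (each side's view of the same error).  Pairs
touching no RefOG contribute nothing.

Normalized tallies are carried as exact rationals (``fractions.Fraction``)
so that aggregation is independent of summation order and stratified
subtotals recompose to the global scores bit for bit.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import FrozenSet, Iterable, Mapping, NamedTuple, Optional, Sequence

from .model import (
    ExclusionSet,
    GeneID,
    GeneUniverse,
    IntegrityError,
    OrthogroupCollection,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Sentinel policies for overlapping predicted groups.
OVERLAP_STRICT = "strict"
OVERLAP_FIRST_WINS = "first-wins"


@dataclass(frozen=True)
class PairCounts:
    """Raw and (n-1)-normalized TP/FP/FN pair tallies for one RefOG.

    ``n`` is the RefOG size after universe restriction and exclusions; the
    invariant ``tp_raw + fn_raw == n(n-1)/2`` always holds.
    """

    refog_label: str
    n: int
    tp_raw: int
    fp_raw: int
    fn_raw: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(
                f"RefOG {self.refog_label!r}: n={self.n} cannot form pairs"
            )
        if min(self.tp_raw, self.fp_raw, self.fn_raw) < 0:
            raise ValidationError(f"RefOG {self.refog_label!r}: negative pair count")
        if self.tp_raw + self.fn_raw != comb(self.n, 2):
            raise ValidationError(
                f"RefOG {self.refog_label!r}: tp_raw + fn_raw = "
                f"{self.tp_raw + self.fn_raw} != C({self.n},2)"
            )

    @property
    def tp_norm(self) -> Fraction:
        return Fraction(self.tp_raw, self.n - 1)

    @property
    def fp_norm(self) -> Fraction:
        return Fraction(self.fp_raw, self.n - 1)

    @property
    def fn_norm(self) -> Fraction:
        return Fraction(self.fn_raw, self.n - 1)


class RefogDiagnostics(NamedTuple):
    """Fragmentation diagnostics for one RefOG."""

    refog_label: str
    fragments: int  # distinct predicted groups holding >= 1 member
    missing: int    # members assigned to no predicted group
    extra: int      # non-members co-grouped with the plurality fragment
    exact: bool     # some predicted group equals the member set exactly


class AggregateScores(NamedTuple):
    """Precision/recall/F computed from summed normalized counts.

    ``precision`` is ``None`` (undefined) when no predicted pair touches any
    RefOG; the F-score is then 0 rather than rewarding empty predictions.
    """

    precision: Optional[float]
    recall: float
    f_score: float


@dataclass(frozen=True)
class BenchmarkResult:
    """Complete output of a benchmark run."""

    precision: Optional[float]
    recall: float
    f_score: float
    exact_count: int
    per_refog: tuple[PairCounts, ...]
    diagnostics: tuple[RefogDiagnostics, ...]
    unscoreable: tuple[str, ...] = ()
    ari: Optional[float] = None
    dropped_genes: int = 0


def build_gene_index(
    collection: OrthogroupCollection, policy: str = OVERLAP_STRICT
) -> dict[GeneID, str]:
    """Map each gene to its group label.

    Overlapping predicted groups are an error under the default ``strict``
    policy (every benchmarked inference method emits disjoint orthogroups,
    so overlap usually signals a parsing fault); under ``first-wins`` the
    lexicographically first group label keeps the gene and a warning is
    logged.
    """
    index: dict[GeneID, str] = {}
    clashes = 0
    for label in sorted(collection.groups):
        for g in collection.groups[label]:
            if g in index:
                if policy == OVERLAP_STRICT:
                    raise IntegrityError(
                        f"gene {g} in groups {index[g]!r} and {label!r} "
                        f"of {collection.name!r} (overlap policy 'strict')"
                    )
                clashes += 1
                continue
            index[g] = label
    if clashes:
        logger.warning(
            "%s: %d overlapping gene assignments resolved first-wins",
            collection.name, clashes,
        )
    return index


def _restrict(
    refogs: OrthogroupCollection,
    predicted: OrthogroupCollection,
    universe: GeneUniverse,
    exclusions: ExclusionSet,
    overlap_policy: str,
) -> tuple[dict[str, FrozenSet[GeneID]], dict[str, FrozenSet[GeneID]], int]:
    """Apply the shared scoring restrictions to both collections.

    Returns (RefOG member sets, predicted group sets, count of predicted
    genes dropped for lying outside the universe).  Excluded genes are
    removed from both sides; empty groups vanish.
    """
    keep = universe.all_genes() - exclusions
    ref_members = {}
    for label, members in refogs.groups.items():
        restricted = frozenset(members & keep)
        if restricted:
            ref_members[label] = restricted

    index = build_gene_index(predicted, policy=overlap_policy)
    dropped = sum(1 for g in index if g not in universe)
    pred_groups: dict[str, set[GeneID]] = {}
    for g, label in index.items():
        if g in keep:
            pred_groups.setdefault(label, set()).add(g)
    if dropped:
        logger.info(
            "%s: %d predicted genes outside the gene universe dropped",
            predicted.name, dropped,
        )
    return ref_members, {k: frozenset(v) for k, v in pred_groups.items()}, dropped


def count_pairs(
    refogs: OrthogroupCollection,
    predicted: OrthogroupCollection,
    universe: GeneUniverse,
    exclusions: ExclusionSet = frozenset(),
    *,
    overlap_policy: str = OVERLAP_STRICT,
) -> list[PairCounts]:
    """Per-RefOG raw and normalized TP/FP/FN pair counts.

    RefOGs reduced below two members by universe restriction or exclusions
    cannot form pairs and are skipped with a warning (the (n-1)
    normalization is undefined at n = 1).
    """
    ref_members, pred_groups, _ = _restrict(
        refogs, predicted, universe, exclusions, overlap_policy
    )
    counts: list[PairCounts] = []
    for label in sorted(refogs.groups):
        members = ref_members.get(label, frozenset())
        n = len(members)
        if n < 2:
            logger.warning(
                "RefOG %s has %d members after restriction; unscoreable", label, n
            )
            continue
        tp = 0
        fp = 0
        for pg in pred_groups.values():
            c = len(pg & members)
            if c == 0:
                continue
            tp += comb(c, 2)
            fp += c * (len(pg) - c)
        fn = comb(n, 2) - tp
        counts.append(PairCounts(label, n, tp, fp, fn))
    return counts


def unscoreable_refogs(
    refogs: OrthogroupCollection,
    universe: GeneUniverse,
    exclusions: ExclusionSet = frozenset(),
) -> tuple[str, ...]:
    """Labels of RefOGs with fewer than two members after restriction."""
    keep = universe.all_genes() - exclusions
    return tuple(
        label
        for label in sorted(refogs.groups)
        if len(refogs.groups[label] & keep) < 2
    )


def aggregate(counts: Sequence[PairCounts]) -> AggregateScores:
    """Sum normalized counts over RefOGs and derive precision/recall/F.

    Sums are exact rationals accumulated in sorted-label order, so the
    result is independent of input order and recomposes exactly from any
    partition of the RefOGs.
    """
    if not counts:
        raise ValidationError("aggregate requires at least one scoreable RefOG")
    ordered = sorted(counts, key=lambda c: c.refog_label)
    tp = sum((c.tp_norm for c in ordered), Fraction(0))
    fp = sum((c.fp_norm for c in ordered), Fraction(0))
    fn = sum((c.fn_norm for c in ordered), Fraction(0))
    recall = tp / (tp + fn)  # tp + fn >= 1 pair per RefOG, never zero
    if tp + fp == 0:
        logger.warning("no predicted pair touches any RefOG; precision undefined")
        return AggregateScores(None, float(recall), 0.0)
    precision = tp / (tp + fp)
    if precision + recall == 0:
        f = Fraction(0)
    else:
        f = 2 * precision * recall / (precision + recall)
    return AggregateScores(float(precision), float(recall), float(f))


def exact_matches(
    refogs: OrthogroupCollection,
    predicted: OrthogroupCollection,
    universe: GeneUniverse,
    exclusions: ExclusionSet = frozenset(),
    *,
    overlap_policy: str = OVERLAP_STRICT,
) -> tuple[int, dict[str, bool]]:
    """Count RefOGs predicted exactly: no extra or missing genes.

    Both sides are restricted to the universe and purged of excluded genes
    first, so e.g. an outgroup-species gene riding along in a predicted
    group does not spoil an otherwise exact match.
    """
    ref_members, pred_groups, _ = _restrict(
        refogs, predicted, universe, exclusions, overlap_policy
    )
    pred_sets = set(pred_groups.values())
    flags = {}
    for label in sorted(refogs.groups):
        members = ref_members.get(label, frozenset())
        flags[label] = bool(members) and members in pred_sets
    return sum(flags.values()), flags


def split_diagnostics(
    refogs: OrthogroupCollection,
    predicted: OrthogroupCollection,
    universe: GeneUniverse,
    exclusions: ExclusionSet = frozenset(),
    *,
    overlap_policy: str = OVERLAP_STRICT,
) -> list[RefogDiagnostics]:
    """Per-RefOG fragmentation summary.

    ``fragments`` counts distinct predicted groups holding at least one
    member, ``missing`` the members assigned nowhere, and ``extra`` the
    non-members sharing the plurality fragment (the predicted group with
    the most members; ties broken by lexicographic group label).
    """
    ref_members, pred_groups, _ = _restrict(
        refogs, predicted, universe, exclusions, overlap_policy
    )
    pred_sets = set(pred_groups.values())
    out: list[RefogDiagnostics] = []
    for label in sorted(refogs.groups):
        members = ref_members.get(label, frozenset())
        holding = {
            plabel: len(pg & members)
            for plabel, pg in pred_groups.items()
            if pg & members
        }
        fragments = len(holding)
        assigned = sum(holding.values())
        missing = len(members) - assigned
        if holding:
            plurality = min(holding, key=lambda p: (-holding[p], p))
            extra = len(pred_groups[plurality]) - holding[plurality]
        else:
            extra = 0
        exact = bool(members) and members in pred_sets
        out.append(RefogDiagnostics(label, fragments, missing, extra, exact))
    return out


def adjusted_rand(
    partition_a: OrthogroupCollection,
    partition_b: OrthogroupCollection,
    universe: GeneUniverse,
    *,
    overlap_policy: str = OVERLAP_STRICT,
) -> float:
    """Adjusted Rand index between two orthogroup partitions of the universe.

    Genes of the universe absent from a collection are completed as
    singletons, so both partitions cover exactly the same gene set.  The
    index is chance-corrected: 1 for identical partitions, ~0 for random
    agreement, negative for worse-than-chance agreement.
    """
    genes = sorted(universe.all_genes())
    if not genes:
        raise ValidationError("adjusted_rand requires a non-empty universe")

    def labels_for(coll: OrthogroupCollection) -> list[int]:
        index = build_gene_index(coll, policy=overlap_policy)
        ids: dict[str, int] = {}
        out: list[int] = []
        nxt = 0
        for g in genes:
            lab = index.get(g)
            if lab is None:
                out.append(nxt)  # fresh singleton label
                nxt += 1
                continue
            key = f"grp:{lab}"
            if key not in ids:
                ids[key] = nxt
                nxt += 1
            out.append(ids[key])
        return out

    la, lb = labels_for(partition_a), labels_for(partition_b)
    contingency = Counter(zip(la, lb))
    a_sizes = Counter(la)
    b_sizes = Counter(lb)
    n = len(genes)
    sum_nij = sum(comb(v, 2) for v in contingency.values())
    sum_a = sum(comb(v, 2) for v in a_sizes.values())
    sum_b = sum(comb(v, 2) for v in b_sizes.values())
    total = comb(n, 2)
    expected = Fraction(sum_a * sum_b, total) if total else Fraction(0)
    max_index = Fraction(sum_a + sum_b, 2)
    if max_index == expected:
        return 1.0  # both partitions degenerate (all singletons or identical)
    return float((sum_nij - expected) / (max_index - expected))


def benchmark(
    refogs: OrthogroupCollection,
    predicted: OrthogroupCollection,
    universe: GeneUniverse,
    exclusions: ExclusionSet = frozenset(),
    *,
    compute_ari: bool = False,
    overlap_policy: str = OVERLAP_STRICT,
) -> BenchmarkResult:
    """Run the full benchmark: pair counts, aggregate P/R/F, exact count,
    fragmentation diagnostics and (optionally) the adjusted Rand index."""
    counts = count_pairs(
        refogs, predicted, universe, exclusions, overlap_policy=overlap_policy
    )
    scores = aggregate(counts)
    exact_count, _ = exact_matches(
        refogs, predicted, universe, exclusions, overlap_policy=overlap_policy
    )
    diags = split_diagnostics(
        refogs, predicted, universe, exclusions, overlap_policy=overlap_policy
    )
    _, _, dropped = _restrict(refogs, predicted, universe, exclusions, overlap_policy)
    ari = (
        adjusted_rand(refogs, predicted, universe, overlap_policy=overlap_policy)
        if compute_ari
        else None
    )
    return BenchmarkResult(
        precision=scores.precision,
        recall=scores.recall,
        f_score=scores.f_score,
        exact_count=exact_count,
        per_refog=tuple(counts),
        diagnostics=tuple(diags),
        unscoreable=unscoreable_refogs(refogs, universe, exclusions),
        ari=ari,
        dropped_genes=dropped,
    )
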