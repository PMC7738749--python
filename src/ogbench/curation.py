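"""Curation-support computations: HMM gathering thresholds, alignment
column trimming, and longest-isoform proteome reduction.

These are the reproducible numeric steps of benchmark curation.  Gathering
deliberately over-collects: the e-value cutoff is chosen so the candidate
set is a fixed multiple (3x by default) of the hits implied by the worst
scoring seed member, because false-positive family members are best
discarded later on gene-tree evidence, not on e-values.
"""

from __future__ import annotations

import logging
import re
import statistics
from dataclasses import dataclass
from math import floor
from typing import Callable, Iterable, Optional, Sequence

from .io import HmmHit, HmmHitTable
from .model import GeneID, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GatheringResult:
    """Outcome of gathering-threshold selection for one RefOG."""

    seed_worst_evalue: float      # e-value of the worst-scoring seed member
    seed_implied_count: int       # hits at or better than that e-value
    target_count: int             # floor(multiplier * seed_implied_count)
    threshold_evalue: float       # e-value of the last gathered hit
    gathered: tuple[GeneID, ...]  # in ranking order


def select_gathering_threshold(
    hits: HmmHitTable,
    seed_members: Iterable[GeneID],
    multiplier: float = 3.0,
) -> GatheringResult:
    """Choose the gathered candidate set from an hmmsearch ranking.

    Hits are ranked by ascending e-value (ties: descending bit score, then
    lexicographic gene ID; a gene hit several times keeps its best row).
    The worst e-value among the seed members implies a count k of hits at
    or better than it; the gathered set is the first ``floor(multiplier*k)``
    hits of the ranking — cut by rank, not by e-value, when ties straddle
    the cut.  With ``multiplier=1`` this returns exactly the seed-implied
    prefix.
    """
    seed = frozenset(seed_members)
    if not seed:
        raise ValidationError("select_gathering_threshold: empty seed set")
    if not len(hits):
        raise ValidationError("select_gathering_threshold: empty hit table")
    if multiplier <= 0:
        raise ValidationError(f"multiplier must be positive, got {multiplier}")

    ranked: list[HmmHit] = []
    seen: set[GeneID] = set()
    for row in hits.sorted().rows:
        if row.gene in seen:
            continue  # keep each gene's best-ranked row only
        seen.add(row.gene)
        ranked.append(row)

    missing = sorted(str(g) for g in seed if g not in seen)
    if missing:
        raise ValidationError(
            f"seed members absent from the hit table: {', '.join(missing)}"
        )

    seed_worst = max(row.evalue for row in ranked if row.gene in seed)
    seed_implied = sum(1 for row in ranked if row.evalue <= seed_worst)
    target = floor(multiplier * seed_implied)
    if target > len(ranked):
        logger.warning(
            "target of %d hits exceeds the %d available; gathering all",
            target, len(ranked),
        )
    take = min(target, len(ranked))
    gathered = tuple(row.gene for row in ranked[:take])
    threshold = ranked[take - 1].evalue
    return GatheringResult(
        seed_worst_evalue=seed_worst,
        seed_implied_count=seed_implied,
        target_count=target,
        threshold_evalue=threshold,
        gathered=gathered,
    )


@dataclass(frozen=True)
class TrimmedAlignment:
    """Column bookkeeping from gap-fraction trimming.

    ``kept`` and ``removed`` are disjoint 0-based column indices whose
    union is the full column range, both in original order.
    """

    kept: tuple[int, ...]
    removed: tuple[int, ...]
    removed_gap_fractions: tuple[float, ...]

    @property
    def median_removed_gap_fraction(self) -> Optional[float]:
        if not self.removed_gap_fractions:
            return None
        return statistics.median(self.removed_gap_fractions)

    def apply(self, sequences: Sequence[str]) -> list[str]:
        """Project aligned sequences onto the kept columns."""
        return ["".join(s[i] for i in self.kept) for s in sequences]


def trim_columns(
    alignment: Sequence[str],
    max_gap_fraction: float = 0.5,
    *,
    gap_char: str = "-",
) -> TrimmedAlignment:
    """Remove MSA columns whose gap fraction strictly exceeds the threshold.

    A column at exactly the threshold is kept (mirroring TrimAl's ``-gt``
    semantics, where ``-gt 0.5`` removes columns with *more than* 50%
    gaps).  Short alignments are typically trimmed with a laxer 0.75
    threshold, or not at all; that choice is the caller's.  Trimming is
    idempotent: re-trimming a trimmed alignment removes nothing.
    """
    seqs = [str(s) for s in alignment]
    if not seqs:
        raise ValidationError("trim_columns: empty alignment")
    ncol = len(seqs[0])
    if any(len(s) != ncol for s in seqs):
        raise ValidationError("trim_columns: ragged alignment")
    nrow = len(seqs)
    kept: list[int] = []
    removed: list[int] = []
    fractions: list[float] = []
    for col in range(ncol):
        gaps = sum(1 for s in seqs if s[col] == gap_char)
        frac = gaps / nrow
        if frac > max_gap_fraction:
            removed.append(col)
            fractions.append(frac)
        else:
            kept.append(col)
    return TrimmedAlignment(tuple(kept), tuple(removed), tuple(fractions))


def longest_isoform_reduce(
    records: Sequence,
    locus_rule: str | Callable[[str], Optional[str]],
) -> list:
    """Keep one record per gene locus: the longest protein isoform.

    ``locus_rule`` is a regex whose first group extracts the locus key from
    a record ID, or a callable doing the same.  Equal-length ties keep the
    lexicographically smallest record ID; output is sorted by locus key.
    A record the rule cannot map to a locus is an error.
    """
    if isinstance(locus_rule, str):
        pattern = re.compile(locus_rule)

        def rule(rid: str) -> Optional[str]:
            m = pattern.search(rid)
            if not m:
                return None
            return m.group(1) if m.groups() else m.group(0)

    else:
        rule = locus_rule

    best: dict[str, tuple] = {}  # locus -> (record_id, seq_len, record)
    for record in records:
        rid, seq = _id_and_seq(record)
        locus = rule(rid)
        if locus is None:
            raise ValidationError(
                f"locus rule matched nothing for record {rid!r}"
            )
        cur = best.get(locus)
        better = (
            cur is None
            or len(seq) > cur[1]
            or (len(seq) == cur[1] and rid < cur[0])
        )
        if better:
            best[locus] = (rid, len(seq), record)
    return [best[locus][2] for locus in sorted(best)]


def _id_and_seq(record) -> tuple[str, str]:
    if hasattr(record, "id") and hasattr(record, "seq"):
        return str(record.id), str(record.seq)
    rid, seq = record
    return str(rid), str(seq)
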