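"""Classify RefOGs by technical-challenge axes and score each tercile.

Four axes are profiled per RefOG:

* ``size`` — gene count N,
* ``rate`` — evolutionary rate proxied by mean pairwise sequence identity I
  (in percent; *low* rate means *high* identity),
* ``quality`` — alignment quality Q, a norMD score consumed from a
  precomputed table (norMD itself is an external tool, not reimplemented),
* ``domains`` — number D of family-specific conserved domains, i.e. Pfam
  families present in at least 75% of the RefOG's genes.

Each axis splits the RefOGs into low/medium/high terciles, either at the
fixed published cutoffs (default) or data-driven by ranking the profiled
values into thirds, and the pair-based precision/recall/F machinery is
re-applied to each tercile's subset of RefOGs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .io import DomainHitTable
from .model import GeneID, ValidationError
from .scoring import AggregateScores, PairCounts, aggregate

logger = logging.getLogger(__name__)

AXES = ("size", "rate", "quality", "domains")
TERCILES = ("low", "medium", "high")

GAP_CHARS = frozenset("-.")

#: Default confidence filter for per-domain calls (independent e-value).
DEFAULT_DOMAIN_EVALUE = 1e-3

#: Fraction of a RefOG's genes a domain family must occur in to count as
#: family-specific conserved.
DEFAULT_PREVALENCE = 0.75


@dataclass(frozen=True)
class ChallengeProfile:
    """Measured challenge values for one RefOG, plus tercile labels."""

    refog_label: str
    size: int
    identity: Optional[float] = None  # mean pairwise identity, percent
    quality: Optional[float] = None   # norMD score, unitless
    domains: Optional[int] = None     # family-specific conserved domain count
    terciles: Mapping[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValidationError(
                f"RefOG {self.refog_label!r}: size {self.size} < 2"
            )
        if self.identity is not None and not (0.0 <= self.identity <= 100.0):
            raise ValidationError(
                f"RefOG {self.refog_label!r}: identity {self.identity} outside [0, 100]"
            )
        if self.domains is not None and self.domains < 0:
            raise ValidationError(
                f"RefOG {self.refog_label!r}: negative domain count"
            )


def mean_pairwise_identity(alignment: Sequence, *, gap_chars=GAP_CHARS) -> float:
    """Mean pairwise percent identity of an MSA (the "FamID" rate proxy).

    For each unordered sequence pair, identity = (columns with identical
    residues) / (columns where at least one of the two has a residue);
    columns gapped in both sequences are ignored.  The result is the mean
    over all pairs, in percent.

    ``alignment`` is a sequence of aligned strings, of ``(id, seq)`` pairs,
    or anything with ``str``-able rows of equal length.
    """
    seqs = _as_strings(alignment)
    if len(seqs) < 2:
        raise ValidationError("mean_pairwise_identity needs at least 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValidationError("ragged alignment: sequences differ in length")
    total = 0.0
    npairs = 0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            a, b = seqs[i], seqs[j]
            matches = 0
            denom = 0
            for ca, cb in zip(a, b):
                ga, gb = ca in gap_chars, cb in gap_chars
                if ga and gb:
                    continue
                denom += 1
                if not ga and not gb and ca == cb:
                    matches += 1
            if denom == 0:
                logger.warning("sequence pair with no residue columns; identity 0")
                ident = 0.0
            else:
                ident = 100.0 * matches / denom
            total += ident
            npairs += 1
    return total / npairs


def _as_strings(alignment: Sequence) -> list[str]:
    seqs: list[str] = []
    for row in alignment:
        if isinstance(row, str):
            seqs.append(row)
        elif isinstance(row, tuple) and len(row) == 2:
            seqs.append(str(row[1]))
        elif hasattr(row, "seq"):
            seqs.append(str(row.seq))
        else:
            seqs.append(str(row))
    return seqs


def conserved_domain_count(
    hits: DomainHitTable,
    refog_members: Iterable[GeneID],
    prevalence_threshold: float = DEFAULT_PREVALENCE,
) -> int:
    """Number of domain families present in >= ``prevalence_threshold`` of
    the RefOG's genes.

    Prevalence is a per-gene presence/absence predicate: several instances
    of one family in one gene count once.  ``hits`` should already be
    filtered to confident calls (see :meth:`DomainHitTable.filtered`).
    """
    members = frozenset(refog_members)
    if not members:
        raise ValidationError("conserved_domain_count: empty RefOG member set")
    carriers: dict[str, set[GeneID]] = {}
    for row in hits.rows:
        if row.gene in members:
            carriers.setdefault(row.family, set()).add(row.gene)
    n = len(members)
    return sum(1 for genes in carriers.values() if len(genes) / n >= prevalence_threshold)


def mean_domain_count(
    hits: DomainHitTable, refog_members: Iterable[GeneID]
) -> float:
    """Mean number of domain instances per gene over the RefOG's members.

    Genes with no confident domain call count as zero.
    """
    members = frozenset(refog_members)
    if not members:
        raise ValidationError("mean_domain_count: empty RefOG member set")
    instances = {g: 0 for g in members}
    for row in hits.rows:
        if row.gene in members:
            instances[row.gene] += 1
    return sum(instances.values()) / len(members)


# ---------------------------------------------------------------------------
# Tercile schemes


@dataclass(frozen=True)
class TercileScheme:
    """How to map a profiled value to a low/medium/high tercile.

    ``fixed`` uses the published cutoffs of the 70-RefOG benchmark:

    ============ ===================== =========================== ==========
    axis         low                   medium                      high
    ============ ===================== =========================== ==========
    size N       N < 15                15 <= N < 31                N >= 31
    rate (via I) I > 73.8              62.4 < I <= 73.8            I <= 62.4
    quality Q    Q < 0.88              0.88 <= Q <= 1.15           Q > 1.15
    domains D    D <= 1                2 <= D <= 3                 D > 3
    ============ ===================== =========================== ==========

    (The rate axis labels the *rate*, so high identity means a *low* rate.)

    ``data`` ranks the profiled values and cuts them into thirds of as
    equal size as possible, never splitting tied values across a boundary.
    """

    kind: str = "fixed"

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "data"):
            raise ValidationError(f"unknown tercile scheme {self.kind!r}")


def _fixed_label(axis: str, value: float) -> str:
    if axis == "size":
        if value < 15:
            return "low"
        return "medium" if value < 31 else "high"
    if axis == "rate":
        if value > 73.8:
            return "low"
        return "medium" if value > 62.4 else "high"
    if axis == "quality":
        if value < 0.88:
            return "low"
        return "medium" if value <= 1.15 else "high"
    if axis == "domains":
        if value <= 1:
            return "low"
        return "medium" if value <= 3 else "high"
    raise ValidationError(f"unknown axis {axis!r}")


#: Per-axis sort direction for the data-driven scheme: the key orders
#: RefOGs from the "low" tercile to the "high" one.  Identity is negated
#: because low rate corresponds to high identity.
_DATA_KEYS: dict[str, Callable[[float], float]] = {
    "size": lambda v: v,
    "rate": lambda v: -v,
    "quality": lambda v: v,
    "domains": lambda v: v,
}


def _data_labels(axis: str, values: Mapping[str, float]) -> dict[str, str]:
    key = _DATA_KEYS[axis]
    ordered = sorted(values, key=lambda lab: (key(values[lab]), lab))
    n = len(ordered)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    cuts = [sizes[0], sizes[0] + sizes[1]]
    # never split a run of tied values across a tercile boundary: extend
    # the lower tercile to absorb the ties
    for ci in range(2):
        c = cuts[ci]
        while 0 < c < n and key(values[ordered[c]]) == key(values[ordered[c - 1]]):
            c += 1
        cuts[ci] = c
    cuts[1] = max(cuts[1], cuts[0])
    labels: dict[str, str] = {}
    for i, lab in enumerate(ordered):
        if i < cuts[0]:
            labels[lab] = "low"
        elif i < cuts[1]:
            labels[lab] = "medium"
        else:
            labels[lab] = "high"
    return labels


_AXIS_VALUE = {
    "size": lambda p: p.size,
    "rate": lambda p: p.identity,
    "quality": lambda p: p.quality,
    "domains": lambda p: p.domains,
}


def assign_terciles(
    profiles: Sequence[ChallengeProfile],
    scheme: TercileScheme = TercileScheme("fixed"),
) -> list[ChallengeProfile]:
    """Attach a tercile label per available axis to every profile.

    An axis with a missing value on any profile is skipped entirely (with a
    warning), so the terciles always partition the full RefOG set on the
    axes they cover.
    """
    if not profiles:
        return []
    labels: dict[str, dict[str, str]] = {}
    for axis in AXES:
        values = {p.refog_label: _AXIS_VALUE[axis](p) for p in profiles}
        if any(v is None for v in values.values()):
            missing = sorted(l for l, v in values.items() if v is None)
            logger.warning(
                "axis %r skipped: no value for %d RefOGs (e.g. %s)",
                axis, len(missing), missing[0],
            )
            continue
        if scheme.kind == "fixed":
            labels[axis] = {l: _fixed_label(axis, v) for l, v in values.items()}
        else:
            labels[axis] = _data_labels(axis, values)
    return [
        dataclasses.replace(
            p, terciles={axis: labels[axis][p.refog_label] for axis in labels}
        )
        for p in profiles
    ]


def stratified_scores(
    counts: Sequence[PairCounts],
    profiles: Sequence[ChallengeProfile],
) -> dict[str, dict[str, Optional[AggregateScores]]]:
    """Aggregate P/R/F per axis and tercile.

    Every scored RefOG must carry a label on each axis present in the
    profiles.  Empty terciles are reported as ``None`` rather than raising.
    """
    by_label = {p.refog_label: p for p in profiles}
    missing = [c.refog_label for c in counts if c.refog_label not in by_label]
    if missing:
        raise ValidationError(f"no challenge profile for RefOGs: {missing[:5]}")
    axes = sorted({axis for p in profiles for axis in p.terciles})
    out: dict[str, dict[str, Optional[AggregateScores]]] = {}
    for axis in axes:
        out[axis] = {}
        for terc in TERCILES:
            subset = [
                c for c in counts if by_label[c.refog_label].terciles.get(axis) == terc
            ]
            out[axis][terc] = aggregate(subset) if subset else None
    return out


def build_profiles(
    refogs,
    alignments: Mapping[str, Sequence],
    domain_hits: Optional[DomainHitTable] = None,
    quality: Optional[Mapping[str, float]] = None,
    *,
    domain_evalue: float = DEFAULT_DOMAIN_EVALUE,
    prevalence_threshold: float = DEFAULT_PREVALENCE,
) -> list[ChallengeProfile]:
    """Measure every available axis for each RefOG of a collection.

    ``alignments`` maps RefOG label to its MSA; axes without input data
    (identity without an alignment, quality without a score) are left
    ``None`` and later skipped by :func:`assign_terciles`.
    """
    filtered = domain_hits.filtered(domain_evalue) if domain_hits is not None else None
    profiles = []
    for label in sorted(refogs.groups):
        members = refogs.groups[label]
        identity = None
        if label in alignments:
            identity = mean_pairwise_identity(alignments[label])
        domains = None
        if filtered is not None:
            domains = conserved_domain_count(
                filtered, members, prevalence_threshold=prevalence_threshold
            )
        q = quality.get(label) if quality else None
        profiles.append(
            ChallengeProfile(
                refog_label=label,
                size=len(members),
                identity=identity,
                quality=q,
                domains=domains,
            )
        )
    return profiles
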