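"""Core domain objects: gene identifiers, gene universes, orthogroup collections.

Genes are identified by a (species tag, accession) pair.  The canonical
string form is ``species|accession``; parsers also accept an underscore
separator or an explicit token-to-species mapping, because the output
formats of orthogroup inference tools disagree on how (or whether) species
are encoded in gene identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Mapping


class OgbenchError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(OgbenchError):
    """A file could not be parsed (malformed line, bad field, ...)."""


class IntegrityError(OgbenchError):
    """Parsed data violates a structural invariant (duplicates, overlap)."""


class ValidationError(OgbenchError):
    """An operation was called with arguments that violate its preconditions."""


CANONICAL_SEP = "|"


@dataclass(frozen=True, order=True)
class GeneID:
    """A namespaced gene identifier: short species tag + accession."""

    species: str
    accession: str

    def __post_init__(self) -> None:
        if not self.species:
            raise ValidationError("GeneID species tag must be non-empty")
        if not self.accession:
            raise ValidationError("GeneID accession must be non-empty")

    def __str__(self) -> str:
        return f"{self.species}{CANONICAL_SEP}{self.accession}"

    @classmethod
    def parse(cls, token: str, sep: str = CANONICAL_SEP) -> "GeneID":
        """Parse ``species<sep>accession``, splitting on the first separator."""
        head, s, tail = token.partition(sep)
        if not s or not head or not tail:
            raise ParseError(
                f"cannot split gene token {token!r} into species and accession "
                f"with separator {sep!r}"
            )
        return cls(head, tail)


@dataclass(frozen=True)
class GeneUniverse:
    """The benchmark-eligible genes, grouped per species.

    Genes of species absent from the universe are *foreign* (e.g. outgroup
    proteomes used by one method variant); they are retained by parsers and
    filtered out at scoring time.
    """

    per_species: Mapping[str, FrozenSet[GeneID]]
    _all: FrozenSet[GeneID] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        merged: set[GeneID] = set()
        for tag, genes in self.per_species.items():
            for g in genes:
                if g.species != tag:
                    raise IntegrityError(
                        f"gene {g} filed under species {tag!r} in the universe"
                    )
            merged.update(genes)
        object.__setattr__(self, "_all", frozenset(merged))

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.per_species))

    def all_genes(self) -> FrozenSet[GeneID]:
        return self._all

    def __contains__(self, gene: GeneID) -> bool:
        return gene in self._all

    def __len__(self) -> int:
        return len(self._all)

    def is_foreign(self, gene: GeneID) -> bool:
        """True when the gene's species is not a benchmark species."""
        return gene.species not in self.per_species


ROLE_REFERENCE = "reference"
ROLE_PREDICTED = "predicted"


@dataclass(frozen=True)
class OrthogroupCollection:
    """A named family of gene sets, either curated reference orthogroups
    (RefOGs) or the output of an inference method.

    Reference collections must be pairwise disjoint: a gene belongs to at
    most one RefOG.  Predicted collections are allowed to overlap at parse
    time; overlap policy is applied when a gene index is built.
    """

    name: str
    role: str
    groups: Mapping[str, FrozenSet[GeneID]]

    def __post_init__(self) -> None:
        if self.role not in (ROLE_REFERENCE, ROLE_PREDICTED):
            raise ValidationError(f"unknown collection role {self.role!r}")
        for label, members in self.groups.items():
            if not members:
                raise IntegrityError(f"group {label!r} in {self.name!r} is empty")
        if self.role == ROLE_REFERENCE:
            seen: dict[GeneID, str] = {}
            for label in sorted(self.groups):
                for g in self.groups[label]:
                    if g in seen:
                        raise IntegrityError(
                            f"gene {g} appears in reference groups "
                            f"{seen[g]!r} and {label!r}"
                        )
                    seen[g] = label

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.groups))

    def all_genes(self) -> FrozenSet[GeneID]:
        out: set[GeneID] = set()
        for members in self.groups.values():
            out.update(members)
        return frozenset(out)

    def n_groups(self) -> int:
        return len(self.groups)

    def total_genes(self) -> int:
        """Sum of group sizes (counts a gene once per group it appears in)."""
        return sum(len(m) for m in self.groups.values())


ExclusionSet = FrozenSet[GeneID]


def make_universe(genes: Iterable[GeneID]) -> GeneUniverse:
    """Build a universe from a flat iterable of genes."""
    per: dict[str, set[GeneID]] = {}
    for g in genes:
        per.setdefault(g.species, set()).add(g)
    return GeneUniverse({tag: frozenset(v) for tag, v in per.items()})
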