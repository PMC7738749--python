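"""Synthetic benchmark fixtures with known error structure.

The generator emulates the shape of the curated benchmark — by default 70
reference orthogroups spread over 12 species with a pool of background
genes that belong to no RefOG — and perturbs perfect predictions with the
error modes a real inference method exhibits: splitting an orthogroup into
fragments, merging two orthogroups, leaving genes unassigned, and pulling
in contaminant background genes.

:func:`oracle_score` is a deliberately naive re-statement of the scoring
definitions: it walks every unordered gene pair in the universe and
classifies it literally.  It shares no code with :mod:`ogbench.scoring`
and exists as the independent ground truth the fast implementation is
checked against.

All generators are pure functions of their arguments including the seed:
one ``random.Random`` stream per call, with draws in a documented, fixed
order (RefOG sizes, then species offsets, then member placement, then
background placement; perturbations in spec order).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from math import ceil
from typing import FrozenSet, Mapping, Optional, Sequence

from .io import DomainHit, DomainHitTable
from .model import (
    ExclusionSet,
    GeneID,
    GeneUniverse,
    OrthogroupCollection,
    ROLE_PREDICTED,
    ROLE_REFERENCE,
    ValidationError,
    make_universe,
)

ORACLE_MAX_GENES = 2000

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Reference orthogroup generation


def generate_refogs(
    n_refogs: int = 70,
    sizes: tuple[int, int] | Sequence[int] = (5, 60),
    n_species: int = 12,
    background_genes: int = 200,
    seed: int = 0,
) -> tuple[GeneUniverse, OrthogroupCollection]:
    """Generate a gene universe and disjoint reference orthogroups.

    ``sizes`` is either a ``(min, max)`` range sampled per RefOG or an
    explicit per-RefOG size list.  Members are spread over species
    round-robin from a seeded random starting species, so per-species
    universes stay balanced while species composition varies per RefOG.
    Background genes belong to no RefOG.
    """
    if n_refogs < 1:
        raise ValidationError("n_refogs must be >= 1")
    if n_species < 1:
        raise ValidationError("n_species must be >= 1")
    rng = random.Random(seed)
    if len(sizes) == 2 and not isinstance(sizes, list):
        lo, hi = sizes
        size_list = [rng.randint(lo, hi) for _ in range(n_refogs)]
    else:
        size_list = list(sizes)
        if len(size_list) != n_refogs:
            raise ValidationError(
                f"{len(size_list)} explicit sizes for {n_refogs} RefOGs"
            )
    if min(size_list) < 2:
        raise ValidationError("RefOG sizes must be >= 2")

    species = [f"sp{i + 1:02d}" for i in range(n_species)]
    groups: dict[str, FrozenSet[GeneID]] = {}
    genes: list[GeneID] = []
    for j, size in enumerate(size_list):
        start = rng.randrange(n_species)
        members = []
        for k in range(size):
            tag = species[(start + k) % n_species]
            members.append(GeneID(tag, f"og{j:03d}m{k:03d}"))
        label = f"RefOG{j:03d}"
        groups[label] = frozenset(members)
        genes.extend(members)
    for k in range(background_genes):
        tag = species[k % n_species]
        genes.append(GeneID(tag, f"bg{k:05d}"))
    universe = make_universe(genes)
    refogs = OrthogroupCollection("synthetic-refogs", ROLE_REFERENCE, groups)
    return universe, refogs


def background_pool(
    universe: GeneUniverse, refogs: OrthogroupCollection
) -> tuple[GeneID, ...]:
    """Universe genes belonging to no RefOG, in sorted order."""
    return tuple(sorted(universe.all_genes() - refogs.all_genes()))


# ---------------------------------------------------------------------------
# Perturbations


@dataclass(frozen=True)
class PerturbationSpec:
    """A declarative description of prediction errors to inject.

    * ``splits``: (refog label, fragment sizes summing to the RefOG size)
    * ``merges``: pairs of RefOG labels whose predictions are unioned
    * ``drops``: (refog label, number of members left unassigned)
    * ``contaminants``: (refog label, number of background genes added)

    Applied per RefOG in the fixed order split -> drop -> contaminate;
    merging a RefOG that is also split is rejected.
    """

    splits: tuple[tuple[str, tuple[int, ...]], ...] = ()
    merges: tuple[tuple[str, str], ...] = ()
    drops: tuple[tuple[str, int], ...] = ()
    contaminants: tuple[tuple[str, int], ...] = ()
    seed: int = 0

    def touched_labels(self) -> frozenset[str]:
        labels = {lab for lab, _ in self.splits}
        labels.update(lab for pair in self.merges for lab in pair)
        labels.update(lab for lab, _ in self.drops)
        labels.update(lab for lab, _ in self.contaminants)
        return frozenset(labels)


def apply_perturbations(
    refogs: OrthogroupCollection,
    spec: PerturbationSpec,
    background: Sequence[GeneID] = (),
) -> OrthogroupCollection:
    """Produce a predicted collection by perturbing perfect predictions.

    Unperturbed RefOGs are copied verbatim (same labels).  Deterministic
    for a given spec (one RNG stream seeded from ``spec.seed``; choices
    are drawn from sorted candidate lists).
    """
    groups = {lab: set(m) for lab, m in refogs.groups.items()}
    split_labels = {lab for lab, _ in spec.splits}
    for a, b in spec.merges:
        for lab in (a, b):
            if lab not in groups:
                raise ValidationError(f"merge names unknown RefOG {lab!r}")
            if lab in split_labels:
                raise ValidationError(
                    f"RefOG {lab!r} cannot be both split and merged"
                )
    rng = random.Random(spec.seed)

    # split -> fragments named <label>.s0, .s1, ...
    fragments_of: dict[str, list[str]] = {lab: [lab] for lab in groups}
    for lab, frag_sizes in spec.splits:
        if lab not in refogs.groups:
            raise ValidationError(f"split names unknown RefOG {lab!r}")
        members = sorted(groups.pop(lab))
        if sum(frag_sizes) != len(members) or any(s < 1 for s in frag_sizes):
            raise ValidationError(
                f"split sizes {frag_sizes} do not partition RefOG {lab!r} "
                f"of size {len(members)}"
            )
        rng.shuffle(members)
        fragments_of[lab] = []
        pos = 0
        for i, s in enumerate(frag_sizes):
            flabel = f"{lab}.s{i}"
            groups[flabel] = set(members[pos:pos + s])
            fragments_of[lab].append(flabel)
            pos += s

    # drop members (spread over the RefOG's fragments at random)
    for lab, count in spec.drops:
        if lab not in refogs.groups:
            raise ValidationError(f"drop names unknown RefOG {lab!r}")
        if count < 1:
            raise ValidationError(f"drop count for {lab!r} must be >= 1")
        present = sorted(
            g for flab in fragments_of[lab] if flab in groups for g in groups[flab]
        )
        if count > len(present):
            raise ValidationError(
                f"cannot drop {count} members from RefOG {lab!r} "
                f"({len(present)} present)"
            )
        for g in rng.sample(present, count):
            for flab in fragments_of[lab]:
                groups.get(flab, set()).discard(g)
        for flab in list(fragments_of[lab]):
            if flab in groups and not groups[flab]:
                del groups[flab]

    # contaminants: background genes added to the RefOG's first fragment
    pool = sorted(set(background))
    used: set[GeneID] = set()
    for lab, count in spec.contaminants:
        if lab not in refogs.groups:
            raise ValidationError(f"contaminant names unknown RefOG {lab!r}")
        if count < 1:
            raise ValidationError(f"contaminant count for {lab!r} must be >= 1")
        available = [g for g in pool if g not in used]
        if count > len(available):
            raise ValidationError(
                f"spec needs {count} background genes for {lab!r}; "
                f"{len(available)} available"
            )
        chosen = rng.sample(available, count)
        used.update(chosen)
        targets = [f for f in fragments_of[lab] if f in groups]
        if not targets:
            raise ValidationError(
                f"RefOG {lab!r} has no surviving fragment to contaminate"
            )
        groups[targets[0]].update(chosen)

    # merges last: union the two (possibly already dropped/contaminated) sets
    for a, b in spec.merges:
        members = groups.pop(a, set()) | groups.pop(b, set())
        if members:
            groups[f"{a}+{b}"] = members

    return OrthogroupCollection(
        f"{refogs.name}-perturbed",
        ROLE_PREDICTED,
        {lab: frozenset(m) for lab, m in groups.items() if m},
    )


# ---------------------------------------------------------------------------
# Brute-force oracle


@dataclass(frozen=True)
class OracleScore:
    """Scores from literal all-pairs enumeration (the ground truth)."""

    per_refog: Mapping[str, tuple[int, int, int, int]]  # label -> (n, tp, fp, fn)
    precision: Optional[float]
    recall: float
    f_score: float
    unscoreable: tuple[str, ...]


def oracle_score(
    refogs: OrthogroupCollection,
    predicted: OrthogroupCollection,
    universe: GeneUniverse,
    exclusions: ExclusionSet = frozenset(),
) -> OracleScore:
    """Score by exhaustive enumeration of every unordered gene pair.

    Classifies each pair literally: co-predicted and co-referenced -> one
    TP for that RefOG; co-referenced only -> one FN; co-predicted across a
    RefOG boundary -> one FP for the RefOG of each endpoint that has one.
    Guarded to universes of at most 2,000 genes.
    """
    genes = sorted(universe.all_genes() - frozenset(exclusions))
    if len(genes) > ORACLE_MAX_GENES:
        raise ValidationError(
            f"oracle guard: {len(genes)} genes exceeds {ORACLE_MAX_GENES}"
        )
    gene_set = set(genes)

    ref_of: dict[GeneID, str] = {}
    for lab, members in refogs.groups.items():
        for g in members:
            if g in gene_set:
                ref_of[g] = lab
    pred_of: dict[GeneID, str] = {}
    for lab in sorted(predicted.groups):
        for g in predicted.groups[lab]:
            if g in gene_set and g not in pred_of:
                pred_of[g] = lab

    n_of: dict[str, int] = {}
    for g, lab in ref_of.items():
        n_of[lab] = n_of.get(lab, 0) + 1
    scoreable = {lab for lab, n in n_of.items() if n >= 2}
    unscoreable = tuple(
        sorted(set(refogs.groups) - scoreable)
    )

    tp = {lab: 0 for lab in scoreable}
    fp = {lab: 0 for lab in scoreable}
    fn = {lab: 0 for lab in scoreable}
    for i in range(len(genes)):
        gi = genes[i]
        ri = ref_of.get(gi)
        pi = pred_of.get(gi)
        for j in range(i + 1, len(genes)):
            gj = genes[j]
            rj = ref_of.get(gj)
            co_pred = pi is not None and pi == pred_of.get(gj)
            if ri is not None and ri == rj:
                if ri in scoreable:
                    if co_pred:
                        tp[ri] += 1
                    else:
                        fn[ri] += 1
            elif co_pred:
                if ri is not None and ri in scoreable:
                    fp[ri] += 1
                if rj is not None and rj in scoreable:
                    fp[rj] += 1

    sum_tp = Fraction(0)
    sum_fp = Fraction(0)
    sum_fn = Fraction(0)
    per: dict[str, tuple[int, int, int, int]] = {}
    for lab in sorted(scoreable):
        n = n_of[lab]
        per[lab] = (n, tp[lab], fp[lab], fn[lab])
        sum_tp += Fraction(tp[lab], n - 1)
        sum_fp += Fraction(fp[lab], n - 1)
        sum_fn += Fraction(fn[lab], n - 1)
    if not per:
        raise ValidationError("oracle: no scoreable RefOG")
    recall = float(sum_tp / (sum_tp + sum_fn))
    if sum_tp + sum_fp == 0:
        return OracleScore(per, None, recall, 0.0, unscoreable)
    precision = sum_tp / (sum_tp + sum_fp)
    rec = sum_tp / (sum_tp + sum_fn)
    f = 2 * precision * rec / (precision + rec) if precision + rec else Fraction(0)
    return OracleScore(per, float(precision), recall, float(f), unscoreable)


# ---------------------------------------------------------------------------
# Bundles and randomized fixtures


@dataclass(frozen=True)
class FixtureBundle:
    """A complete offline benchmark scenario with oracle-computed truth."""

    universe: GeneUniverse
    refogs: OrthogroupCollection
    predicted: OrthogroupCollection
    exclusions: ExclusionSet
    expected: OracleScore


def make_bundle(
    n_refogs: int = 70,
    sizes: tuple[int, int] | Sequence[int] = (5, 60),
    n_species: int = 12,
    background_genes: int = 200,
    spec: Optional[PerturbationSpec] = None,
    exclusions: ExclusionSet = frozenset(),
    seed: int = 0,
) -> FixtureBundle:
    """Generate refogs, apply a perturbation spec, and oracle-score it."""
    universe, refogs = generate_refogs(
        n_refogs, sizes, n_species, background_genes, seed
    )
    if spec is None:
        spec = PerturbationSpec(seed=seed)
    predicted = apply_perturbations(refogs, spec, background_pool(universe, refogs))
    expected = oracle_score(refogs, predicted, universe, exclusions)
    return FixtureBundle(universe, refogs, predicted, exclusions, expected)


def random_bundle(seed: int) -> FixtureBundle:
    """A randomized small scenario mixing all perturbation modes.

    Used for the oracle-equivalence campaign: every structural parameter
    (RefOG count and sizes, species count, background pool, perturbations,
    exclusions) is drawn from one stream seeded by ``seed``.
    """
    rng = random.Random(seed)
    n_refogs = rng.randint(3, 10)
    sizes = [rng.randint(2, 8) for _ in range(n_refogs)]
    n_species = rng.randint(3, 8)
    background = rng.randint(5, 20)
    universe, refogs = generate_refogs(
        n_refogs, sizes, n_species, background, seed=rng.randrange(2**31)
    )
    labels = sorted(refogs.groups)
    rng.shuffle(labels)
    splits = []
    drops = []
    contaminants = []
    merge_candidates = []
    for lab in labels:
        size = len(refogs.groups[lab])
        action = rng.random()
        if action < 0.25 and size >= 4:
            cut = rng.randint(1, size - 1)
            splits.append((lab, (cut, size - cut)))
        elif action < 0.40:
            drops.append((lab, rng.randint(1, max(1, size // 2))))
        elif action < 0.55:
            contaminants.append((lab, rng.randint(1, 2)))
        elif action < 0.70:
            merge_candidates.append(lab)
    merges = tuple(
        (merge_candidates[i], merge_candidates[i + 1])
        for i in range(0, len(merge_candidates) - 1, 2)
    )
    spec = PerturbationSpec(
        splits=tuple(splits),
        merges=merges,
        drops=tuple(drops),
        contaminants=tuple(contaminants),
        seed=rng.randrange(2**31),
    )
    predicted = apply_perturbations(refogs, spec, background_pool(universe, refogs))
    pool = sorted(universe.all_genes())
    exclusions = frozenset(rng.sample(pool, rng.randint(0, max(1, len(pool) // 20))))
    expected = oracle_score(refogs, predicted, universe, exclusions)
    return FixtureBundle(universe, refogs, predicted, exclusions, expected)


# ---------------------------------------------------------------------------
# Stratification fixtures


@dataclass(frozen=True)
class StratificationFixtures:
    """Synthetic per-RefOG MSAs, domain hits and quality scores.

    ``planted`` records the generating parameters (per-RefOG substitution
    rate, per-family prevalence fraction) so tests can assert against the
    intended structure rather than re-deriving it.
    """

    msas: Mapping[str, list[tuple[str, str]]]
    domain_hits: DomainHitTable
    quality: Mapping[str, float]
    planted_rates: Mapping[str, float]
    planted_prevalence: Mapping[str, dict[str, float]]


def generate_stratification_fixtures(
    refogs: OrthogroupCollection,
    seed: int = 0,
    alignment_length: int = 60,
) -> StratificationFixtures:
    """Emit MSAs with controllable divergence, planted domain tables and
    quality scores covering all terciles.

    Each RefOG gets a random ancestral protein mutated independently per
    member at a per-RefOG substitution rate (rate 0 means 100% identity);
    sequences are generated gapless, so the MSA is trivially valid.  Domain
    families are planted at prevalence fractions 0.5/0.75/1.0 and quality
    scores drawn uniformly over [0.5, 1.5].
    """
    rng = random.Random(seed)
    msas: dict[str, list[tuple[str, str]]] = {}
    rates: dict[str, float] = {}
    prevalence: dict[str, dict[str, float]] = {}
    quality: dict[str, float] = {}
    rows: list[DomainHit] = []
    for label in sorted(refogs.groups):
        members = sorted(refogs.groups[label])
        rate = rng.uniform(0.0, 0.45)
        rates[label] = rate
        ancestor = [rng.choice(AMINO_ACIDS) for _ in range(alignment_length)]
        msa = []
        for g in members:
            seq = []
            for aa in ancestor:
                if rng.random() < rate:
                    seq.append(rng.choice(AMINO_ACIDS.replace(aa, "")))
                else:
                    seq.append(aa)
            msa.append((str(g), "".join(seq)))
        msas[label] = msa

        n_fam = rng.randint(1, 4)
        prevalence[label] = {}
        for fidx in range(n_fam):
            family = f"FAM_{label}_{fidx}"
            frac = rng.choice((0.5, 0.75, 1.0))
            prevalence[label][family] = frac
            carriers = rng.sample(members, ceil(frac * len(members)))
            for g in carriers:
                rows.append(DomainHit(g, family, 1e-10, 1, alignment_length))
        quality[label] = round(rng.uniform(0.5, 1.5), 3)
    return StratificationFixtures(
        msas=msas,
        domain_hits=DomainHitTable(tuple(rows)),
        quality=quality,
        planted_rates=rates,
        planted_prevalence=prevalence,
    )
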