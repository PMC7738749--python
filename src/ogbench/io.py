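"""Readers and writers for every external representation the benchmark touches.

Orthogroup flat files come in three dialects:

``flat``
    One group per line.  An optional ``label:`` prefix names the group;
    unlabeled lines are auto-numbered by position.  Gene tokens are
    whitespace-separated.
``orthomcl``
    ``GROUP: geneA geneB ...`` — like ``flat`` but the label prefix is
    mandatory.
``orthofinder-tsv``
    Tab-separated; first row is a header whose columns (after the group
    label column) are species tags; cells hold comma-plus-space separated
    accessions belonging to that species.

Species attribution of a bare gene token is resolved either by a
``species_map`` (token -> species tag) or by a prefix rule splitting on a
separator character (``|`` by default, ``_`` also common); the content of
the proteomes is never consulted.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd
from Bio import SeqIO

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # Bio.SearchIO flags itself experimental
    from Bio import SearchIO

from .model import (
    CANONICAL_SEP,
    ExclusionSet,
    GeneID,
    GeneUniverse,
    IntegrityError,
    OrthogroupCollection,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

DIALECTS = ("flat", "orthomcl", "orthofinder-tsv")


def _resolve_token(
    token: str,
    sep: str,
    species_map: Optional[Mapping[str, str]],
    where: str,
) -> GeneID:
    if species_map is not None:
        try:
            return GeneID(species_map[token], token)
        except KeyError:
            raise ParseError(f"{where}: token {token!r} absent from species map")
    try:
        return GeneID.parse(token, sep=sep)
    except ParseError as exc:
        raise ParseError(f"{where}: {exc}")


def read_orthogroups(
    path: str | Path,
    dialect: str,
    role: str,
    *,
    sep: str = CANONICAL_SEP,
    species_map: Optional[Mapping[str, str]] = None,
    name: Optional[str] = None,
) -> OrthogroupCollection:
    """Read an orthogroup collection from a flat file in the given dialect.

    Blank lines and ``#`` comment lines are ignored.  Singleton groups are
    preserved.  Duplicate group labels raise :class:`ParseError`; a gene
    present in two *reference* groups raises :class:`IntegrityError`.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise OSError(f"orthogroup file not found: {path}")

    if dialect == "orthofinder-tsv":
        groups = _read_orthofinder_tsv(path, species_map)
    else:
        groups = _read_flat(path, dialect, sep, species_map)

    return OrthogroupCollection(name or path.stem, role, groups)


def _read_flat(
    path: Path,
    dialect: str,
    sep: str,
    species_map: Optional[Mapping[str, str]],
) -> dict[str, frozenset[GeneID]]:
    groups: dict[str, frozenset[GeneID]] = {}
    auto = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            where = f"{path}:{lineno}"
            label_part, colon, body = line.partition(":")
            if colon and " " not in label_part and sep not in label_part:
                label = label_part.strip()
                if not label:
                    raise ParseError(f"{where}: empty group label before ':'")
            elif dialect == "orthomcl":
                raise ParseError(f"{where}: orthomcl dialect requires 'label: genes'")
            else:
                label, body = f"OG{auto:07d}", line
            auto += 1
            tokens = body.split()
            if not tokens:
                raise ParseError(f"{where}: group {label!r} has no genes")
            if label in groups:
                raise ParseError(f"{where}: duplicate group label {label!r}")
            groups[label] = frozenset(
                _resolve_token(t, sep, species_map, where) for t in tokens
            )
    return groups


def _read_orthofinder_tsv(
    path: Path,
    species_map: Optional[Mapping[str, str]],
) -> dict[str, frozenset[GeneID]]:
    groups: dict[str, frozenset[GeneID]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty orthofinder-tsv file")
        species_tags = header[1:]
        if not species_tags:
            raise ParseError(f"{path}:1: header has no species columns")
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            where = f"{path}:{lineno}"
            label = row[0].strip()
            if not label:
                raise ParseError(f"{where}: missing group label in first column")
            if label in groups:
                raise ParseError(f"{where}: duplicate group label {label!r}")
            members: set[GeneID] = set()
            for tag, cell in zip(species_tags, row[1:]):
                cell = cell.strip()
                if not cell:
                    continue
                for acc in cell.split(", "):
                    acc = acc.strip()
                    if not acc:
                        raise ParseError(f"{where}: empty gene entry in column {tag!r}")
                    if species_map is not None:
                        members.add(_resolve_token(acc, CANONICAL_SEP, species_map, where))
                    else:
                        members.add(GeneID(tag, acc))
            if not members:
                raise ParseError(f"{where}: group {label!r} has no genes")
            groups[label] = frozenset(members)
    return groups


def write_orthogroups(
    collection: OrthogroupCollection, path: str | Path
) -> None:
    """Write a collection in the ``flat`` dialect (canonical gene tokens)."""
    with open(path, "w") as fh:
        for label in sorted(collection.groups):
            genes = " ".join(sorted(str(g) for g in collection.groups[label]))
            fh.write(f"{label}: {genes}\n")


def read_exclusions(
    path: str | Path,
    *,
    sep: str = CANONICAL_SEP,
    species_map: Optional[Mapping[str, str]] = None,
) -> ExclusionSet:
    """Read the low-certainty gene list: whitespace-separated tokens."""
    genes: set[GeneID] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            for token in line.split():
                genes.add(_resolve_token(token, sep, species_map, f"{path}:{lineno}"))
    return frozenset(genes)


def read_fasta_universe(
    paths: Sequence[str | Path], species_tags: Sequence[str]
) -> GeneUniverse:
    """Build the gene universe from one proteome FASTA per species.

    Record IDs become accessions, namespaced by the species tag of their
    file.  A duplicated record ID within one species is an integrity error;
    an empty FASTA yields an empty species set (with a warning).
    """
    if len(paths) != len(species_tags):
        raise ValidationError(
            f"{len(paths)} FASTA paths but {len(species_tags)} species tags"
        )
    per_species: dict[str, frozenset[GeneID]] = {}
    for path, tag in zip(paths, species_tags):
        if tag in per_species:
            raise ValidationError(f"species tag {tag!r} given twice")
        seen: set[str] = set()
        genes: set[GeneID] = set()
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in seen:
                raise IntegrityError(
                    f"{path}: duplicate record ID {record.id!r} in species {tag!r}"
                )
            seen.add(record.id)
            genes.add(GeneID(tag, record.id))
        if not genes:
            logger.warning("proteome %s (%s) contains no records", path, tag)
        per_species[tag] = frozenset(genes)
    return GeneUniverse(per_species)


class HmmHit(NamedTuple):
    """One full-sequence hit from an hmmsearch run."""

    gene: GeneID
    query: str
    evalue: float
    score: float


@dataclass(frozen=True)
class HmmHitTable:
    """hmmsearch full-sequence hits, in file order until sorted.

    The deterministic sort is ascending e-value, ties broken by descending
    bit score then lexicographic gene identifier.
    """

    rows: tuple[HmmHit, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def sorted(self) -> "HmmHitTable":
        key = lambda h: (h.evalue, -h.score, str(h.gene))
        return HmmHitTable(tuple(sorted(self.rows, key=key)))


def read_hmm_hits(
    path: str | Path,
    *,
    sep: str = CANONICAL_SEP,
    species_map: Optional[Mapping[str, str]] = None,
) -> HmmHitTable:
    """Parse an hmmsearch ``--tblout`` table into an :class:`HmmHitTable`."""
    rows: list[HmmHit] = []
    try:
        for qresult in SearchIO.parse(str(path), "hmmer3-tab"):
            for hit in qresult:
                if hit.evalue < 0:
                    raise ParseError(
                        f"{path}: negative e-value {hit.evalue!r} for target {hit.id!r}"
                    )
                gene = _resolve_token(hit.id, sep, species_map, str(path))
                rows.append(HmmHit(gene, qresult.id, float(hit.evalue), float(hit.bitscore)))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed hmmsearch tblout: {exc}")
    return HmmHitTable(tuple(rows))


class DomainHit(NamedTuple):
    """One domain instance from an hmmscan run against Pfam.

    Envelope coordinates are 1-based inclusive.
    """

    gene: GeneID
    family: str
    evalue: float
    env_start: int
    env_end: int


@dataclass(frozen=True)
class DomainHitTable:
    """Per-domain hits; one row per domain instance."""

    rows: tuple[DomainHit, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def filtered(self, max_evalue: float) -> "DomainHitTable":
        """Keep only domain calls at or below the e-value threshold."""
        return DomainHitTable(tuple(r for r in self.rows if r.evalue <= max_evalue))


def read_domain_hits(
    path: str | Path,
    *,
    sep: str = CANONICAL_SEP,
    species_map: Optional[Mapping[str, str]] = None,
) -> DomainHitTable:
    """Parse an hmmscan ``--domtblout`` table (gene as query, family as target)."""
    rows: list[DomainHit] = []
    try:
        for qresult in SearchIO.parse(str(path), "hmmscan3-domtab"):
            gene = _resolve_token(qresult.id, sep, species_map, str(path))
            for hit in qresult:
                for hsp in hit:
                    if hsp.evalue < 0:
                        raise ParseError(
                            f"{path}: negative e-value {hsp.evalue!r} for {hit.id!r}"
                        )
                    start = hsp.env_start + 1  # 0-based half-open -> 1-based inclusive
                    end = hsp.env_end
                    if start > end:
                        raise ParseError(
                            f"{path}: inverted envelope {start}..{end} for {hit.id!r}"
                        )
                    rows.append(DomainHit(gene, hit.id, float(hsp.evalue), start, end))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed hmmscan domtblout: {exc}")
    return DomainHitTable(tuple(rows))


def read_quality_scores(path: str | Path) -> dict[str, float]:
    """Read precomputed alignment-quality (norMD) scores.

    Two-column TSV: RefOG label, score.  Lines starting ``#`` are comments.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=["refog", "score"], dtype=str
    )
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        label = str(row["refog"]).strip()
        try:
            score = float(row["score"])
        except (TypeError, ValueError):
            raise ParseError(f"{path}: non-numeric quality score for {label!r}")
        if label in out:
            raise ParseError(f"{path}: duplicate quality entry for {label!r}")
        out[label] = score
    return out


def read_alignment_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA multiple sequence alignment as (id, sequence) pairs."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ParseError(f"{path}: empty alignment")
    lengths = {len(s) for _, s in records}
    if len(lengths) > 1:
        raise ParseError(f"{path}: ragged alignment (lengths {sorted(lengths)})")
    return records


# ---------------------------------------------------------------------------
# Benchmark reports


def _result_to_dict(result, config: Optional[Mapping] = None) -> dict:
    d = {
        "precision": result.precision,
        "recall": result.recall,
        "f_score": result.f_score,
        "exact_count": result.exact_count,
        "n_refogs_scored": len(result.per_refog),
        "ari": result.ari,
        "dropped_genes": result.dropped_genes,
        "unscoreable": list(result.unscoreable),
        "per_refog": [
            {
                "refog": pc.refog_label,
                "n": pc.n,
                "tp_raw": pc.tp_raw,
                "fp_raw": pc.fp_raw,
                "fn_raw": pc.fn_raw,
                "tp_norm": float(pc.tp_norm),
                "fp_norm": float(pc.fp_norm),
                "fn_norm": float(pc.fn_norm),
            }
            for pc in result.per_refog
        ],
        "diagnostics": [
            {
                "refog": dg.refog_label,
                "fragments": dg.fragments,
                "missing": dg.missing,
                "extra": dg.extra,
                "exact": dg.exact,
            }
            for dg in result.diagnostics
        ],
    }
    if config is not None:
        d["config"] = dict(config)
    return d


def write_report(
    result,
    path: str | Path,
    format: str = "json",
    *,
    config: Optional[Mapping] = None,
) -> None:
    """Write a :class:`~ogbench.scoring.BenchmarkResult` to disk.

    Output is byte-stable: identical results produce identical files.  The
    JSON form round-trips all numeric fields exactly (floats use shortest
    round-trip repr); the TSV form prints aggregate percentages at fixed
    precision for human consumption.
    """
    if format == "json":
        payload = json.dumps(
            _result_to_dict(result, config), indent=2, sort_keys=True
        )
        Path(path).write_text(payload + "\n")
    elif format == "tsv":
        lines = []
        if config:
            for k in sorted(config):
                lines.append(f"# {k}: {config[k]}")
        pct = lambda x: "NA" if x is None else f"{100.0 * x:.1f}"
        lines.append(f"# precision\t{pct(result.precision)}")
        lines.append(f"# recall\t{pct(result.recall)}")
        lines.append(f"# f_score\t{pct(result.f_score)}")
        lines.append(f"# exact_count\t{result.exact_count}")
        if result.ari is not None:
            lines.append(f"# ari\t{result.ari:.4f}")
        lines.append(
            "refog\tn\ttp_raw\tfp_raw\tfn_raw\ttp_norm\tfp_norm\tfn_norm"
            "\tfragments\tmissing\textra\texact"
        )
        diag = {d.refog_label: d for d in result.diagnostics}
        for pc in result.per_refog:
            d = diag[pc.refog_label]
            lines.append(
                f"{pc.refog_label}\t{pc.n}\t{pc.tp_raw}\t{pc.fp_raw}\t{pc.fn_raw}"
                f"\t{float(pc.tp_norm)!r}\t{float(pc.fp_norm)!r}\t{float(pc.fn_norm)!r}"
                f"\t{d.fragments}\t{d.missing}\t{d.extra}\t{int(d.exact)}"
            )
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown report format {format!r}")


def read_report_json(path: str | Path):
    """Re-read a JSON report into a BenchmarkResult (exact round-trip)."""
    from .scoring import BenchmarkResult, PairCounts, RefogDiagnostics

    d = json.loads(Path(path).read_text())
    per = tuple(
        PairCounts(p["refog"], p["n"], p["tp_raw"], p["fp_raw"], p["fn_raw"])
        for p in d["per_refog"]
    )
    diag = tuple(
        RefogDiagnostics(
            g["refog"], g["fragments"], g["missing"], g["extra"], g["exact"]
        )
        for g in d["diagnostics"]
    )
    return BenchmarkResult(
        precision=d["precision"],
        recall=d["recall"],
        f_score=d["f_score"],
        exact_count=d["exact_count"],
        per_refog=per,
        diagnostics=diag,
        unscoreable=tuple(d["unscoreable"]),
        ari=d["ari"],
        dropped_genes=d["dropped_genes"],
    )
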