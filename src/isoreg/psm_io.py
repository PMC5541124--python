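"""Readers and writers for PSM tables, packaged reference tables, annotation
tables, and interaction edge lists.

The PSM table is the pipeline's raw input unit: one row per peptide-spectrum
match (PSM), carrying the protein accession, a Mascot-like search score, a
target/decoy flag, and iTRAQ four-plex reporter intensities for channels
114/115/116/117. Missing intensities are serialized as empty fields.

Four reference tables are packaged as TSV fixtures (checksum-pinned):

========  ==============================================================
table id  contents
========  ==============================================================
T1A       ten most upregulated proteins, vehicle vs sham (log2 ratios)
T1B       ten most downregulated proteins, vehicle vs sham
T2        group 1 — SAH-induced upregulation abolished by U0126
T3        group 2 — SAH-induced downregulation abolished by U0126
========  ==============================================================
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import FixtureIntegrityError, ParseError

CHANNELS = (114, 115, 116, 117)

PSM_COLUMNS = [
    "psm_id", "experiment_id", "peptide", "accession", "score", "is_decoy",
    "i114", "i115", "i116", "i117",
]

#: Controlled vocabulary of molecular-function categories for annotations.
CATEGORY_VOCABULARY = frozenset({
    "catalytic activity",
    "binding",
    "structural activity",
    "enzyme regulator activity",
    "transcription factor activity",
    "receptor activity",
    "translation",
    "transporter",
})

#: Pinned checksums of the packaged reference tables.
FIXTURE_SHA256 = {
    "T1A": ("table1a.tsv", "46397db89323c73e2657ca63e56f17006d9e44f499c7d5121a3d3611d636693c"),
    "T1B": ("table1b.tsv", "c3ce533c7e12ff47cd6554fef4f4434f7760e30c24495586edfe18c3b8d8407e"),
    "T2": ("table2.tsv", "ffbd63b4cdc56f3695955eed30e6c6aac5df25e6b4eb99f99343ce7133102283"),
    "T3": ("table3.tsv", "2339aa7803c9709ca8f2881ba7d36b21f8fd4808191f5f61edc8c3366be42d68"),
}


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match.

    ``intensities`` maps reporter channel (114/115/116/117) to a non-negative
    intensity; channels without a measurement are simply absent from the map.
    ``q_value`` is filled in by :func:`isoreg.filtering.estimate_qvalues`.
    """

    psm_id: str
    experiment_id: str
    peptide: str
    accession: str
    score: float
    is_decoy: bool
    intensities: Mapping[int, float] = field(default_factory=dict)
    q_value: float | None = None

    def with_q(self, q: float) -> "PSMRecord":
        return replace(self, q_value=q)


@dataclass(frozen=True)
class PaperTableRow:
    """One row of a packaged reference table: accession, protein name, log2 ratio."""

    accession: str
    protein_name: str
    log2_ratio: float


@dataclass(frozen=True)
class AnnotationRecord:
    """Molecular-function annotation: accession -> non-empty set of categories."""

    accession: str
    categories: frozenset[str]


@dataclass(frozen=True)
class NetworkEdge:
    """Undirected scored interaction between two distinct accessions.

    Endpoints are stored in sorted order so that (A, B) == (B, A).
    """

    accession_a: str
    accession_b: str
    score: float

    def __post_init__(self) -> None:
        if self.accession_a > self.accession_b:
            a, b = self.accession_b, self.accession_a
            object.__setattr__(self, "accession_a", a)
            object.__setattr__(self, "accession_b", b)


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

def _parse_intensity(text: str, row: int, col: str) -> float | None:
    if text == "":
        return None
    try:
        value = float(text)
    except ValueError as exc:
        raise ParseError(f"row {row}: non-numeric intensity {text!r} in {col}") from exc
    if not math.isfinite(value) or value < 0:
        raise ParseError(f"row {row}: negative or non-finite intensity {text!r} in {col}")
    return value


def read_psm_table(path: str | Path) -> list[PSMRecord]:
    """Read a tab-separated PSM table.

    Raises :class:`ParseError` (with the 1-based data-row number) on a
    malformed header, a non-numeric score, a negative intensity, or a bad
    decoy flag. Empty intensity fields become missing channels.
    """
    path = Path(path)
    records: list[PSMRecord] = []
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected header {PSM_COLUMNS}")
        if header != PSM_COLUMNS:
            raise ParseError(f"{path}: malformed header {header!r}, expected {PSM_COLUMNS}")
        for row_no, row in enumerate(reader, start=1):
            if len(row) != len(PSM_COLUMNS):
                raise ParseError(f"row {row_no}: expected {len(PSM_COLUMNS)} fields, got {len(row)}")
            psm_id, experiment_id, peptide, accession, score_s, decoy_s = row[:6]
            try:
                score = float(score_s)
            except ValueError as exc:
                raise ParseError(f"row {row_no}: non-numeric score {score_s!r}") from exc
            if not math.isfinite(score):
                raise ParseError(f"row {row_no}: non-finite score {score_s!r}")
            if decoy_s not in {"0", "1"}:
                raise ParseError(f"row {row_no}: is_decoy must be 0 or 1, got {decoy_s!r}")
            intensities = {}
            for channel, text in zip(CHANNELS, row[6:]):
                value = _parse_intensity(text, row_no, f"i{channel}")
                if value is not None:
                    intensities[channel] = value
            records.append(PSMRecord(
                psm_id=psm_id, experiment_id=experiment_id, peptide=peptide,
                accession=accession, score=score, is_decoy=decoy_s == "1",
                intensities=intensities,
            ))
    return records


def write_psm_table(records: Sequence[PSMRecord], path: str | Path) -> None:
    """Write PSM records as a TSV readable by :func:`read_psm_table`.

    Floats are written with ``repr`` so the round trip is lossless. An empty
    record set is refused: a PSM table without rows is almost always an
    upstream mistake.
    """
    if not records:
        raise ValueError("refusing to write an empty PSM table")
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PSM_COLUMNS)
        for rec in records:
            row = [rec.psm_id, rec.experiment_id, rec.peptide, rec.accession,
                   repr(rec.score), "1" if rec.is_decoy else "0"]
            for channel in CHANNELS:
                value = rec.intensities.get(channel)
                row.append("" if value is None else repr(value))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

def _fixture_bytes(table_id: str) -> bytes:
    try:
        filename, expected_sha = FIXTURE_SHA256[table_id]
    except KeyError:
        raise FixtureIntegrityError(
            f"unknown table id {table_id!r}; expected one of {sorted(FIXTURE_SHA256)}")
    try:
        data = (resources.files("isoreg") / "fixtures" / filename).read_bytes()
    except FileNotFoundError as exc:
        raise FixtureIntegrityError(f"fixture {filename} is missing from the package") from exc
    actual = hashlib.sha256(data).hexdigest()
    if actual != expected_sha:
        raise FixtureIntegrityError(
            f"fixture {filename} checksum mismatch: expected {expected_sha}, got {actual}")
    return data


def parse_table_rows(text: str) -> list[PaperTableRow]:
    """Parse a reference-table TSV body (``#`` comments, then a header row)."""
    rows: list[PaperTableRow] = []
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    if not lines or lines[0].split("\t") != ["accession", "name", "log2"]:
        raise ParseError("reference table must start with header accession/name/log2")
    for row_no, line in enumerate(lines[1:], start=1):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"row {row_no}: expected 3 fields, got {len(fields)}")
        accession, name, log2_s = fields
        try:
            log2 = float(log2_s)
        except ValueError as exc:
            raise ParseError(f"row {row_no}: non-numeric log2 {log2_s!r}") from exc
        if not math.isfinite(log2):
            raise ParseError(f"row {row_no}: non-finite log2 {log2_s!r}")
        rows.append(PaperTableRow(accession=accession, protein_name=name, log2_ratio=log2))
    return rows


def load_fixture(table_id: str) -> list[PaperTableRow]:
    """Load a packaged reference table (``T1A``, ``T1B``, ``T2`` or ``T3``).

    The file's checksum is verified against a pinned value before parsing, so
    a tampered or corrupted fixture fails loudly rather than silently shifting
    downstream counts. Duplicate accessions are preserved verbatim (the group-1
    table lists four accessions twice).
    """
    return parse_table_rows(_fixture_bytes(table_id).decode())


# ---------------------------------------------------------------------------
# Annotation tables and edge lists
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> list[AnnotationRecord]:
    """Read a TSV of ``accession<TAB>category;category;...`` lines.

    Category labels must come from :data:`CATEGORY_VOCABULARY`; an empty
    category set or an unknown label is a :class:`ParseError` naming the row.
    Lines starting with ``#`` are ignored.
    """
    records: list[AnnotationRecord] = []
    seen: dict[str, int] = {}
    with Path(path).open() as handle:
        for row_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"row {row_no}: expected 2 fields, got {len(fields)}")
            accession, cats_s = fields
            categories = frozenset(c.strip() for c in cats_s.split(";") if c.strip())
            if not categories:
                raise ParseError(f"row {row_no}: empty category set for {accession!r}")
            unknown = categories - CATEGORY_VOCABULARY
            if unknown:
                raise ParseError(f"row {row_no}: unknown categories {sorted(unknown)}")
            if accession in seen:
                raise ParseError(
                    f"row {row_no}: duplicate accession {accession!r} (first at row {seen[accession]})")
            seen[accession] = row_no
            records.append(AnnotationRecord(accession=accession, categories=categories))
    return records


def read_edges(path: str | Path) -> list[NetworkEdge]:
    """Read a TSV edge list ``accession_a<TAB>accession_b<TAB>score``.

    Edges are undirected; duplicates (in either orientation) are deduplicated
    keeping the maximum score. Self-edges and scores outside [0, 1] are
    rejected with the row number. An empty file yields an empty list.
    """
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    with Path(path).open() as handle:
        for row_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"row {row_no}: expected 3 fields, got {len(fields)}")
            a, b, score_s = fields
            if a == b:
                raise ParseError(f"row {row_no}: self-edge on {a!r}")
            try:
                score = float(score_s)
            except ValueError as exc:
                raise ParseError(f"row {row_no}: non-numeric score {score_s!r}") from exc
            if not 0.0 <= score <= 1.0:
                raise ParseError(f"row {row_no}: score {score} outside [0, 1]")
            key = (min(a, b), max(a, b))
            if key not in best:
                order.append(key)
                best[key] = score
            else:
                best[key] = max(best[key], score)
    return [NetworkEdge(a, b, best[(a, b)]) for a, b in order]


def demo_path(kind: str) -> Path:
    """Path to a packaged synthetic demo file: ``annotation`` or ``edges``.

    These are hand-constructed illustrative inputs for the summarize stage,
    not database exports.
    """
    names = {"annotation": "demo_annotation.synthetic.tsv",
             "edges": "demo_edges.synthetic.tsv"}
    if kind not in names:
        raise ValueError(f"unknown demo file kind {kind!r}; expected one of {sorted(names)}")
    return Path(str(resources.files("isoreg") / "fixtures" / names[kind]))


def write_edges(edges: Iterable[NetworkEdge], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for edge in edges:
            handle.write(f"{edge.accession_a}\t{edge.accession_b}\t{repr(edge.score)}\n")
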