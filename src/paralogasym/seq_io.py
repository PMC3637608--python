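"""Input/output for the pipeline's external formats.

Three kinds of input describe a dataset of duplicate gene pairs:

* FASTA collections of nucleotide or amino-acid sequences (spliced CDS and
  genomic context per paralog, plus outgroup CDS),
* a tab-separated annotation table with one row per gene (chromosome, strand,
  span, exon intervals, pseudogene flag, optional outgroup-ortholog link),
* a pairing manifest naming paralog-A / paralog-B / outgroup triplets.

All coordinates are 0-based, half-open. Stored sequences are sense-strand;
strand is metadata used only for transcriptional-orientation classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

log = logging.getLogger(__name__)

GAP = "-"


class Alphabet(str, Enum):
    NUCLEOTIDE = "nucleotide"
    AMINO_ACID = "amino_acid"


# Ambiguity codes are preserved on read and excluded from site counts downstream.
_NT_CHARS = frozenset("ACGTN" + GAP)
_AA_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWY*X" + GAP)


def _allowed(alphabet: Alphabet) -> frozenset[str]:
    return _NT_CHARS if alphabet is Alphabet.NUCLEOTIDE else _AA_CHARS


class FastaParseError(ValueError):
    """Malformed FASTA content; message names the offending line."""


class ValidationError(ValueError):
    """A record violates a declared invariant; message names the record."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over a declared alphabet (gaps and N/X allowed)."""

    id: str
    residues: str
    alphabet: Alphabet = Alphabet.NUCLEOTIDE
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r}: empty residues")
        bad = set(self.residues) - _allowed(self.alphabet)
        if bad:
            raise ValidationError(
                f"sequence {self.id!r}: illegal {self.alphabet.value} "
                f"character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic annotation of one gene: location, exon layout, status.

    ``exons`` are 0-based half-open intervals in chromosome coordinates,
    sorted, non-overlapping and contained in ``[span_start, span_end)``.
    """

    gene_id: str
    chromosome: str
    strand: str
    span_start: int
    span_end: int
    exons: tuple[tuple[int, int], ...]
    pseudogene: bool = False
    ortholog_id: str | None = None
    ortholog_chromosome: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (0 <= self.span_start < self.span_end):
            raise ValidationError(
                f"{self.gene_id}: invalid span [{self.span_start}, {self.span_end})"
            )
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValidationError(f"{self.gene_id}: empty exon [{start}, {end})")
            if start < self.span_start or end > self.span_end:
                raise ValidationError(
                    f"{self.gene_id}: exon [{start}, {end}) outside gene span"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"{self.gene_id}: exons overlap or are unsorted at [{start}, {end})"
                )
            prev_end = end

    @property
    def length(self) -> int:
        return self.span_end - self.span_start


@dataclass(frozen=True)
class PairManifestEntry:
    """One duplicate pair plus its outgroup: the unit of analysis."""

    pair_id: str
    paralog_a: str
    paralog_b: str
    outgroup: str
    outgroup_source: str = ""

    def __post_init__(self) -> None:
        if self.paralog_a == self.paralog_b:
            raise ValidationError(f"{self.pair_id}: paralog_a == paralog_b")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, alphabet: Alphabet) -> dict[str, SequenceRecord]:
    """Parse a FASTA file into an ordered mapping id -> record.

    Residues are uppercased and record order is preserved (dicts are ordered).
    Parsing is done line-by-line here, not delegated, so that malformed
    headers and illegal characters can be reported with their line number.
    """
    path = Path(path)
    records: dict[str, SequenceRecord] = {}
    cur_id: str | None = None
    cur_desc = ""
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if cur_id is None:
            return
        if cur_id in records:
            raise FastaParseError(
                f"{path.name}:{header_line}: duplicate id {cur_id!r}"
            )
        residues = "".join(chunks)
        if not residues:
            raise FastaParseError(f"{path.name}:{header_line}: record {cur_id!r} has no sequence")
        try:
            records[cur_id] = SequenceRecord(cur_id, residues, alphabet, cur_desc)
        except ValidationError as exc:
            raise FastaParseError(f"{path.name}:{header_line}: {exc}") from exc

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path.name}:{lineno}: empty FASTA header")
                parts = header.split(None, 1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                chunks = []
                header_line = lineno
            else:
                if cur_id is None:
                    raise FastaParseError(
                        f"{path.name}:{lineno}: sequence data before first header"
                    )
                seq = line.upper()
                bad = set(seq) - _allowed(alphabet)
                if bad:
                    raise FastaParseError(
                        f"{path.name}:{lineno}: illegal {alphabet.value} "
                        f"character(s) {sorted(bad)}"
                    )
                chunks.append(seq)
        flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation TSV
#
# Columns: gene_id, chromosome, strand, start, end, exons (comma-separated
# "start-end" pairs), pseudogene (0/1), ortholog_id, ortholog_chromosome
# (the last two may be empty).

ANNOTATION_COLUMNS = [
    "gene_id", "chromosome", "strand", "start", "end",
    "exons", "pseudogene", "ortholog_id", "ortholog_chromosome",
]


def _parse_exons(text: str, gene_id: str) -> tuple[tuple[int, int], ...]:
    out = []
    for token in str(text).split(","):
        token = token.strip()
        if not token:
            continue
        try:
            start_s, end_s = token.split("-")
            out.append((int(start_s), int(end_s)))
        except ValueError as exc:
            raise ValidationError(f"{gene_id}: cannot parse exon {token!r}") from exc
    if not out:
        raise ValidationError(f"{gene_id}: no exons")
    return tuple(out)


def read_annotations(path: str | Path) -> dict[str, GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation table missing column(s): {missing}")
    annots: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        gene_id = row.gene_id
        if gene_id in annots:
            raise ValidationError(f"duplicate annotation for {gene_id!r}")
        annots[gene_id] = GeneAnnotation(
            gene_id=gene_id,
            chromosome=row.chromosome,
            strand=row.strand,
            span_start=int(row.start),
            span_end=int(row.end),
            exons=_parse_exons(row.exons, gene_id),
            pseudogene=str(row.pseudogene).strip() in ("1", "True", "true"),
            ortholog_id=row.ortholog_id or None,
            ortholog_chromosome=row.ortholog_chromosome or None,
        )
    return annots


def write_annotations(annots: Iterable[GeneAnnotation], path: str | Path) -> None:
    rows = []
    for a in annots:
        rows.append({
            "gene_id": a.gene_id,
            "chromosome": a.chromosome,
            "strand": a.strand,
            "start": a.span_start,
            "end": a.span_end,
            "exons": ",".join(f"{s}-{e}" for s, e in a.exons),
            "pseudogene": int(a.pseudogene),
            "ortholog_id": a.ortholog_id or "",
            "ortholog_chromosome": a.ortholog_chromosome or "",
        })
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pairing manifest

MANIFEST_COLUMNS = ["pair_id", "paralog_a", "paralog_b", "outgroup", "outgroup_source"]


def read_manifest(
    path: str | Path,
    sequences: dict[str, SequenceRecord] | None = None,
    annotations: dict[str, GeneAnnotation] | None = None,
) -> list[PairManifestEntry]:
    """Read the triplet manifest, cross-checking every id that is checkable.

    ``sequences``/``annotations`` are optional so the manifest can be read
    standalone; when given, every referenced id must resolve (outgroups are
    checked against sequences only — they may lack annotations).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing column(s): {missing}")
    entries = []
    unresolved: list[str] = []
    for row in df.itertuples(index=False):
        entry = PairManifestEntry(
            pair_id=row.pair_id,
            paralog_a=row.paralog_a,
            paralog_b=row.paralog_b,
            outgroup=row.outgroup,
            outgroup_source=getattr(row, "outgroup_source", ""),
        )
        if sequences is not None:
            for gid in (entry.paralog_a, entry.paralog_b, entry.outgroup):
                if gid not in sequences:
                    unresolved.append(gid)
        if annotations is not None:
            for gid in (entry.paralog_a, entry.paralog_b):
                if gid not in annotations:
                    unresolved.append(gid)
        entries.append(entry)
    if unresolved:
        raise ValidationError(
            "manifest references unknown id(s): " + ", ".join(sorted(set(unresolved)))
        )
    if not entries:
        log.warning("manifest %s is empty", path)
    return entries


def write_manifest(entries: Iterable[PairManifestEntry], path: str | Path) -> None:
    rows = [
        {
            "pair_id": e.pair_id,
            "paralog_a": e.paralog_a,
            "paralog_b": e.paralog_b,
            "outgroup": e.outgroup,
            "outgroup_source": e.outgroup_source,
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)
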