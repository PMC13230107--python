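"""Readers and writers for every external format the pipeline touches.

Formats: CDS FASTA (DNA alphabet), host codon-usage tables in the Kazusa text
dialect (``CODON freq (count)`` blocks, RNA or DNA alphabet) or an equivalent
3-column TSV, BLAST-style tabular similarity hits, and a gene annotation TSV.
All downstream modules consume only the domain types defined here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._genetic_code import CODONS, GENETIC_CODE
from .errors import ParseError, ValidationError

LIFESTYLES = ("virulent", "temperate", "prophage")

_SEQ_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class CdsRecord:
    """One protein-coding sequence: the per-gene unit of analysis."""

    gene_id: str
    genome_id: str
    sequence: str
    lifestyle: str | None = None
    product: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"gene {self.gene_id!r}: empty sequence")
        bad = set(self.sequence) - _SEQ_CHARS
        if bad:
            raise ValidationError(
                f"gene {self.gene_id!r}: characters outside A/C/G/T/N: {sorted(bad)}"
            )
        if self.lifestyle is not None and self.lifestyle not in LIFESTYLES:
            raise ValidationError(
                f"gene {self.gene_id!r}: unknown lifestyle {self.lifestyle!r}; "
                f"expected one of {LIFESTYLES}"
            )


@dataclass(frozen=True)
class CodonUsageTable:
    """64-codon reference usage table (the source of CAI weights).

    ``entries`` maps each DNA codon to ``(frequency_per_1000, count)``;
    ``total_codons`` is the number of codons the table was built from.
    """

    entries: dict[str, tuple[float, int]]
    total_codons: int
    genetic_code: dict[str, str] = field(default_factory=lambda: dict(GENETIC_CODE))

    def __post_init__(self) -> None:
        missing = [c for c in CODONS if c not in self.entries]
        if missing:
            raise ValidationError(f"codon usage table missing codons: {missing}")
        extra = set(self.entries) - set(CODONS)
        if extra:
            raise ValidationError(f"codon usage table has unknown codons: {sorted(extra)}")
        if self.total_codons <= 0:
            raise ValidationError("total_codons must be positive")
        for codon, (freq, count) in self.entries.items():
            if freq < 0 or count < 0:
                raise ValidationError(f"codon {codon}: negative frequency or count")
            expected = 1000.0 * count / self.total_codons
            if abs(expected - freq) > 0.05:
                raise ValidationError(
                    f"codon {codon}: frequency {freq} inconsistent with count "
                    f"{count}/{self.total_codons} (expected ~{expected:.3f})"
                )
        counted = sum(c for _, c in self.entries.values())
        if counted and counted != self.total_codons:
            raise ValidationError(
                f"counts sum to {counted}, not total_codons={self.total_codons}"
            )

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "CodonUsageTable":
        total = sum(counts.values())
        entries = {c: (1000.0 * n / total, n) for c, n in counts.items()}
        return cls(entries=entries, total_codons=total)

    def count(self, codon: str) -> int:
        return self.entries[codon][1]


@dataclass(frozen=True)
class DirectionalHit:
    """One directional whole-genome comparison (query → subject)."""

    query_id: str
    subject_id: str
    pid: float
    pcov: float

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValidationError(f"self-hit: {self.query_id}")
        for name, v in (("pid", self.pid), ("pcov", self.pcov)):
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"{self.query_id}->{self.subject_id}: {name}={v} outside [0, 100]"
                )


@dataclass(frozen=True)
class AnnotationRow:
    """Join row linking a gene to its genome, lifestyle and product."""

    gene_id: str
    genome_id: str
    lifestyle: str
    product: str = ""
    trna_count: int | None = None
    genome_size_bp: int | None = None

    def __post_init__(self) -> None:
        if self.lifestyle not in LIFESTYLES:
            raise ValidationError(
                f"gene {self.gene_id!r}: unknown lifestyle {self.lifestyle!r}; "
                f"expected one of {LIFESTYLES}"
            )
        if self.trna_count is not None and self.trna_count < 0:
            raise ValidationError(f"gene {self.gene_id!r}: negative trna_count")
        if self.genome_size_bp is not None and self.genome_size_bp <= 0:
            raise ValidationError(f"gene {self.gene_id!r}: non-positive genome_size_bp")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta_cds(path: str | Path) -> list[CdsRecord]:
    """Read CDS records from a FASTA file.

    The header token before the first whitespace becomes ``gene_id``; the
    remainder of the header (if any) is retained as ``product``. Sequences are
    uppercased. Duplicate gene ids and empty files are errors.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first:
            raise ParseError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise ParseError(f"{path}: line 1 does not start with '>'")
    records: list[CdsRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        gene_id = entry.id
        if gene_id in seen:
            raise ValidationError(f"{path}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        desc = entry.description[len(entry.id):].strip()
        records.append(
            CdsRecord(
                gene_id=gene_id,
                genome_id="",
                sequence=str(entry.seq).upper(),
                product=desc or None,
            )
        )
    if not records:
        raise ParseError(f"{path}: no FASTA entries")
    return records


def write_fasta_cds(records: Iterable[CdsRecord], path: str | Path) -> None:
    """Write CDS records as FASTA (inverse of :func:`read_fasta_cds`)."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description=r.product or "")
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


# ---------------------------------------------------------------------------
# Codon usage tables

_KAZUSA_BLOCK = re.compile(r"([ACGTUacgtu]{3})\s+(\d+(?:\.\d+)?)\s*\(\s*(\d+(?:\.\d+)?)\s*\)")


def read_codon_usage_table(path: str | Path, dialect: str = "kazusa") -> CodonUsageTable:
    """Read a 64-codon reference usage table.

    ``kazusa``: whitespace-separated ``CODON freq (count)`` blocks, any layout,
    RNA (U) or DNA (T) alphabet — U is normalised to T internally.
    ``tsv``: header + 3 columns ``codon, freq_per_1000, count``.
    """
    path = Path(path)
    entries: dict[str, tuple[float, int]] = {}
    if dialect == "kazusa":
        text = path.read_text()
        for m in _KAZUSA_BLOCK.finditer(text):
            codon = m.group(1).upper().replace("U", "T")
            entries[codon] = (float(m.group(2)), int(float(m.group(3))))
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"codon", "freq_per_1000", "count"}
        if not required <= set(df.columns):
            raise ParseError(f"{path}: expected columns {sorted(required)}")
        for _, row in df.iterrows():
            codon = str(row["codon"]).upper().replace("U", "T")
            entries[codon] = (float(row["freq_per_1000"]), int(row["count"]))
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'kazusa' or 'tsv'")
    missing = [c for c in CODONS if c not in entries]
    if missing:
        raise ValidationError(f"{path}: missing codons: {missing}")
    total = sum(c for _, c in entries.values())
    return CodonUsageTable(entries=entries, total_codons=total)


def write_codon_usage_table(table: CodonUsageTable, path: str | Path) -> None:
    """Write a usage table in the 3-column TSV dialect."""
    rows = [
        {"codon": c, "freq_per_1000": table.entries[c][0], "count": table.entries[c][1]}
        for c in CODONS
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Similarity hits

def read_directional_hits(
    path: str | Path,
    query_col: str = "qseqid",
    subject_col: str = "sseqid",
    pid_col: str = "pident",
    cov_col: str = "qcovs",
) -> list[DirectionalHit]:
    """Read BLAST-style tabular hits (TSV with a header row).

    Which column carries query coverage varies between BLAST invocations, so
    the column names are parameters rather than guesses. Self-hits are
    dropped; out-of-range identities/coverages raise with the row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {query_col, subject_col, pid_col, cov_col}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, found {list(df.columns)}")
    hits: list[DirectionalHit] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        q = str(getattr(row, query_col))
        s = str(getattr(row, subject_col))
        if q == s:
            continue
        pid = float(getattr(row, pid_col))
        pcov = float(getattr(row, cov_col))
        try:
            hits.append(DirectionalHit(q, s, pid, pcov))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return hits


def write_directional_hits(hits: Iterable[DirectionalHit], path: str | Path) -> None:
    rows = [
        {"qseqid": h.query_id, "sseqid": h.subject_id, "pident": h.pid, "qcovs": h.pcov}
        for h in hits
    ]
    pd.DataFrame(rows, columns=["qseqid", "sseqid", "pident", "qcovs"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Annotation tables

_ANNOT_COLS = ["gene_id", "genome_id", "lifestyle", "product", "trna_count", "genome_size_bp"]


def read_annotation_table(path: str | Path) -> list[AnnotationRow]:
    """Read the gene annotation TSV (inverse of :func:`write_annotation_table`)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "genome_id": str})
    required = {"gene_id", "genome_id", "lifestyle"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: expected at least columns {sorted(required)}")
    rows: list[AnnotationRow] = []
    for rec in df.to_dict("records"):
        lifestyle = str(rec["lifestyle"])
        if lifestyle not in LIFESTYLES:
            raise ValidationError(
                f"{path}: gene {rec['gene_id']!r}: unknown lifestyle {lifestyle!r}; "
                f"expected one of {LIFESTYLES}"
            )
        product = rec.get("product", "")
        trna = rec.get("trna_count")
        size = rec.get("genome_size_bp")
        rows.append(
            AnnotationRow(
                gene_id=str(rec["gene_id"]),
                genome_id=str(rec["genome_id"]),
                lifestyle=lifestyle,
                product="" if product is None or pd.isna(product) else str(product),
                trna_count=None if trna is None or pd.isna(trna) else int(trna),
                genome_size_bp=None if size is None or pd.isna(size) else int(size),
            )
        )
    return rows


def write_annotation_table(rows: Iterable[AnnotationRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "genome_id": r.genome_id,
                "lifestyle": r.lifestyle,
                "product": r.product,
                "trna_count": r.trna_count,
                "genome_size_bp": r.genome_size_bp,
            }
            for r in rows
        ],
        columns=_ANNOT_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


# alias used by the pipeline for generic tidy output
def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any tidy result table as TSV with a header."""
    df.to_csv(path, sep="\t", index=False)


def annotation_frame(rows: Sequence[AnnotationRow]) -> pd.DataFrame:
    """Annotation rows as a DataFrame (column order fixed)."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "genome_id": r.genome_id,
                "lifestyle": r.lifestyle,
                "product": r.product,
                "trna_count": r.trna_count,
                "genome_size_bp": r.genome_size_bp,
            }
            for r in rows
        ],
        columns=_ANNOT_COLS,
    )
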