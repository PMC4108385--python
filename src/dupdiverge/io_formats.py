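"""Readers and writers for the external formats the pipeline consumes.

All genomic coordinates are 1-based inclusive (the GFF3 convention) and every
consumer of this module sees that convention regardless of the source dialect.
Dialects fixed here:

* FASTA — protein or CDS; record id is the first whitespace-delimited token
  of the header.
* Gene-model TSV — one gene per line, columns
  ``gene_id  chromosome  strand  biotype  lineage_specific  exons`` where
  ``exons`` is a comma-separated list of ``start-end`` spans sorted by
  genomic start and ``lineage_specific`` is ``1``/``0``.
* GFF3 — ``gene``/``mRNA``/``CDS`` features; a gene with several transcripts
  is collapsed to the transcript with the longest summed CDS.
* Alignment table — BLAST tabular "outfmt 6" (qseqid sseqid pident length
  mismatch gapopen qstart qend sstart send evalue bitscore); percent identity
  is on the 0–100 scale in the file and rescaled to [0, 1] in memory.
* Expression matrix — TSV with header ``gene_id<TAB>tissue1<TAB>...`` and
  one FPKM row per gene.
* Lineage table — TSV ``gene_id  lineage_specific`` with a ``1``/``0`` flag
  (1 = no homolog recorded outside the focal species).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GeneModel",
    "SequenceRecord",
    "AlignmentHit",
    "ExpressionMatrix",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models_tsv",
    "read_alignment_table",
    "write_alignment_table",
    "read_expression_matrix",
    "read_lineage_table",
    "write_lineage_table",
    "apply_lineage_flags",
]

STOP_AA = "*"
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
_DNA_ALPHABET = set("ACGTN")
_STOP_CODONS = {"TAA", "TAG", "TGA"}


class FormatError(ValueError):
    """A file violated the dialect or validation rules documented here."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's location, coding-exon layout, biotype and lineage flag.

    ``coding_exons`` are (start, end) spans in genomic coordinates, 1-based
    inclusive, sorted by genomic start and non-overlapping.
    ``lineage_specific`` is True when no homolog of the gene is recorded
    outside the focal species.
    """

    gene_id: str
    chromosome: str
    strand: str
    coding_exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"
    lineage_specific: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.coding_exons)
        if len(exons) < 1:
            raise FormatError(f"{self.gene_id}: gene model needs at least one coding exon")
        for s, e in exons:
            if s > e or s < 1:
                raise FormatError(f"{self.gene_id}: malformed exon span ({s}, {e})")
        if list(exons) != sorted(exons, key=lambda x: x[0]):
            raise FormatError(f"{self.gene_id}: exons must be sorted by genomic start")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise FormatError(f"{self.gene_id}: overlapping exons ({s1},{e1}) and ({s2},{e2})")
        object.__setattr__(self, "coding_exons", exons)

    @property
    def n_exons(self) -> int:
        return len(self.coding_exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        """Exon lengths in genomic order (end − start + 1)."""
        return tuple(e - s + 1 for s, e in self.coding_exons)

    @property
    def exon_lengths_5to3(self) -> tuple[int, ...]:
        """Exon lengths in transcription order (reversed on the minus strand)."""
        lens = self.exon_lengths
        return lens if self.strand == "+" else lens[::-1]

    @property
    def is_pseudogene(self) -> bool:
        return "pseudogene" in self.biotype


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record, either a protein or a coding sequence (CDS)."""

    id: str
    kind: str  # "protein" | "cds"
    residues: str

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise FormatError(f"{self.id}: empty sequence")
        if self.kind == "protein":
            bad = set(residues) - _PROTEIN_ALPHABET
            if bad:
                raise FormatError(f"{self.id}: non-amino-acid characters {sorted(bad)}")
            if STOP_AA in residues[:-1]:
                raise FormatError(f"{self.id}: internal stop in protein sequence")
        elif self.kind == "cds":
            bad = set(residues) - _DNA_ALPHABET
            if bad:
                raise FormatError(f"{self.id}: non-nucleotide characters {sorted(bad)}")
            if len(self.coding) % 3 != 0:
                raise FormatError(
                    f"{self.id}: CDS length {len(residues)} not divisible by 3 "
                    "after terminal-stop trimming"
                )
        else:
            raise FormatError(f"{self.id}: unknown sequence kind {self.kind!r}")

    @property
    def coding(self) -> str:
        """CDS with one terminal stop codon trimmed, if present."""
        if self.kind != "cds":
            raise ValueError("coding is only defined for CDS records")
        r = self.residues
        if len(r) >= 3 and len(r) % 3 == 0 and r[-3:] in _STOP_CODONS:
            return r[:-3]
        return r

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise protein hit; identity is a fraction in [0, 1]."""

    query_id: str
    subject_id: str
    percent_identity: float
    aligned_length: int
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 1.0:
            raise FormatError(
                f"{self.query_id}/{self.subject_id}: identity {self.percent_identity} "
                "outside [0, 1]"
            )
        if self.aligned_length < 1:
            raise FormatError(f"{self.query_id}/{self.subject_id}: aligned_length < 1")


class ExpressionMatrix:
    """Gene × tissue grid of FPKM values (non-negative), backed by a DataFrame."""

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids in expression matrix: {dupes}")
        if data.columns.duplicated().any():
            raise FormatError("duplicate tissue names in expression matrix")
        if data.isna().any().any():
            raise FormatError("missing cells in expression matrix")
        if (data.values < 0).any():
            raise FormatError("negative FPKM values in expression matrix")
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissue_names(self) -> list[str]:
        return list(self.data.columns)

    def fpkm(self, gene_id: str) -> pd.Series:
        if gene_id not in self.data.index:
            raise KeyError(f"gene {gene_id!r} not in expression matrix")
        return self.data.loc[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.data.index

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, kind: str) -> list[SequenceRecord]:
    """Read a protein or CDS FASTA into validated records.

    Record ids are the first whitespace-delimited token of each header.
    Duplicate ids and empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, kind=kind, residues=str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models

_TSV_COLUMNS = ["gene_id", "chromosome", "strand", "biotype", "lineage_specific", "exons"]


def read_gene_models(path: str | Path, format: str = "tsv") -> list[GeneModel]:
    """Read gene models from GFF3 or the in-repo TSV dialect.

    Genes with zero CDS features are skipped with a warning. Multi-transcript
    genes are collapsed to the transcript with the longest summed CDS.
    """
    if format == "tsv":
        return _read_gene_models_tsv(path)
    if format == "gff3":
        return _read_gene_models_gff3(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _parse_exons_field(gene_id: str, text: str) -> tuple[tuple[int, int], ...]:
    spans = []
    for token in text.split(","):
        try:
            s, e = token.split("-")
            spans.append((int(s), int(e)))
        except ValueError as exc:
            raise FormatError(f"{gene_id}: malformed exon span {token!r}") from exc
    return tuple(spans)


def _read_gene_models_tsv(path: str | Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise FormatError(f"gene-model TSV header must be {_TSV_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_TSV_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(_TSV_COLUMNS)} columns")
            gene_id, chrom, strand, biotype, lineage, exons = fields
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    chromosome=chrom,
                    strand=strand,
                    coding_exons=_parse_exons_field(gene_id, exons),
                    biotype=biotype,
                    lineage_specific=lineage == "1",
                )
            )
    return models


def write_gene_models_tsv(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for m in models:
            exons = ",".join(f"{s}-{e}" for s, e in m.coding_exons)
            fh.write(
                "\t".join(
                    [
                        m.gene_id,
                        m.chromosome,
                        m.strand,
                        m.biotype,
                        "1" if m.lineage_specific else "0",
                        exons,
                    ]
                )
                + "\n"
            )


def _read_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    models = []
    for gene in db.features_of_type("gene"):
        biotype = (gene.attributes.get("biotype") or gene.attributes.get("gene_biotype") or ["protein_coding"])[0]
        best_spans: list[tuple[int, int]] | None = None
        best_len = -1
        transcripts = list(db.children(gene, featuretype="mRNA")) or [gene]
        for tx in transcripts:
            spans = sorted((c.start, c.end) for c in db.children(tx, featuretype="CDS"))
            if not spans:
                continue
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise FormatError(
                        f"{gene.id}: overlapping CDS features ({s1},{e1}) and ({s2},{e2}) "
                        f"in transcript {tx.id}"
                    )
            total = sum(e - s + 1 for s, e in spans)
            if total > best_len:
                best_len, best_spans = total, spans
        if best_spans is None:
            warnings.warn(f"gene {gene.id} has no CDS features; skipped", stacklevel=2)
            continue
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                coding_exons=tuple(best_spans),
                biotype=biotype,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Alignment table (BLAST outfmt 6 dialect)

def read_alignment_table(path: str | Path) -> list[AlignmentHit]:
    """Read a 12-column tab-separated hit table; self-hits are dropped."""
    hits = []
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            q, s = fields[0], fields[1]
            try:
                pident = float(fields[2])
                length = int(fields[3])
                bits = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            if q == s:
                n_self += 1
                continue
            hits.append(
                AlignmentHit(
                    query_id=q,
                    subject_id=s,
                    percent_identity=pident / 100.0,
                    aligned_length=length,
                    bit_score=bits,
                )
            )
    if not hits and n_self:
        warnings.warn(f"{path}: only self-hits present; no usable alignments", stacklevel=2)
    return hits


def write_alignment_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column dialect (unused columns zero-filled)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity * 100.0:.2f}",
                        str(h.aligned_length),
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                        "0.0",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Expression matrix and lineage table

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene_id":
        raise FormatError(f"expression matrix first column must be 'gene_id', got {df.index.name!r}")
    return ExpressionMatrix(df)


def read_lineage_table(path: str | Path) -> dict[str, bool]:
    flags: dict[str, bool] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "lineage_specific"]:
            raise FormatError("lineage table header must be 'gene_id\\tlineage_specific'")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene_id, flag = line.split("\t")
            flags[gene_id] = flag == "1"
    return flags


def write_lineage_table(flags: dict[str, bool], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlineage_specific\n")
        for gene_id, flag in flags.items():
            fh.write(f"{gene_id}\t{'1' if flag else '0'}\n")


def apply_lineage_flags(models: Sequence[GeneModel], flags: dict[str, bool]) -> list[GeneModel]:
    """Return copies of the gene models with lineage flags from a lineage table."""
    from dataclasses import replace

    return [replace(m, lineage_specific=flags.get(m.gene_id, m.lineage_specific)) for m in models]
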