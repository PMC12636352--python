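"""Readers/writers for the formats the pipeline touches, plus promoter geometry.

Internal coordinate convention is BED-style 0-based half-open everywhere.
GFF3 input (1-based inclusive) is converted on read. Promoter FASTA headers
follow the ``pangene|accession|gene`` dialect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from ._encode import revcomp

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start in {self}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter allele: the upstream window of one gene copy.

    Sequences are oriented 5'->3' toward the TSS (minus-strand windows are
    reverse-complemented on extraction).
    """

    pangene_id: str
    accession_id: str
    gene_id: str
    sequence: str
    interval: GenomicInterval | None = None

    def __post_init__(self):
        if self.interval is not None and len(self.interval) != len(self.sequence):
            raise ValueError(
                f"{self.gene_id}: interval length {len(self.interval)} != "
                f"sequence length {len(self.sequence)}"
            )


class PromoterSet:
    """Ordered collection of promoter records, unique by gene_id."""

    def __init__(self, records: Iterable[PromoterRecord] = ()):
        self._records: list[PromoterRecord] = []
        self._by_gene: dict[str, int] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: PromoterRecord) -> None:
        if rec.gene_id in self._by_gene:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
        self._by_gene[rec.gene_id] = len(self._records)
        self._records.append(rec)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[PromoterRecord]:
        return iter(self._records)

    def __getitem__(self, gene_id: str) -> PromoterRecord:
        return self._records[self._by_gene[gene_id]]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_gene

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self._records]

    def pangene_ids(self) -> list[str]:
        return [r.pangene_id for r in self._records]

    def by_pangene(self) -> dict[str, list[PromoterRecord]]:
        out: dict[str, list[PromoterRecord]] = {}
        for rec in self._records:
            out.setdefault(rec.pangene_id, []).append(rec)
        return out

    def subset(self, gene_ids: Iterable[str]) -> "PromoterSet":
        return PromoterSet(self[g] for g in gene_ids)

    def sorted_by_gene(self) -> "PromoterSet":
        return PromoterSet(sorted(self._records, key=lambda r: r.gene_id))


@dataclass
class ExpressionTable:
    """gene_id -> expression on the log2(TPM+1) scale."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for g, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite expression for {g}")

    def __getitem__(self, gene_id: str) -> float:
        return self.values[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values

    def __len__(self) -> int:
        return len(self.values)

    def vector(self, gene_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.values[g] for g in gene_ids], dtype=float)


# ---------------------------------------------------------------------------
# promoter geometry


def make_promoter_bed(annotation: pd.DataFrame, window_bp: int = 2000,
                      contig_lengths: dict[str, int] | None = None) -> list[GenomicInterval]:
    """Upstream window of each gene, in transcription orientation.

    ``annotation`` needs columns gene_id, contig, start, end (1-based inclusive,
    GFF3 convention) and strand. The TSS is the gene start on + and the gene
    end on -. Windows are truncated at coordinate 0; on the minus strand,
    truncation at the contig end requires ``contig_lengths``.
    """
    out = []
    for row in annotation.itertuples(index=False):
        strand = row.strand
        if strand not in ("+", "-"):
            raise ValueError(f"gene {row.gene_id}: unknown strand {strand!r}")
        if strand == "+":
            tss0 = int(row.start) - 1          # 0-based TSS position
            start = max(0, tss0 - window_bp)
            end = tss0
        else:
            tss0 = int(row.end)                # half-open end == 0-based pos after gene
            start = tss0
            end = tss0 + window_bp
            if contig_lengths is not None:
                if row.contig not in contig_lengths:
                    raise ValueError(f"no contig length for {row.contig}")
                end = min(end, contig_lengths[row.contig])
        if end <= start:
            warnings.warn(f"gene {row.gene_id}: empty promoter window, skipped")
            continue
        out.append(GenomicInterval(str(row.contig), start, end, strand))
    return out


def extract_promoters(genome, intervals: Iterable[GenomicInterval],
                      id_map: Iterable[tuple[str, str, str]]) -> PromoterSet:
    """Pull promoter sequences out of a genome.

    ``genome`` is a mapping contig -> sequence string (e.g. a dict or a
    ``pyfaidx.Fasta`` handle; values are str()-able). ``id_map`` yields
    (pangene_id, accession_id, gene_id) aligned with ``intervals``.
    Minus-strand sequences are reverse-complemented so every promoter reads
    5'->3' toward the TSS.
    """
    records = []
    for iv, (pangene, accession, gene) in zip(intervals, id_map, strict=True):
        contig_seq = str(genome[iv.contig][:])
        if iv.end > len(contig_seq):
            raise ValueError(
                f"interval {iv.contig}:{iv.start}-{iv.end} beyond contig end "
                f"({len(contig_seq)})"
            )
        seq = contig_seq[iv.start:iv.end]
        if iv.strand == "-":
            seq = revcomp(seq)
        records.append(PromoterRecord(pangene, accession, gene, seq.upper(), iv))
    return PromoterSet(records)


# ---------------------------------------------------------------------------
# FASTA / TSV / BED io


def read_promoter_fasta(path: str | Path) -> PromoterSet:
    """Read a promoter FASTA with ``>pangene|accession|gene`` headers."""
    records = []
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(_fasta_record(header, "".join(chunks)))
                header = (line[1:], lineno)
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}:{lineno}: sequence before header")
                chunks.append(line.strip())
        if header is not None:
            records.append(_fasta_record(header, "".join(chunks)))
    return PromoterSet(records)


def _fasta_record(header: tuple[str, int], seq: str) -> PromoterRecord:
    text, lineno = header
    parts = text.split()[0].split("|")
    if len(parts) != 3:
        raise ValueError(
            f"line {lineno}: header {text!r} does not follow 'pangene|accession|gene'"
        )
    return PromoterRecord(parts[0], parts[1], parts[2], seq.upper())


def write_promoter_fasta(promoters: PromoterSet, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in promoters:
            fh.write(f">{rec.pangene_id}|{rec.accession_id}|{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_expression(path: str | Path, transform: str = "raw_tpm") -> ExpressionTable:
    """Read a two-column TSV (gene_id, value).

    ``transform='raw_tpm'`` applies log2(TPM+1); ``'none'`` takes values as-is.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need gene_id and value columns")
    genes = df.iloc[:, 0].astype(str)
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if vals.isna().any():
        bad = genes[vals.isna()].iloc[0]
        raise ValueError(f"{path}: non-numeric expression for {bad}")
    if genes.duplicated().any():
        raise ValueError(f"{path}: duplicate gene_id {genes[genes.duplicated()].iloc[0]}")
    if transform == "raw_tpm":
        if (vals < 0).any():
            raise ValueError(f"{path}: negative TPM")
        vals = np.log2(vals + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    return ExpressionTable(dict(zip(genes, vals.astype(float))))


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\texpression\n")
        for g in sorted(table.values):
            fh.write(f"{g}\t{table.values[g]:.6g}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3+ reader; columns beyond 6 are ignored."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            out.append(GenomicInterval(parts[0], start, end, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Iterable[str] | None = None) -> None:
    with open(path, "w") as fh:
        names = list(names) if names is not None else None
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_membership(path: str | Path) -> pd.DataFrame:
    """Pangene membership TSV with columns pangene_id, gene_id, accession_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"pangene_id", "gene_id", "accession_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_gff_genes(path: str | Path) -> pd.DataFrame:
    """Gene records from a GFF3 as a DataFrame (coordinates left 1-based
    inclusive; conversion happens in make_promoter_bed)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("gene_id", ""))
            rows.append((gene_id, f[0], int(f[3]), int(f[4]), f[6]))
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])
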