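"""Readers/writers for the standard formats the pipeline touches.

All genomic coordinates are normalized to a single internal convention:
0-based, half-open ``[start, end)``.  GTF (1-based, closed) is converted
at the boundary.  Sequences are upper-cased with U mapped to T; N bases
are retained and downstream stages define their own N handling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


VALID_STRANDS = {"+", "-", "."}
_SEQ_ALPHABET = frozenset("ACGTN")
_SEQ_TRANSLATE = str.maketrans("acgtunU", "ACGTTNT")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene with its span and exon structure (internal coordinates)."""

    gene_id: str
    chrom: str
    strand: str
    span: GenomicInterval
    biotype: str = ""
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        prev_end = None
        for exon in self.exons:
            if exon.start < self.span.start or exon.end > self.span.end:
                raise ValueError(
                    f"exon [{exon.start}, {exon.end}) outside gene span "
                    f"[{self.span.start}, {self.span.end}) for {self.gene_id}"
                )
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"exons overlap or unsorted in {self.gene_id}")
            prev_end = exon.end

    @property
    def tss(self) -> int:
        """Transcription start site position (strand-aware, 0-based)."""
        return self.span.start if self.strand == "+" else self.span.end - 1


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence over {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(self.seq) - _SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    @classmethod
    def from_raw(cls, ident: str, raw: str) -> "SequenceRecord":
        """Normalize a raw sequence string (case, U->T) and validate."""
        return cls(ident, raw.translate(_SEQ_TRANSLATE))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ExpressionMatrix:
    """A dense feature x sample expression grid."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "log2"  # {"raw", "log2"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.scale not in {"raw", "log2"}:
            raise ValueError(f"scale must be raw or log2, got {self.scale!r}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing entries")
        if self.scale == "raw" and (self.values < 0).any():
            raise ValueError("negative values in raw-scale expression matrix")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in feature_ids]
        return ExpressionMatrix(list(feature_ids), list(self.sample_ids),
                                self.values[rows], self.scale)


@dataclass
class ClinicalTable:
    """Per-sample survival records with optional subtype and covariates."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    subtype: list[str] | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("clinical columns misaligned")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids in clinical table")
        if (self.time <= 0).any():
            bad = self.sample_ids[int(np.argmax(self.time <= 0))]
            raise ValueError(f"non-positive survival time for sample {bad!r}")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event must be 0 or 1")
        if self.subtype is not None and len(self.subtype) != n:
            raise ValueError("subtype column misaligned")

    def __len__(self) -> int:
        return len(self.sample_ids)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into intervals (coordinates verbatim).

    Track/browser/comment lines are skipped; missing name columns get
    auto-generated ``bed_<lineno>`` names.  Errors name the offending line.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: fewer than 3 columns at line {lineno}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-integer coordinates at line {lineno}"
                ) from exc
            if start >= end:
                raise FormatError(f"{path}: start >= end at line {lineno}")
            if start < 0:
                raise FormatError(f"{path}: negative start at line {lineno}")
            name = fields[3] if len(fields) > 3 and fields[3] else f"bed_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
            if name in seen:
                raise FormatError(f"{path}: duplicate interval name {name!r} at line {lineno}")
            seen.add(name)
            intervals.append(GenomicInterval(chrom, start, end, name, strand))
    if not intervals:
        raise FormatError(f"{path}: no intervals found (empty file?)")
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GTF (GFF2 dialect, gene_id / gene_biotype attributes)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str | Path, biotype_filter: str = "any") -> list[GeneModel]:
    """Read gene models from a GTF file.

    GTF 1-based closed coordinates are converted to internal 0-based
    half-open (start s -> s - 1).  Genes without exon lines receive a
    single exon equal to their span.  ``biotype_filter="any"`` disables
    biotype filtering.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}: fewer than 9 columns at line {lineno}")
            chrom, _, feature, start_s, end_s, _, strand, _, attr_s = fields[:9]
            if feature not in {"gene", "exon", "transcript"}:
                continue
            try:
                start, end = int(start_s) - 1, int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer coordinates at line {lineno}") from exc
            attrs = _parse_attributes(attr_s)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise FormatError(f"{path}: missing gene_id attribute at line {lineno}")
            rec = genes.setdefault(gene_id, {"span": None, "exons": [], "chrom": chrom,
                                             "strand": strand, "biotype": ""})
            if feature == "gene":
                rec["span"] = (start, end)
                rec["chrom"] = chrom
                rec["strand"] = strand
                rec["biotype"] = attrs.get("gene_biotype", attrs.get("gene_type", ""))
                if gene_id not in order:
                    order.append(gene_id)
            elif feature == "exon":
                rec["exons"].append((start, end))
                if gene_id not in order:
                    order.append(gene_id)

    models: list[GeneModel] = []
    for gene_id in order:
        rec = genes[gene_id]
        if rec["span"] is None:
            if not rec["exons"]:
                continue
            rec["span"] = (min(s for s, _ in rec["exons"]),
                           max(e for _, e in rec["exons"]))
        span_start, span_end = rec["span"]
        span = GenomicInterval(rec["chrom"], span_start, span_end, gene_id, rec["strand"])
        exons = sorted(rec["exons"])
        for es, ee in exons:
            if es < span_start or ee > span_end:
                raise FormatError(
                    f"{path}: exon [{es}, {ee}) outside gene span for {gene_id}"
                )
        if not exons:
            exons = [(span_start, span_end)]
        exon_ivs = tuple(
            GenomicInterval(rec["chrom"], es, ee, f"{gene_id}_exon{i}", rec["strand"])
            for i, (es, ee) in enumerate(exons, start=1)
        )
        model = GeneModel(gene_id, rec["chrom"], rec["strand"], span,
                          rec["biotype"], exon_ivs)
        if biotype_filter != "any" and model.biotype != biotype_filter:
            continue
        models.append(model)
    return models


def write_gtf(models: Iterable[GeneModel], path: str | Path,
              source: str = "selnc") -> None:
    """Write gene models to GTF (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        for gm in models:
            attrs = f'gene_id "{gm.gene_id}"; gene_biotype "{gm.biotype}";'
            fh.write(
                f"{gm.chrom}\t{source}\tgene\t{gm.span.start + 1}\t{gm.span.end}\t.\t"
                f"{gm.strand}\t.\t{attrs}\n"
            )
            for exon in gm.exons:
                fh.write(
                    f"{gm.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{gm.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord.from_raw(rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Expression matrix TSV (features in rows, samples in columns)
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate feature ids")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing entries (ragged rows?)")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression values") from exc
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                            values, scale)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "feature"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Clinical TSV: sample \t time \t event [\t subtype [\t covariates...]]
# ---------------------------------------------------------------------------

def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: clinical header must contain {sorted(required)}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing entries in clinical table")
    subtype = df["subtype"].astype(str).tolist() if "subtype" in df.columns else None
    extra = [c for c in df.columns if c not in {"sample", "time", "event", "subtype"}]
    covariates = df[extra].astype(float) if extra else None
    if covariates is not None:
        covariates.index = df["sample"].astype(str)
    return ClinicalTable(
        sample_ids=df["sample"].astype(str).tolist(),
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=int),
        subtype=subtype,
        covariates=covariates,
    )


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    data = {"sample": table.sample_ids, "time": table.time, "event": table.event}
    if table.subtype is not None:
        data["subtype"] = table.subtype
    df = pd.DataFrame(data)
    if table.covariates is not None:
        for col in table.covariates.columns:
            df[col] = table.covariates[col].to_numpy()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
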