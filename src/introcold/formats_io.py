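"""Readers and writers for the external formats the pipeline touches.

Everything tabular is UTF-8, tab-delimited, with a deterministic column
order so that identical analyses produce byte-identical files.  Internal
genomic coordinates are 0-based half-open (the BED convention); an import
flag accepts 1-based fully-closed tables such as marker-interval lists.

The three in-memory containers defined here — :class:`SampleDescriptor`,
:class:`ExpressionMatrix` and :class:`GenomicInterval` — are shared by every
downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOTYPES = ("recurrent", "introgression")
CONDITIONS = ("control", "cold")
#: default cold-stress sampling times in hours; the pooled control is time 0
COLD_TIMEPOINTS = (2, 6, 12, 24, 48)

VALID_BASES = frozenset("ACGTN")

INTERVAL_KINDS = ("gene", "segment", "qtl")


class FormatError(ValueError):
    """Raised when an external file violates its format contract."""


def make_sample_id(genotype: str, condition: str, time_h: int, replicate: int) -> str:
    return f"{genotype}_{condition}_{time_h}h_r{replicate}"


@dataclass(frozen=True, order=True)
class SampleDescriptor:
    """One array/sample in the two-genotype time-course design.

    The pooled control (samples collected under control conditions and
    pooled across collection times) is represented as ``condition='control',
    time_h=0``; cold samples carry their stress duration in hours.
    """

    sample_id: str
    genotype: str
    condition: str
    time_h: int
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise FormatError(f"unknown genotype {self.genotype!r} for sample {self.sample_id!r}")
        if self.condition not in CONDITIONS:
            raise FormatError(f"unknown condition {self.condition!r} for sample {self.sample_id!r}")
        if (self.condition == "control") != (self.time_h == 0):
            raise FormatError(
                f"sample {self.sample_id!r}: condition=control iff time_h=0 "
                f"(got condition={self.condition!r}, time_h={self.time_h})"
            )
        if self.condition == "cold" and self.time_h <= 0:
            raise FormatError(f"sample {self.sample_id!r}: cold sample needs time_h > 0")
        if self.replicate < 1:
            raise FormatError(f"sample {self.sample_id!r}: replicate must be >= 1")


@dataclass
class ExpressionMatrix:
    """A genes x samples intensity matrix plus its sample design.

    ``values`` is a DataFrame indexed by gene id with one column per
    sample id, in design order.  ``scale`` records whether the values are
    linear intensities or a log2 view derived from them.
    """

    values: pd.DataFrame
    samples: tuple[SampleDescriptor, ...]
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        if self.scale not in ("linear", "log2"):
            raise FormatError(f"unknown scale {self.scale!r}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample ids in design")
        keys = [(s.genotype, s.condition, s.time_h, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (genotype, condition, time, replicate) in design")
        if list(self.values.columns) != ids:
            raise FormatError("matrix columns do not match design sample ids (order included)")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.values.isna().any().any():
            raise FormatError("matrix contains missing values")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise FormatError("linear-scale matrix contains negative intensities")

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def descriptor(self, sample_id: str) -> SampleDescriptor:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def select(
        self,
        genotype: str | None = None,
        condition: str | None = None,
        time_h: int | None = None,
        replicate: int | None = None,
    ) -> list[str]:
        """Sample ids matching the given design coordinates (None = any)."""
        out = []
        for s in self.samples:
            if genotype is not None and s.genotype != genotype:
                continue
            if condition is not None and s.condition != condition:
                continue
            if time_h is not None and s.time_h != time_h:
                continue
            if replicate is not None and s.replicate != replicate:
                continue
            out.append(s.sample_id)
        return out

    def timepoints(self) -> list[int]:
        return sorted({s.time_h for s in self.samples if s.condition == "cold"})

    def log2_view(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """log2(value + pseudocount) view of a linear matrix."""
        if self.scale != "linear":
            raise FormatError("log2_view requires a linear-scale matrix")
        if pseudocount == 0 and (self.values.to_numpy() <= 0).any():
            raise FormatError("non-positive intensities with pseudocount 0")
        return ExpressionMatrix(np.log2(self.values + pseudocount), self.samples, scale="log2")

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[genes], self.samples, scale=self.scale)


# ----------------------------------------------------------------------
# expression matrix + design TSV

DESIGN_COLUMNS = ["sample_id", "genotype", "condition", "time_h", "replicate"]


def write_design(samples: Sequence[SampleDescriptor], path: str | Path) -> None:
    rows = [
        (s.sample_id, s.genotype, s.condition, s.time_h, s.replicate) for s in samples
    ]
    pd.DataFrame(rows, columns=DESIGN_COLUMNS).to_csv(path, sep="\t", index=False)


def load_design(path: str | Path) -> tuple[SampleDescriptor, ...]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"design {path}: missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                SampleDescriptor(
                    sample_id=row["sample_id"],
                    genotype=row["genotype"],
                    condition=row["condition"],
                    time_h=int(row["time_h"]),
                    replicate=int(row["replicate"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"design {path}, row {i + 2}: {exc}") from exc
    return tuple(out)


def write_expression(matrix: ExpressionMatrix, path: str | Path, design_path: str | Path | None = None) -> None:
    df = matrix.values.copy()
    df.insert(0, "gene_id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    if design_path is not None:
        write_design(matrix.samples, design_path)


def load_expression(path: str | Path, design_path: str | Path, scale: str = "linear") -> ExpressionMatrix:
    """Load a tab-separated expression matrix validated against its design.

    The first column holds gene ids; every remaining column must be
    described by one design row.  Non-numeric or missing cells are format
    errors that name the offending row and column.
    """
    samples = load_design(design_path)
    by_id = {s.sample_id: s for s in samples}
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected a gene-id column plus sample columns")
    gene_col = raw.columns[0]
    sample_cols = list(raw.columns[1:])
    for c in sample_cols:
        if c not in by_id:
            raise FormatError(f"{path}: sample column {c!r} missing from design {design_path}")
    genes = raw[gene_col].tolist()
    seen: set[str] = set()
    for i, g in enumerate(genes):
        if g in seen:
            raise FormatError(f"{path}, row {i + 2}: duplicate gene id {g!r}")
        seen.add(g)
    values = pd.DataFrame(index=pd.Index(genes, name="gene_id"), columns=sample_cols, dtype=float)
    for c in sample_cols:
        col = raw[c]
        converted = pd.to_numeric(col, errors="coerce")
        bad = converted.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}, row {i + 2}, column {c!r}: non-numeric cell {col.iloc[i]!r}"
            )
        values[c] = converted.to_numpy()
    ordered = [s for s in samples if s.sample_id in set(sample_cols)]
    values = values[[s.sample_id for s in ordered]]
    return ExpressionMatrix(values, tuple(ordered), scale=scale)


# ----------------------------------------------------------------------
# FASTA


def load_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an id -> uppercase-sequence mapping.

    Symbols outside A/C/G/T/N (after uppercasing) are rejected.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(f"{path}: record {rec.id!r} contains invalid symbols {sorted(bad)}")
        if rec.id in records:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = seq
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ----------------------------------------------------------------------
# BED intervals


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval tagged with its role in the analysis."""

    chrom: str
    start: int
    end: int
    name: str
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.kind not in INTERVAL_KINDS:
            raise FormatError(f"unknown interval kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"interval {self.name!r}: require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based fully-closed."""
    return start + 1, end


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based fully-closed -> 0-based half-open."""
    return start - 1, end


def load_bed(path: str | Path, kind: str, one_based: bool = False) -> list[GenomicInterval]:
    """Load a 4+ column BED file as intervals of the given kind.

    With ``one_based=True`` the coordinates are interpreted as 1-based
    fully-closed (marker-table style) and converted on the fly.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}, line {lineno}: expected >= 4 BED columns")
            chrom, s, e, name = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: non-integer coordinate") from exc
            if one_based:
                start, end = to_zero_based(start, end)
            try:
                out.append(GenomicInterval(chrom, start, end, name, kind))
            except FormatError as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


# ----------------------------------------------------------------------
# GMT gene-set maps


@dataclass(frozen=True)
class GeneSet:
    term: str
    description: str
    genes: tuple[str, ...]


def load_gmt(path: str | Path) -> dict[str, GeneSet]:
    """GMT file as an ordered term -> GeneSet mapping.

    Duplicate genes within one term are collapsed (first occurrence kept).
    """
    out: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}, line {lineno}: expected term, description, >= 1 gene")
            term, desc = fields[0], fields[1]
            if term in out:
                raise FormatError(f"{path}, line {lineno}: duplicate term {term!r}")
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            out[term] = GeneSet(term, desc, tuple(genes))
    return out


def write_gmt(sets: Mapping[str, GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, gs in sets.items():
            fh.write("\t".join([term, gs.description, *gs.genes]) + "\n")
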