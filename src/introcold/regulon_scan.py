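"""Promoter extraction, DRE core-motif scanning, and regulon assignment.

The DRE/CRT core motif (A/GCCGAC) is the binding element of DREB1/CBF
transcription factors.  The scanner reports every occurrence of GCCGAC or
ACCGAC on the forward strand of a promoter window and, in the default
both-strands mode, every occurrence of their reverse complements (GTCGGC,
GTCGGT) as minus-strand hits.  Overlapping occurrences are all reported.

A gene belongs to the DREB1 regulon when it is commonly cold-induced in
both genotypes *and* carries >= 1 DRE core motif in its promoter window
(-1000..-10 relative to the start codon).  Regulon members are further
annotated with their Pearson correlation to each DREB1 driver over the
concatenated per-genotype time-course of replicate-mean log2 values;
``r > 0.9`` (strict) defines co-expression, and a member co-expressed
with the designated specific driver but with neither of the other two is
flagged as driver-specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import ExpressionMatrix, GenomicInterval
from .sam_test import ContractError

DRE_WORDS = ("GCCGAC", "ACCGAC")
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

PROMOTER_UPSTREAM = 1000  # window start, bp upstream of the start codon
PROMOTER_OFFSET = 10  # window end, bp upstream of the start codon


def reverse_complement(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    sequence: str
    window_start: int  # relative coordinate, e.g. -1000
    window_end: int  # relative coordinate, e.g. -10 (inclusive)
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.sequence) > PROMOTER_UPSTREAM - PROMOTER_OFFSET + 1:
            raise ContractError("promoter window longer than -1000..-10")


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    offset: int  # 0-based within the promoter window
    strand: str  # '+' or '-'
    word: str  # the DRE word (forward-strand spelling)


def extract_promoter(
    gene: GenomicInterval, strand: str, chrom_seq: str
) -> PromoterRecord:
    """The -1000..-10 window upstream of the start codon, strand aware.

    For a plus-strand gene the start codon sits at ``gene.start``; for a
    minus-strand gene it sits at ``gene.end`` and the window is the
    reverse complement of the downstream-flanking sequence.  Windows are
    truncated at chromosome edges with a warning.
    """
    if strand not in ("+", "-"):
        raise ContractError(f"bad strand {strand!r}")
    L = len(chrom_seq)
    if gene.start >= L or gene.end > L:
        raise ContractError(f"gene {gene.name!r} lies off the chromosome (length {L})")
    if strand == "+":
        lo = gene.start - PROMOTER_UPSTREAM
        hi = gene.start - PROMOTER_OFFSET + 1
        trunc_lo = max(0, lo)
        seq = chrom_seq[trunc_lo:hi].upper()
        if trunc_lo > lo:
            warnings.warn(
                f"promoter of {gene.name} truncated at chromosome start "
                f"({hi - trunc_lo} of {hi - lo} nt)"
            )
    else:
        lo = gene.end + PROMOTER_OFFSET - 1
        hi = gene.end + PROMOTER_UPSTREAM
        trunc_hi = min(L, hi)
        seq = reverse_complement(chrom_seq[lo:trunc_hi].upper())
        if trunc_hi < hi:
            warnings.warn(
                f"promoter of {gene.name} truncated at chromosome end "
                f"({trunc_hi - lo} of {hi - lo} nt)"
            )
    if not seq:
        raise ContractError(f"gene {gene.name!r}: empty promoter window")
    return PromoterRecord(gene.name, seq, -PROMOTER_UPSTREAM, -PROMOTER_OFFSET, strand)


def scan_dre(promoter: PromoterRecord | tuple[str, str], both_strands: bool = True) -> list[MotifHit]:
    """All DRE core-motif occurrences in one promoter window.

    Accepts a :class:`PromoterRecord` or a ``(gene_id, sequence)`` pair.
    Minus-strand hits are occurrences of the reverse-complemented words in
    the given sequence, reported at their position in that sequence with
    the forward-strand spelling of the word.
    """
    if isinstance(promoter, PromoterRecord):
        gene_id, seq = promoter.gene_id, promoter.sequence
    else:
        gene_id, seq = promoter
    seq = seq.upper()
    hits: list[MotifHit] = []
    k = 6
    for off in range(len(seq) - k + 1):
        window = seq[off : off + k]
        for word in DRE_WORDS:
            if window == word:
                hits.append(MotifHit(gene_id, off, "+", word))
            elif both_strands and window == reverse_complement(word):
                hits.append(MotifHit(gene_id, off, "-", word))
    return hits


def scan_promoters(
    promoters: dict[str, str], both_strands: bool = True
) -> dict[str, list[MotifHit]]:
    return {g: scan_dre((g, seq), both_strands) for g, seq in promoters.items()}


def hits_table(hits: dict[str, list[MotifHit]]) -> pd.DataFrame:
    rows = [
        (h.gene_id, h.offset, h.strand, h.word)
        for gene in sorted(hits)
        for h in hits[gene]
    ]
    return pd.DataFrame(rows, columns=["gene_id", "offset", "strand", "word"])


# ----------------------------------------------------------------------
# regulon assignment


def coexpression_profile(
    matrix: ExpressionMatrix, gene: str, pseudocount: float = 1.0
) -> np.ndarray:
    """Concatenated genotype-wise time-course of replicate-mean log2 values
    (control, then each cold timepoint, recurrent then introgression)."""
    log2 = matrix.log2_view(pseudocount).values
    row = log2.loc[gene]
    out = []
    for genotype in ("recurrent", "introgression"):
        ctrl = matrix.select(genotype=genotype, condition="control")
        if not ctrl:
            continue  # genotype absent from this design
        out.append(row[ctrl].mean())
        for t in matrix.timepoints():
            ids = matrix.select(genotype=genotype, condition="cold", time_h=t)
            if ids:
                out.append(row[ids].mean())
    return np.asarray(out)


def assign_regulons(
    common_induced: set[str],
    hits: dict[str, list[MotifHit]],
    matrix: ExpressionMatrix,
    drivers: dict[str, str],
    specific_driver: str = "DREB1C",
    r_cutoff: float = 0.9,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Regulon membership and driver co-expression for commonly induced genes.

    ``drivers`` maps driver names (e.g. DREB1A/B/C) to gene ids present in
    the matrix.  A flat (constant) profile has undefined correlation; such
    genes are kept with ``flat_profile=True`` and no co-expression flags.
    """
    if specific_driver not in drivers:
        raise ContractError(f"specific driver {specific_driver!r} not among drivers")
    for name, gid in drivers.items():
        if gid not in matrix.values.index:
            raise ContractError(f"driver {name} ({gid}) missing from the matrix")

    log2 = matrix.log2_view(pseudocount).values
    # profile matrix for all genes of interest, vectorised
    genes = sorted(common_induced)
    cols = []
    for genotype in ("recurrent", "introgression"):
        ctrl = matrix.select(genotype=genotype, condition="control")
        if not ctrl:
            continue
        cols.append(log2[ctrl].mean(axis=1))
        for t in matrix.timepoints():
            ids = matrix.select(genotype=genotype, condition="cold", time_h=t)
            if ids:
                cols.append(log2[ids].mean(axis=1))
    profiles = pd.DataFrame(np.column_stack(cols), index=log2.index)

    driver_profiles = {
        name: profiles.loc[gid].to_numpy() for name, gid in drivers.items()
    }
    rows = []
    for gene in genes:
        n_hits = len(hits.get(gene, []))
        in_regulon = n_hits >= 1
        prof = profiles.loc[gene].to_numpy()
        flat = np.isclose(prof.std(), 0.0)
        record: dict = {
            "gene_id": gene,
            "n_dre_hits": n_hits,
            "in_dreb1_regulon": in_regulon,
            "flat_profile": bool(flat),
        }
        coexpr: dict[str, bool] = {}
        for name, dprof in driver_profiles.items():
            if flat or np.isclose(dprof.std(), 0.0):
                r = np.nan
                co = False
            else:
                r = float(np.corrcoef(prof, dprof)[0, 1])
                co = r > r_cutoff
            record[f"r_{name}"] = r
            record[f"coexpressed_{name}"] = co
            coexpr[name] = co
        others = [n for n in drivers if n != specific_driver]
        record["dreb1c_specific"] = bool(
            in_regulon
            and coexpr.get(specific_driver, False)
            and not any(coexpr[o] for o in others)
        )
        rows.append(record)
    return pd.DataFrame(rows)
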