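"""Co-localization of gene loci and QTL intervals with introgressed segments.

Intervals are 0-based half-open; two intervals overlap iff they share a
chromosome and ``max(starts) < min(ends)`` — half-open abutment is not an
overlap.  Intersection uses a per-chromosome sort-and-sweep, linear in
output size after sorting.  A configurable flank widens segments to
capture "near-segment" genes (default 0 bp: overlap only).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import GenomicInterval


@dataclass(frozen=True)
class OverlapPair:
    a: GenomicInterval
    b: GenomicInterval
    overlap: int  # bp
    contained: bool  # a fully inside b


def intersect_intervals(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> list[OverlapPair]:
    """All overlapping (a, b) pairs with their overlap length.

    Output order follows the input order of ``set_a`` then ``set_b``.
    """
    by_chrom: dict[str, list[tuple[int, GenomicInterval, int]]] = defaultdict(list)
    for pos, b in enumerate(set_b):
        by_chrom[b.chrom].append((b.start, b, pos))
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda t: (t[0], t[2]))

    out: list[OverlapPair] = []
    for a in set_a:
        candidates = by_chrom.get(a.chrom, [])
        matches = []
        for start_b, b, pos in candidates:
            if start_b >= a.end:
                break
            if b.end > a.start:
                matches.append((pos, b))
        for _, b in sorted(matches):
            ov = min(a.end, b.end) - max(a.start, b.start)
            out.append(
                OverlapPair(a, b, ov, contained=a.start >= b.start and a.end <= b.end)
            )
    return out


def _flanked(segments: Sequence[GenomicInterval], flank: int) -> list[GenomicInterval]:
    if flank == 0:
        return list(segments)
    return [
        replace(s, start=max(0, s.start - flank), end=s.end + flank) for s in segments
    ]


def colocalization_report(
    deg_labels: Mapping[str, Iterable[str]],
    gene_intervals: Sequence[GenomicInterval],
    segments: Sequence[GenomicInterval],
    qtls: Sequence[GenomicInterval],
    flank: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-segment table of overlapping DEGs and QTLs, plus unlinked DEGs.

    ``deg_labels`` maps each differential gene to its set labels (from the
    temporal classification).  Returns ``(per_segment, unlinked)``:
    per-segment rows carry DEG counts, gene ids with labels, and
    overlapping QTL names; ``unlinked`` lists DEGs mapping to no segment
    (or carrying no interval at all, flagged unplaced).
    """
    deg_set = set(deg_labels)
    placed = {iv.name: iv for iv in gene_intervals}
    deg_ivs = [placed[g] for g in sorted(deg_set) if g in placed]

    seg_widened = _flanked(segments, flank)
    gene_pairs = intersect_intervals(deg_ivs, seg_widened)
    qtl_pairs = intersect_intervals(list(qtls), seg_widened)

    genes_by_seg: dict[str, list[OverlapPair]] = defaultdict(list)
    for p in gene_pairs:
        genes_by_seg[p.b.name].append(p)
    qtls_by_seg: dict[str, list[str]] = defaultdict(list)
    for p in qtl_pairs:
        qtls_by_seg[p.b.name].append(p.a.name)

    rows = []
    for seg in segments:
        pairs = genes_by_seg.get(seg.name, [])
        gene_ids = [p.a.name for p in pairs]
        rows.append(
            {
                "segment": seg.name,
                "chrom": seg.chrom,
                "start": seg.start,
                "end": seg.end,
                "n_degs": len(gene_ids),
                "n_contained": sum(p.contained for p in pairs),
                "deg_genes": ";".join(gene_ids),
                "deg_labels": ";".join(
                    ",".join(sorted(deg_labels[g])) for g in gene_ids
                ),
                "n_qtls": len(qtls_by_seg.get(seg.name, [])),
                "qtls": ";".join(sorted(set(qtls_by_seg.get(seg.name, [])))),
            }
        )
    per_segment = pd.DataFrame(
        rows,
        columns=[
            "segment", "chrom", "start", "end", "n_degs", "n_contained",
            "deg_genes", "deg_labels", "n_qtls", "qtls",
        ],
    )

    linked = {p.a.name for p in gene_pairs}
    unlinked_rows = []
    for g in sorted(deg_set):
        if g in linked:
            continue
        unlinked_rows.append(
            {
                "gene_id": g,
                "placed": g in placed,
                "labels": ",".join(sorted(deg_labels[g])),
            }
        )
    unlinked = pd.DataFrame(unlinked_rows, columns=["gene_id", "placed", "labels"])
    return per_segment, unlinked
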