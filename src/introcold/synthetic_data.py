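"""Synthetic two-genotype cold-stress time-course data with planted truth.

The generator emulates the design of a seedling cold-stress microarray
experiment comparing an introgression line against its recurrent parent:
two genotypes, one pooled control per genotype, five stress timepoints
(2, 6, 12, 24, 48 h), three biological replicates.  Genes are planted into
truth classes that realise the characteristic genotype-temporal expression
patterns of such an experiment — commonly induced/repressed, genotype-
specific, constitutively shifted between genotypes, and two biphasic
shapes (repressed-then-induced in both genotypes; induced-then-repressed
in the introgression line only) — plus a null class.

The expression model is additive on the log2 scale::

    log2 intensity = baseline(gene) + genotype offset + cold effect(gene, genotype, t)
                     + N(0, noise_sd_log2)

and is exponentiated to linear intensities.  Alongside the matrix the
module generates promoter sequences with planted DRE core motifs, a toy
12-chromosome annotation with non-overlapping introgressed segments and
QTL intervals, and a flat GO map with one deliberately enriched term —
so that every downstream stage can be tested against known ground truth.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import (
    COLD_TIMEPOINTS,
    ExpressionMatrix,
    GeneSet,
    GenomicInterval,
    SampleDescriptor,
    make_sample_id,
)

TRUTH_CLASSES = (
    "common_induced",
    "common_repressed",
    "recurrent_specific_induced",
    "recurrent_specific_repressed",
    "il_specific_induced",
    "il_specific_repressed",
    "constitutive_up_il",
    "constitutive_down_il",
    "down_then_up",
    "up_then_down_il",
    "null",
)

#: planted counts emulating the relative class abundances of a two-genotype
#: cold-stress study at a 2,000-gene desk scale (commonly regulated genes
#: dominating, induced outnumbering repressed, a modest constitutive block)
DEFAULT_PLANTED_COUNTS = {
    "common_induced": 120,
    "common_repressed": 40,
    "recurrent_specific_induced": 50,
    "recurrent_specific_repressed": 40,
    "il_specific_induced": 45,
    "il_specific_repressed": 15,
    "constitutive_up_il": 30,
    "constitutive_down_il": 20,
    "down_then_up": 20,
    "up_then_down_il": 20,
}

MotifPlant = namedtuple("MotifPlant", ["offset", "word", "strand"])

#: DRE core motif words planted on the forward strand
DRE_WORDS = ("GCCGAC", "ACCGAC")

PROMOTER_LENGTH = 991  # window -1000..-10 relative to the start codon


class ConfigurationError(ValueError):
    """Raised for an inconsistent :class:`SimulationConfig`."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 2000
    n_replicates: int = 3
    timepoints: tuple[int, ...] = COLD_TIMEPOINTS
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_sd_log2: float = 0.25
    planted_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_COUNTS)
    )
    #: planted effect on log2 scale; default 3.0 (8-fold) clears the 5-fold
    #: calling threshold (log2 5 ~ 2.32) with margin
    effect_log2: float = 3.0
    #: fraction of the commonly induced class receiving >= 1 planted DRE word
    motif_plant_rate: float = 0.5
    n_segments: int = 17
    n_qtls: int = 31
    n_segments_with_qtl: int = 15
    n_chromosomes: int = 12
    chromosome_length: int = 4_000_000
    gene_length: int = 3_000
    n_go_terms: int = 20
    go_base_rate: float = 0.05
    go_enrichment_factor: float = 10.0
    go_enriched_term: str = "GO:0000001"
    go_enriched_class: str = "il_specific_induced"

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 2:
            raise ConfigurationError("need n_genes >= 1 and n_replicates >= 2")
        ts = tuple(self.timepoints)
        if any(b <= a for a, b in zip(ts, ts[1:])) or any(t <= 0 for t in ts):
            raise ConfigurationError("timepoints must be strictly increasing positive hours")
        self.timepoints = ts
        if self.effect_log2 <= 0 or self.baseline_log2_sd <= 0 or self.noise_sd_log2 < 0:
            raise ConfigurationError("effect and sd parameters must be positive")
        unknown = set(self.planted_counts) - set(TRUTH_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown truth classes {sorted(unknown)}")
        planted = sum(v for k, v in self.planted_counts.items() if k != "null")
        if any(v < 0 for v in self.planted_counts.values()):
            raise ConfigurationError("planted counts must be non-negative")
        if planted > self.n_genes:
            raise ConfigurationError(
                f"planted counts sum to {planted} > n_genes={self.n_genes}"
            )
        if "null" in self.planted_counts:
            if self.planted_counts["null"] != self.n_genes - planted:
                raise ConfigurationError("explicit null count inconsistent with n_genes")

    @property
    def n_null(self) -> int:
        return self.n_genes - sum(
            v for k, v in self.planted_counts.items() if k != "null"
        )


@dataclass
class TruthTable:
    """Planted ground truth: class labels, motif plants, genomic placement."""

    classes: pd.Series  # gene_id -> truth class
    motif_offsets: dict[str, list[MotifPlant]] = field(default_factory=dict)
    placement: dict[str, str] = field(default_factory=dict)  # gene -> segment ('' = outside)

    def genes_of(self, *classes: str) -> list[str]:
        want = set(classes)
        return [g for g, c in self.classes.items() if c in want]

    def to_frame(self) -> pd.DataFrame:
        genes = list(self.classes.index)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "truth_class": [self.classes[g] for g in genes],
                "motif_offsets": [
                    ";".join(f"{m.offset}:{m.word}:{m.strand}" for m in self.motif_offsets.get(g, []))
                    for g in genes
                ],
                "segment": [self.placement.get(g, "") for g in genes],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def expected_sets(self) -> dict[str, set[str]]:
        """Gene sets the classifier is expected to report, derived from truth.

        The biphasic classes imply memberships beyond their own label: a
        gene repressed early and induced late in both genotypes belongs in
        both the commonly induced and the commonly repressed sets; a gene
        induced early and repressed late in the introgression line only
        belongs in both IL-specific direction sets.
        """
        cl = self.classes
        def genes(*want: str) -> set[str]:
            return {g for g, c in cl.items() if c in want}

        return {
            "common_induced": genes("common_induced", "down_then_up"),
            "common_repressed": genes("common_repressed", "down_then_up"),
            "recurrent_specific_induced": genes("recurrent_specific_induced"),
            "recurrent_specific_repressed": genes("recurrent_specific_repressed"),
            "il_specific_induced": genes("il_specific_induced", "up_then_down_il"),
            "il_specific_repressed": genes("il_specific_repressed", "up_then_down_il"),
            "constitutive_up_il": genes("constitutive_up_il"),
            "constitutive_down_il": genes("constitutive_down_il"),
        }


# ----------------------------------------------------------------------
# expression model


def _phase_split(timepoints: tuple[int, ...]) -> tuple[set[int], set[int]]:
    """(early, late) timepoint sets used by the biphasic classes."""
    canonical_early = {2, 6}
    canonical_late = {24, 48}
    ts = set(timepoints)
    if ts <= set(COLD_TIMEPOINTS):
        return ts & canonical_early, ts & canonical_late
    n = len(timepoints)
    k = max(1, n // 3)
    return set(timepoints[:k]), set(timepoints[-k:])


def cold_effect_log2(truth_class: str, genotype: str, time_h: int,
                     effect: float, timepoints: tuple[int, ...]) -> float:
    """Planted log2 cold-vs-control effect for one class/genotype/time."""
    early, late = _phase_split(timepoints)
    il = genotype == "introgression"
    if truth_class == "common_induced":
        return effect
    if truth_class == "common_repressed":
        return -effect
    if truth_class == "recurrent_specific_induced":
        return effect if not il else 0.0
    if truth_class == "recurrent_specific_repressed":
        return -effect if not il else 0.0
    if truth_class == "il_specific_induced":
        return effect if il else 0.0
    if truth_class == "il_specific_repressed":
        return -effect if il else 0.0
    if truth_class == "down_then_up":
        if time_h in early:
            return -effect
        if time_h in late:
            return effect
        return 0.0
    if truth_class == "up_then_down_il":
        if il and time_h in early:
            return effect
        if il and time_h in late:
            return -effect
        return 0.0
    return 0.0  # null, constitutive classes


def genotype_offset_log2(truth_class: str, genotype: str, effect: float) -> float:
    if genotype != "introgression":
        return 0.0
    if truth_class == "constitutive_up_il":
        return effect
    if truth_class == "constitutive_down_il":
        return -effect
    return 0.0


def _assign_classes(config: SimulationConfig) -> pd.Series:
    width = len(str(config.n_genes))
    genes = [f"g{i + 1:0{width}d}" for i in range(config.n_genes)]
    labels: list[str] = []
    for cls in TRUTH_CLASSES:
        if cls == "null":
            continue
        labels.extend([cls] * config.planted_counts.get(cls, 0))
    labels.extend(["null"] * config.n_null)
    return pd.Series(labels, index=pd.Index(genes, name="gene_id"), name="truth_class")


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, tuple[SampleDescriptor, ...], TruthTable]:
    """Simulate the full two-genotype time-course expression matrix.

    Returns a linear-scale matrix with ``2 genotypes x (1 pooled control +
    len(timepoints)) x n_replicates`` columns, the matching sample design,
    and the planted truth table.  Same config (including seed) gives
    bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    classes = _assign_classes(config)
    genes = list(classes.index)

    samples: list[SampleDescriptor] = []
    for genotype in ("recurrent", "introgression"):
        for rep in range(1, config.n_replicates + 1):
            samples.append(
                SampleDescriptor(
                    make_sample_id(genotype, "control", 0, rep), genotype, "control", 0, rep
                )
            )
        for t in config.timepoints:
            for rep in range(1, config.n_replicates + 1):
                samples.append(
                    SampleDescriptor(
                        make_sample_id(genotype, "cold", t, rep), genotype, "cold", t, rep
                    )
                )

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    means = np.empty((config.n_genes, len(samples)))
    cls_arr = classes.to_numpy()
    for j, s in enumerate(samples):
        geno_off = np.array(
            [genotype_offset_log2(c, s.genotype, config.effect_log2) for c in cls_arr]
        )
        if s.condition == "cold":
            cold = np.array(
                [
                    cold_effect_log2(c, s.genotype, s.time_h, config.effect_log2, config.timepoints)
                    for c in cls_arr
                ]
            )
        else:
            cold = 0.0
        means[:, j] = baseline + geno_off + cold
    noise = rng.normal(0.0, config.noise_sd_log2, means.shape) if config.noise_sd_log2 > 0 else 0.0
    values = np.exp2(means + noise)
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                      columns=[s.sample_id for s in samples])
    matrix = ExpressionMatrix(df, tuple(samples), scale="linear")
    return matrix, tuple(samples), TruthTable(classes=classes)


# ----------------------------------------------------------------------
# promoters


def _contains_dre(seq: str) -> bool:
    rc_words = ("GTCGGC", "GTCGGT")
    return any(w in seq for w in DRE_WORDS + rc_words)


def generate_promoters(
    truth: TruthTable,
    config: SimulationConfig,
    designated: list[str] | None = None,
    reject_background_hits: bool = False,
) -> dict[str, str]:
    """One 991-nt promoter window per gene, with planted DRE words.

    ``designated`` genes (default: the commonly induced truth class)
    receive >= 1 planted DRE word with probability ``motif_plant_rate``;
    plants are recorded in ``truth.motif_offsets``.  The background is
    uniform over A/C/G/T, so accidental motif occurrences are possible and
    deliberately left unrecorded (the scanner, not the truth table, finds
    them) unless ``reject_background_hits`` resamples motif-free
    backgrounds for small toy instances.
    """
    rng = np.random.default_rng([config.seed, 7])
    if designated is None:
        designated = truth.genes_of("common_induced")
    designated_set = set(designated)
    bases = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    truth.motif_offsets = {}
    for gene in truth.classes.index:
        seq = "".join(rng.choice(bases, PROMOTER_LENGTH))
        if reject_background_hits:
            while _contains_dre(seq):
                seq = "".join(rng.choice(bases, PROMOTER_LENGTH))
        plants: list[MotifPlant] = []
        if gene in designated_set and rng.random() < config.motif_plant_rate:
            word = DRE_WORDS[int(rng.integers(len(DRE_WORDS)))]
            offset = int(rng.integers(0, PROMOTER_LENGTH - len(word) + 1))
            seq = seq[:offset] + word + seq[offset + len(word):]
            plants.append(MotifPlant(offset, word, "+"))
        promoters[gene] = seq
        if plants:
            truth.motif_offsets[gene] = plants
    return promoters


# ----------------------------------------------------------------------
# genome annotation: segments, genes, QTLs, GO map


@dataclass
class AnnotationBundle:
    genes: list[GenomicInterval]
    segments: list[GenomicInterval]
    qtls: list[GenomicInterval]
    go_map: dict[str, GeneSet]
    chrom_lengths: dict[str, int]


#: truth classes whose genes are placed inside introgressed segments — the
#: genotype-dependent classes, mirroring expression differences driven by
#: the introgressed chromosome regions themselves
SEGMENT_CLASSES = (
    "il_specific_induced",
    "il_specific_repressed",
    "constitutive_up_il",
    "constitutive_down_il",
    "up_then_down_il",
)


def _overlaps_any(chrom: str, start: int, end: int, intervals: list[GenomicInterval]) -> bool:
    return any(
        iv.chrom == chrom and max(iv.start, start) < min(iv.end, end) for iv in intervals
    )


def generate_genome_annotation(
    truth: TruthTable, config: SimulationConfig
) -> AnnotationBundle:
    """Toy genome annotation consistent with the planted truth.

    Places ``n_segments`` pairwise-disjoint introgressed segments on a
    12-chromosome toy genome, genes of genotype-dependent truth classes
    inside segments and all others outside, QTL intervals overlapping a
    subset of the segments, and a flat GO map with one term planted at
    ``go_enrichment_factor`` times the base rate in a designated class.
    """
    rng = np.random.default_rng([config.seed, 13])
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chromosome_length for c in chroms}

    segments: list[GenomicInterval] = []
    attempts = 0
    while len(segments) < config.n_segments:
        attempts += 1
        if attempts > 10_000:
            raise ConfigurationError("could not place non-overlapping segments")
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(200_000, 400_000))
        start = int(rng.integers(0, chrom_lengths[chrom] - length))
        if _overlaps_any(chrom, start, start + length, segments):
            continue
        segments.append(
            GenomicInterval(chrom, start, start + length, f"seg{len(segments) + 1:02d}", "segment")
        )

    genes: list[GenomicInterval] = []
    truth.placement = {}
    seg_classes = set(SEGMENT_CLASSES)
    for gene, cls in truth.classes.items():
        if cls in seg_classes:
            seg = segments[int(rng.integers(len(segments)))]
            start = int(rng.integers(seg.start, seg.end - config.gene_length))
            chrom = seg.chrom
            truth.placement[gene] = seg.name
        else:
            while True:
                chrom = chroms[int(rng.integers(len(chroms)))]
                start = int(rng.integers(0, chrom_lengths[chrom] - config.gene_length))
                if not _overlaps_any(chrom, start, start + config.gene_length, segments):
                    break
            truth.placement[gene] = ""
        genes.append(GenomicInterval(chrom, start, start + config.gene_length, gene, "gene"))

    qtls: list[GenomicInterval] = []
    n_with = min(config.n_segments_with_qtl, len(segments))
    covered_idx = rng.choice(len(segments), size=n_with, replace=False)
    for i in range(config.n_qtls):
        seg = segments[int(covered_idx[i % n_with])]
        # QTL interval straddles the segment with marker-scale slop
        slop = int(rng.integers(20_000, 120_000))
        start = max(0, seg.start - slop)
        end = min(chrom_lengths[seg.chrom], seg.end + int(rng.integers(0, 80_000)))
        qtls.append(GenomicInterval(seg.chrom, start, end, f"qtl{i + 1:02d}", "qtl"))

    terms = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    enriched_genes = set(truth.genes_of(config.go_enriched_class))
    rate_hi = min(1.0, config.go_base_rate * config.go_enrichment_factor)
    membership: dict[str, list[str]] = {t: [] for t in terms}
    for gene in truth.classes.index:
        hits = [t for t in terms if rng.random() < config.go_base_rate]
        if config.go_enriched_term in terms and gene in enriched_genes:
            if rng.random() < rate_hi and config.go_enriched_term not in hits:
                hits.insert(0, config.go_enriched_term)
        for t in hits[:5]:  # each gene carries 0-5 terms
            membership[t].append(gene)
    go_map = {
        t: GeneSet(t, f"synthetic term {t}", tuple(membership[t]))
        for t in terms
        if membership[t]
    }
    return AnnotationBundle(genes, segments, qtls, go_map, chrom_lengths)
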