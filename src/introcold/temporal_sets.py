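"""Phase assignment and the time-course gene-set algebra.

The cold response is structured into an early phase (I, 2-6 h), a middle
phase (II, 12 h), and a late phase (III, 24-48 h).  Per-timepoint DEG
calls from both genotypes are aggregated into:

* per phase and direction, the commonly regulated set (significant in
  both genotypes at >= 1 timepoint of the phase) and the per-genotype
  remainder;
* global genotype-specific sets — significant with a direction in one
  genotype at >= 1 stage and never significant with that direction in the
  other genotype at any stage (redundancy across phases removed);
* continuously regulated sets — significant with a direction in every
  phase;
* constitutive sets — significant in the between-genotype contrast under
  control conditions and non-responsive to cold in either genotype.

A gene induced in one genotype and repressed in the other is recorded as
specific in both direction ledgers and flagged as a direction conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .sam_test import Contrast, ContractError

PHASES = ("I", "II", "III")
PHASE_OF_TIME = {2: "I", 6: "I", 12: "II", 24: "III", 48: "III"}
DIRECTIONS = ("induced", "repressed")
GENOTYPE_KEYS = {"recurrent": "recurrent", "introgression": "il"}


def assign_phase(time_h: int) -> str:
    """Map a cold-stress timepoint (hours) to its response phase."""
    try:
        return PHASE_OF_TIME[time_h]
    except KeyError:
        raise ContractError(
            f"no phase defined for timepoint {time_h} h (known: {sorted(PHASE_OF_TIME)})"
        ) from None


@dataclass
class GeneSetPartition:
    """The classified cold-response gene sets."""

    # (phase, direction) -> sets
    common: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    recurrent_only_phase: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    il_only_phase: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    # direction -> global sets (redundancy across phases removed)
    common_global: dict[str, set[str]] = field(default_factory=dict)
    recurrent_specific: dict[str, set[str]] = field(default_factory=dict)
    il_specific: dict[str, set[str]] = field(default_factory=dict)
    #: genes induced in one genotype and repressed in the other
    direction_conflicts: set[str] = field(default_factory=set)
    constitutive_up_il: set[str] = field(default_factory=set)
    constitutive_down_il: set[str] = field(default_factory=set)

    def summary_table(self) -> pd.DataFrame:
        """Cold-responsive / constitutive set sizes, one row per set."""
        rows = []
        for direction in DIRECTIONS:
            rows.append(("common", direction, len(self.common_global.get(direction, set()))))
            rows.append(
                ("recurrent_specific", direction, len(self.recurrent_specific.get(direction, set())))
            )
            rows.append(("il_specific", direction, len(self.il_specific.get(direction, set()))))
        rows.append(("constitutive_up_il", "-", len(self.constitutive_up_il)))
        rows.append(("constitutive_down_il", "-", len(self.constitutive_down_il)))
        return pd.DataFrame(rows, columns=["set", "direction", "n_genes"])


def _significance_masks(
    deg_tables: Mapping[Contrast, pd.DataFrame]
) -> tuple[dict[tuple[str, int, str], set[str]], list[str], list[int]]:
    """(genotype, time, direction) -> significant gene set, plus the shared
    gene universe and the timepoints seen."""
    universe: list[str] | None = None
    masks: dict[tuple[str, int, str], set[str]] = {}
    times: set[int] = set()
    for contrast, table in deg_tables.items():
        if contrast.kind != "cold_vs_control":
            continue
        genes = list(table["gene_id"])
        if universe is None:
            universe = genes
        elif set(genes) != set(universe):
            raise ContractError(
                f"DEG table for {contrast.label!r} has a different gene universe"
            )
        times.add(contrast.time_h)
        for direction in DIRECTIONS:
            sig = table[(table["significant"]) & (table["direction"] == direction)]
            masks[(contrast.genotype, contrast.time_h, direction)] = set(sig["gene_id"])
    if universe is None:
        raise ContractError("no cold_vs_control DEG tables supplied")
    return masks, universe, sorted(times)


def classify_common_specific(
    deg_tables: Mapping[Contrast, pd.DataFrame],
    phase_mode: str = "phase",
) -> GeneSetPartition:
    """Partition cold-responsive genes into common and genotype-specific sets.

    ``phase_mode='phase'`` (default) calls a gene common at a phase when it
    is significant in both genotypes at >= 1 timepoint *of that phase*, not
    necessarily the same timepoint; ``'timepoint'`` requires same-timepoint
    co-significance.
    """
    if phase_mode not in ("phase", "timepoint"):
        raise ContractError(f"unknown phase_mode {phase_mode!r}")
    masks, _, times = _significance_masks(deg_tables)
    part = GeneSetPartition()

    def sig_at(genotype: str, direction: str, timeset) -> set[str]:
        out: set[str] = set()
        for t in timeset:
            out |= masks.get((genotype, t, direction), set())
        return out

    phase_times = {ph: [t for t in times if assign_phase(t) == ph] for ph in PHASES}

    for direction in DIRECTIONS:
        for ph in PHASES:
            ts = phase_times[ph]
            rec = sig_at("recurrent", direction, ts)
            il = sig_at("introgression", direction, ts)
            if phase_mode == "phase":
                common = rec & il
            else:
                common = set()
                for t in ts:
                    common |= masks.get(("recurrent", t, direction), set()) & masks.get(
                        ("introgression", t, direction), set()
                    )
            part.common[(ph, direction)] = common
            part.recurrent_only_phase[(ph, direction)] = rec - il
            part.il_only_phase[(ph, direction)] = il - rec

        rec_all = sig_at("recurrent", direction, times)
        il_all = sig_at("introgression", direction, times)
        part.common_global[direction] = rec_all & il_all
        part.recurrent_specific[direction] = rec_all - il_all
        part.il_specific[direction] = il_all - rec_all

    # direction conflicts: specific with one direction while the other
    # genotype is significant only with the opposite direction
    for direction, other in (("induced", "repressed"), ("repressed", "induced")):
        rec_dir = sig_at("recurrent", direction, times)
        il_other = sig_at("introgression", other, times)
        il_dir = sig_at("introgression", direction, times)
        part.direction_conflicts |= (rec_dir & il_other) - il_dir
        il_d = sig_at("introgression", direction, times)
        rec_other = sig_at("recurrent", other, times)
        rec_d = sig_at("recurrent", direction, times)
        part.direction_conflicts |= (il_d & rec_other) - rec_d
    return part


def phase_venn(
    deg_tables: Mapping[Contrast, pd.DataFrame], genotype: str, direction: str
) -> dict[str, int]:
    """Three-way Venn counts over phases I/II/III for one genotype/direction."""
    masks, _, times = _significance_masks(deg_tables)
    by_phase = {ph: set() for ph in PHASES}
    for t in times:
        by_phase[assign_phase(t)] |= masks.get((genotype, t, direction), set())
    s1, s2, s3 = by_phase["I"], by_phase["II"], by_phase["III"]
    return {
        "I_only": len(s1 - s2 - s3),
        "II_only": len(s2 - s1 - s3),
        "III_only": len(s3 - s1 - s2),
        "I_II": len((s1 & s2) - s3),
        "I_III": len((s1 & s3) - s2),
        "II_III": len((s2 & s3) - s1),
        "I_II_III": len(s1 & s2 & s3),
        "total": len(s1 | s2 | s3),
    }


def continuous_response(
    deg_tables: Mapping[Contrast, pd.DataFrame]
) -> dict[tuple[str, str], set[str]]:
    """Genes significant with a direction in every phase, per genotype.

    Continuity requires >= 1 significant timepoint inside each of phases
    I, II, and III.
    """
    masks, _, times = _significance_masks(deg_tables)
    out: dict[tuple[str, str], set[str]] = {}
    for genotype in ("recurrent", "introgression"):
        for direction in DIRECTIONS:
            per_phase = []
            for ph in PHASES:
                s: set[str] = set()
                for t in times:
                    if assign_phase(t) == ph:
                        s |= masks.get((genotype, t, direction), set())
                per_phase.append(s)
            out[(genotype, direction)] = set.intersection(*per_phase) if per_phase else set()
    return out


def constitutive_degs(
    genotype_tables: Mapping[int, pd.DataFrame],
    cold_tables: Mapping[Contrast, pd.DataFrame],
) -> tuple[set[str], set[str]]:
    """Constitutive between-genotype DEGs, up- and down-regulated in the IL.

    A gene is constitutive when it is significant in the introgression-vs-
    recurrent contrast under control conditions *and* is not cold
    responsive — i.e. not significant in any within-genotype cold contrast
    of either genotype.  ``genotype_tables`` is keyed by timepoint with 0 =
    control.
    """
    if 0 not in genotype_tables:
        raise ContractError("constitutive_degs needs the control-condition genotype contrast")
    masks, _, times = _significance_masks(cold_tables)
    cold_responsive: set[str] = set()
    for key, genes in masks.items():
        cold_responsive |= genes

    control = genotype_tables[0]
    up = set(
        control[(control["significant"]) & (control["direction"] == "induced")]["gene_id"]
    )
    down = set(
        control[(control["significant"]) & (control["direction"] == "repressed")]["gene_id"]
    )
    return up - cold_responsive, down - cold_responsive
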