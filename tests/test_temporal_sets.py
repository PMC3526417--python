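import numpy as np
import pandas as pd
import pytest

from introcold.sam_test import Contrast, ContractError
from introcold.temporal_sets import (
    assign_phase,
    classify_common_specific,
    constitutive_degs,
    continuous_response,
    phase_venn,
)

TIMES = (2, 6, 12, 24, 48)


def make_tables(masks, genes):
    """Build DEG tables from {(genotype, time): {gene: direction}} masks."""
    tables = {}
    for genotype in ("recurrent", "introgression"):
        for t in TIMES:
            m = masks.get((genotype, t), {})
            tables[Contrast("cold_vs_control", genotype, t)] = pd.DataFrame(
                {
                    "gene_id": genes,
                    "significant": [g in m for g in genes],
                    "direction": [m.get(g, "induced") for g in genes],
                }
            )
    return tables


class TestAssignPhase:
    @pytest.mark.parametrize("t,phase", [(2, "I"), (6, "I"), (12, "II"), (24, "III"), (48, "III")])
    def test_mapping(self, t, phase):
        assert assign_phase(t) == phase

    def test_unknown_time_rejected(self):
        with pytest.raises(ContractError, match="no phase"):
            assign_phase(36)


class TestClassify:
    def test_common_at_shared_timepoint(self):
        genes = ["a", "b"]
        tables = make_tables(
            {("recurrent", 24): {"a": "induced"}, ("introgression", 24): {"a": "induced"}},
            genes,
        )
        part = classify_common_specific(tables)
        assert part.common[("III", "induced")] == {"a"}
        assert part.common_global["induced"] == {"a"}

    def test_il_specific_when_other_genotype_silent(self):
        genes = ["a"]
        tables = make_tables({("introgression", 2): {"a": "induced"}}, genes)
        part = classify_common_specific(tables)
        assert part.il_specific["induced"] == {"a"}
        assert part.recurrent_specific["induced"] == set()

    def test_phase_mode_vs_timepoint_mode(self):
        # significant in both genotypes within phase III but at different timepoints
        genes = ["a"]
        tables = make_tables(
            {("recurrent", 24): {"a": "induced"}, ("introgression", 48): {"a": "induced"}},
            genes,
        )
        by_phase = classify_common_specific(tables, phase_mode="phase")
        assert by_phase.common[("III", "induced")] == {"a"}
        by_tp = classify_common_specific(tables, phase_mode="timepoint")
        assert by_tp.common[("III", "induced")] == set()

    def test_direction_conflict_in_both_ledgers_and_flagged(self):
        genes = ["a"]
        tables = make_tables(
            {("recurrent", 12): {"a": "induced"}, ("introgression", 24): {"a": "repressed"}},
            genes,
        )
        part = classify_common_specific(tables)
        assert "a" in part.recurrent_specific["induced"]
        assert "a" in part.il_specific["repressed"]
        assert part.direction_conflicts == {"a"}

    def test_random_masks_match_brute_force_set_algebra(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(500)]
        masks = {}
        for genotype in ("recurrent", "introgression"):
            for t in TIMES:
                chosen = rng.choice(genes, size=40, replace=False)
                dirs = rng.choice(["induced", "repressed"], size=40)
                masks[(genotype, t)] = dict(zip(chosen, dirs))
        tables = make_tables(masks, genes)
        part = classify_common_specific(tables)

        def sig(genotype, direction):
            out = set()
            for t in TIMES:
                out |= {g for g, d in masks[(genotype, t)].items() if d == direction}
            return out

        for direction in ("induced", "repressed"):
            rec, il = sig("recurrent", direction), sig("introgression", direction)
            assert part.common_global[direction] == rec & il
            assert part.recurrent_specific[direction] == rec - il
            assert part.il_specific[direction] == il - rec
            for ph, ts in (("I", (2, 6)), ("II", (12,)), ("III", (24, 48))):
                rec_ph = set().union(
                    *({g for g, d in masks[("recurrent", t)].items() if d == direction} for t in ts)
                )
                il_ph = set().union(
                    *({g for g, d in masks[("introgression", t)].items() if d == direction} for t in ts)
                )
                assert part.common[(ph, direction)] == rec_ph & il_ph
                # union property: common + both one-genotype remainders cover
                # everything significant at that phase
                assert (
                    part.common[(ph, direction)]
                    | part.recurrent_only_phase[(ph, direction)]
                    | part.il_only_phase[(ph, direction)]
                ) == rec_ph | il_ph

    def test_mismatched_universe_rejected(self):
        t1 = make_tables({}, ["a", "b"])
        t2 = make_tables({}, ["a", "c"])
        mixed = dict(t1)
        key = Contrast("cold_vs_control", "introgression", 48)
        mixed[key] = t2[key]
        with pytest.raises(ContractError, match="universe"):
            classify_common_specific(mixed)


class TestContinuous:
    def test_all_three_phases_required(self):
        genes = ["a", "b"]
        tables = make_tables(
            {
                ("recurrent", 2): {"a": "induced", "b": "induced"},
                ("recurrent", 12): {"a": "induced"},
                ("recurrent", 24): {"a": "induced"},
                ("recurrent", 6): {"b": "induced"},
            },
            genes,
        )
        cont = continuous_response(tables)
        assert cont[("recurrent", "induced")] == {"a"}  # b lacks phases II and III

    def test_removing_a_timepoint_only_shrinks(self):
        rng = np.random.default_rng(22)
        genes = [f"g{i}" for i in range(100)]
        masks = {
            (gt, t): dict(
                zip(rng.choice(genes, size=30, replace=False), ["induced"] * 30)
            )
            for gt in ("recurrent", "introgression")
            for t in TIMES
        }
        full = continuous_response(make_tables(masks, genes))
        reduced_masks = {k: (v if k[1] != 24 else {}) for k, v in masks.items()}
        reduced = continuous_response(make_tables(reduced_masks, genes))
        for key in full:
            assert reduced[key] <= full[key]


class TestConstitutive:
    def _geno_tables(self, genes, sig_by_time):
        out = {}
        for t in (0,) + TIMES:
            m = sig_by_time.get(t, {})
            out[t] = pd.DataFrame(
                {
                    "gene_id": genes,
                    "significant": [g in m for g in genes],
                    "direction": [m.get(g, "induced") for g in genes],
                }
            )
        return out

    def test_constitutively_up_without_cold_response(self):
        genes = ["a", "b"]
        geno = self._geno_tables(genes, {t: {"a": "induced"} for t in (0,) + TIMES})
        cold = make_tables({}, genes)
        up, down = constitutive_degs(geno, cold)
        assert up == {"a"} and down == set()

    def test_cold_responsive_gene_excluded(self):
        genes = ["a"]
        geno = self._geno_tables(genes, {0: {"a": "induced"}})
        cold = make_tables({("introgression", 24): {"a": "induced"}}, genes)
        up, _ = constitutive_degs(geno, cold)
        assert up == set()

    def test_random_masks_match_oracle(self):
        rng = np.random.default_rng(23)
        genes = [f"g{i}" for i in range(200)]
        ctrl_up = set(rng.choice(genes, 40, replace=False))
        ctrl_down = set(rng.choice(sorted(set(genes) - ctrl_up), 30, replace=False))
        cold_sig = set(rng.choice(genes, 60, replace=False))
        geno = self._geno_tables(
            genes,
            {0: {**{g: "induced" for g in ctrl_up}, **{g: "repressed" for g in ctrl_down}}},
        )
        cold = make_tables({("recurrent", 12): {g: "induced" for g in cold_sig}}, genes)
        up, down = constitutive_degs(geno, cold)
        assert up == ctrl_up - cold_sig
        assert down == ctrl_down - cold_sig

    def test_missing_control_contrast_rejected(self):
        genes = ["a"]
        geno = self._geno_tables(genes, {})
        del geno[0]
        with pytest.raises(ContractError, match="control"):
            constitutive_degs(geno, make_tables({}, genes))


def test_phase_venn_counts_sum_to_total():
    rng = np.random.default_rng(24)
    genes = [f"g{i}" for i in range(150)]
    masks = {
        ("recurrent", t): dict(
            zip(rng.choice(genes, 40, replace=False), ["induced"] * 40)
        )
        for t in TIMES
    }
    venn = phase_venn(make_tables(masks, genes), "recurrent", "induced")
    regions = [v for k, v in venn.items() if k != "total"]
    assert sum(regions) == venn["total"]
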