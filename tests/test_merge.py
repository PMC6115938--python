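"""GPR rules, reaction signatures, model merging, dead-end pruning."""

import numpy as np
import pytest

from ensipipe.errors import GprParseError, StageError
from ensipipe.merge import (DISTINCT, IDENTICAL, PROTON_VARIANT, STOICH_VARIANT,
                            classify_match, find_dead_end_metabolites,
                            merge_pipeline, prune_by_orthology,
                            reaction_signature, remove_dead_ends,
                            transfer_unique_reactions)
from ensipipe.models import (MetabolicModel, Metabolite, Reaction, evaluate_gpr,
                             parse_gpr, rewrite_gpr, simplify_gpr_removing)
from ensipipe.simulate import FixtureSpec, ModelSpec, gen_model, gen_ortholog_map


def rxn(rid, stoich, lb=0.0, ub=1000.0, gpr="", exchange=False):
    return Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                    gpr=gpr, is_exchange=exchange)


def model_from(reactions, objective="", genes=None):
    mets = {m for r in reactions for m in r.stoichiometry}
    m = MetabolicModel(
        id="m", genes=set(genes or []),
        reactions={r.id: r for r in reactions},
        metabolites={mid: Metabolite(id=mid, compartment=mid.rsplit("_", 1)[-1])
                     for mid in mets},
        objective_reaction=objective)
    m.validate()
    return m


class TestGpr:
    @pytest.mark.parametrize("expr,present,expected", [
        ("g1 or g2", {"g2"}, True),
        ("g1 and g2", {"g2"}, False),
        ("", set(), True),
        ("(g1 and g2) or g3", {"g3"}, True),
        ("g1 and (g2 or g3)", {"g1", "g3"}, True),
    ])
    def test_evaluation(self, expr, present, expected):
        assert evaluate_gpr(expr, present) is expected

    def test_parse_error_reports_position(self):
        with pytest.raises(GprParseError) as exc:
            parse_gpr("g1 and (g2 or")
        assert exc.value.position == 13

    def test_unbalanced_paren(self):
        with pytest.raises(GprParseError):
            parse_gpr("(g1 and g2")

    def test_simplify_removes_false_literals(self):
        assert simplify_gpr_removing("g1 or g2", {"g1"}) == "g2"
        assert simplify_gpr_removing("g1 and g2", {"g1"}) is None
        assert simplify_gpr_removing("(g1 and g2) or g3", {"g1"}) == "g3"
        assert simplify_gpr_removing("", {"g1"}) == ""

    def test_rewrite_substitutes_and_rejects_unmapped(self):
        assert rewrite_gpr("gS1 and gS2", {"gS1": "gM1", "gS2": "gM2"}) == "gM1 and gM2"
        with pytest.raises(Exception):
            rewrite_gpr("gS1 and gS3", {"gS1": "gM1"})


class TestSignatures:
    def test_metabolite_order_irrelevant(self):
        r1 = rxn("r1", {"a_c": -1, "b_c": -1, "c_c": 1})
        r2 = rxn("r2", {"b_c": -1, "a_c": -1, "c_c": 1})
        assert reaction_signature(r1) == reaction_signature(r2)

    def test_reversible_direction_normalized(self):
        r1 = rxn("r1", {"a_c": -1, "b_c": 1}, lb=-1000)
        r2 = rxn("r2", {"b_c": -1, "a_c": 1}, lb=-1000)
        assert reaction_signature(r1) == reaction_signature(r2)

    def test_backwards_only_flipped(self):
        fwd = rxn("f", {"a_c": -1, "b_c": 1})
        back = rxn("b", {"b_c": -1, "a_c": 1}, lb=-1000, ub=0.0)
        assert reaction_signature(fwd) == reaction_signature(back)

    def test_proton_flag(self):
        with_h = rxn("r1", {"a_c": -1, "h_c": -1, "b_c": 1})
        without = rxn("r2", {"a_c": -1, "b_c": 1})
        assert reaction_signature(with_h, ignore_protons=True) == \
            reaction_signature(without, ignore_protons=True)
        assert reaction_signature(with_h) != reaction_signature(without)

    def test_coefficient_scaling_normalized(self):
        r1 = rxn("r1", {"a_c": -2, "b_c": 2})
        r2 = rxn("r2", {"a_c": -1, "b_c": 1})
        assert reaction_signature(r1) == reaction_signature(r2)


class TestClassify:
    A = rxn("x", {"a_c": -1, "b_c": -1, "c_c": 1})

    @pytest.mark.parametrize("other,expected", [
        (rxn("y", {"a_c": -1, "b_c": -1, "c_c": 1}), IDENTICAL),
        (rxn("y", {"a_c": -1, "b_c": -1, "h_c": 1, "c_c": 1}), PROTON_VARIANT),
        (rxn("y", {"a_c": -2, "b_c": -1, "c_c": 1}), STOICH_VARIANT),
        (rxn("y", {"a_c": -1, "d_c": 1}), DISTINCT),
    ])
    def test_classes(self, other, expected):
        assert classify_match(self.A, other) == expected
        assert classify_match(other, self.A) == expected  # symmetry


class TestPrune:
    def test_unsatisfiable_reaction_removed(self):
        m = model_from([rxn("r1", {"a_c": -1, "b_c": 1}, gpr="g1")], genes=["g1"])
        pruned, rep = prune_by_orthology(m, {})
        assert "r1" not in pruned.reactions
        assert rep.genes_deleted == 1 and rep.reactions_removed_by_pruning == 1
        assert pruned.metabolites == {}  # orphans dropped

    def test_or_branch_survives_with_simplified_gpr(self):
        m = model_from([rxn("r1", {"a_c": -1, "b_c": 1}, gpr="g1 or g2")],
                       genes=["g1", "g2"])
        pruned, _ = prune_by_orthology(m, {"g2": "gM2"})
        assert pruned.reactions["r1"].gpr == "g2"

    def test_gene_free_reaction_always_kept(self):
        m = model_from([rxn("r1", {"a_c": -1, "b_c": 1})])
        pruned, _ = prune_by_orthology(m, {})
        assert "r1" in pruned.reactions

    def test_input_not_modified(self):
        m = model_from([rxn("r1", {"a_c": -1, "b_c": 1}, gpr="g1")], genes=["g1"])
        prune_by_orthology(m, {})
        assert "r1" in m.reactions and "g1" in m.genes


class TestTransfer:
    def test_planted_classes_handled(self):
        spec = FixtureSpec(seed=31, model_spec=ModelSpec(
            n_identical=1, n_proton_variants=1, n_stoich_variants=1,
            n_new_pathways=1, n_dead_end_chains=0, n_prunable=0))
        recipient, donor, gt = gen_model(spec)
        omap = gen_ortholog_map(spec)
        merged, rep = transfer_unique_reactions(recipient, donor, omap)
        assert rep.reactions_transferred == 2  # the one new pathway
        assert rep.transfers_skipped_identical == 1
        assert rep.transfers_skipped_proton == 1
        assert rep.transfers_skipped_stoich == 1
        assert sorted(rep.transferred_reaction_ids) == sorted(gt.transfer_ids)

    def test_zero_distinct_leaves_recipient_unchanged(self):
        spec = FixtureSpec(seed=32, model_spec=ModelSpec(
            n_new_pathways=0, n_dead_end_chains=0, n_prunable=0))
        recipient, donor, _ = gen_model(spec)
        merged, rep = transfer_unique_reactions(recipient, donor, gen_ortholog_map(spec))
        assert rep.reactions_transferred == 0
        assert set(merged.reactions) == set(recipient.reactions)

    def test_transferred_gpr_rewritten(self):
        spec = FixtureSpec(seed=33)
        recipient, donor, gt = gen_model(spec)
        omap = gen_ortholog_map(spec)
        pruned, _ = prune_by_orthology(donor, omap)
        merged, _ = transfer_unique_reactions(recipient, pruned, omap)
        for rid in gt.transfer_ids:
            assert merged.reactions[rid].gpr.startswith("gN")

    def test_recipient_reactions_never_deleted(self):
        spec = FixtureSpec(seed=34)
        recipient, donor, _ = gen_model(spec)
        omap = gen_ortholog_map(spec)
        pruned, _ = prune_by_orthology(donor, omap)
        merged, _ = transfer_unique_reactions(recipient, pruned, omap)
        assert set(recipient.reactions) <= set(merged.reactions)


def chain_model(objective=None):
    """EX_A <-> A, A -> B, B -> C with C orphan."""
    return model_from([
        rxn("EX_A", {"a_e": -1}, lb=-10, exchange=True),
        rxn("AB", {"a_e": -1, "b_c": 1}),
        rxn("BC", {"b_c": -1, "c_c": 1}),
    ], objective=objective or "")


class TestDeadEnds:
    def test_terminal_metabolite_found(self):
        m = chain_model()
        assert "c_c" in find_dead_end_metabolites(m)
        assert "a_e" not in find_dead_end_metabolites(m)

    def test_consumer_shifts_dead_end_downstream(self):
        m = model_from([
            rxn("EX_A", {"a_e": -1}, lb=-10, exchange=True),
            rxn("AB", {"a_e": -1, "b_c": 1}),
            rxn("BC", {"b_c": -1, "c_c": 1}),
            rxn("CD", {"c_c": -1, "d_c": 1}),
        ])
        dead = find_dead_end_metabolites(m)
        assert "c_c" not in dead and "d_c" in dead

    def test_reversible_exchange_alone_not_dead(self):
        m = model_from([rxn("EX_A", {"a_e": -1}, lb=-10, exchange=True)])
        assert find_dead_end_metabolites(m) == set()

    def test_fixpoint_trace(self):
        out, removed, mets = remove_dead_ends(chain_model())
        assert set(removed) == {"AB", "BC"}
        assert "EX_A" in out.reactions
        assert set(mets) == {"b_c", "c_c"}

    def test_no_dead_ends_unchanged(self):
        spec = FixtureSpec(seed=35, model_spec=ModelSpec(n_dead_end_chains=0))
        recipient, _, _ = gen_model(spec)
        out, removed, mets = remove_dead_ends(recipient)
        assert removed == [] and mets == []

    def test_idempotent(self):
        out, removed, _ = remove_dead_ends(chain_model())
        again, removed2, _ = remove_dead_ends(out)
        assert removed2 == []

    def test_objective_protected(self):
        m = chain_model(objective="BC")
        with pytest.raises(StageError):
            remove_dead_ends(m)

    def test_producer_mode_is_narrower(self):
        m = chain_model()
        _, removed_participant, _ = remove_dead_ends(m, mode="participant")
        _, removed_producer, _ = remove_dead_ends(m, mode="producer")
        assert set(removed_producer) <= set(removed_participant)

    def test_matches_randomized_order_oracle(self):
        """Set-based passes give the same fixpoint as removing dead-end
        reactions one at a time in random order."""
        spec = FixtureSpec(seed=36, model_spec=ModelSpec(
            n_dead_end_chains=3, dead_end_chain_length=4, n_prunable=0))
        recipient, donor, _ = gen_model(spec)
        merged, _ = transfer_unique_reactions(recipient, donor, gen_ortholog_map(spec))
        expected, _, _ = remove_dead_ends(merged)
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = merged.copy()
            while True:
                dead = find_dead_end_metabolites(m)
                candidates = sorted(
                    rid for rid, r in m.reactions.items()
                    if any(met in dead for met in r.stoichiometry))
                if not candidates:
                    break
                victim = candidates[int(rng.integers(len(candidates)))]
                del m.reactions[victim]
                m.remove_orphan_metabolites()
            assert set(m.reactions) == set(expected.reactions)


class TestMergePipeline:
    def test_ground_truth_recovered(self):
        spec = FixtureSpec(seed=37, model_spec=ModelSpec(
            n_identical=2, n_proton_variants=2, n_stoich_variants=1,
            n_new_pathways=2, n_dead_end_chains=2, dead_end_chain_length=3,
            n_prunable=2))
        recipient, donor, gt = gen_model(spec)
        merged, rep = merge_pipeline(recipient, [(donor, gen_ortholog_map(spec))])
        assert sorted(rep.transferred_reaction_ids) == sorted(gt.transfer_ids)
        assert sorted(rep.dead_end_removed_reaction_ids) == sorted(gt.dead_end_removed_ids)
        assert rep.transfers_skipped_proton == len(gt.proton_variant_ids)
        assert rep.transfers_skipped_stoich == len(gt.stoich_variant_ids)
        assert rep.genes_deleted == len(gt.pruned_gene_ids)
        assert (len(merged.genes), len(merged.reactions), len(merged.metabolites)) \
            == (gt.final_n_genes, gt.final_n_reactions, gt.final_n_metabolites)

    def test_second_donor_identical_reaction_not_duplicated(self):
        spec = FixtureSpec(seed=38, model_spec=ModelSpec(
            n_new_pathways=1, n_dead_end_chains=0, n_prunable=0))
        recipient, donor, gt = gen_model(spec)
        omap = gen_ortholog_map(spec)
        merged, rep = merge_pipeline(recipient, [(donor, omap), (donor, omap)])
        assert rep.reactions_transferred == len(gt.transfer_ids)
        assert rep.per_donor[1]["reactions_transferred"] == 0
        assert rep.per_donor[1]["transfers_skipped_identical"] >= len(gt.transfer_ids)

    def test_empty_donor_list_runs_dead_end_pass_only(self):
        recipient, _, _ = gen_model(FixtureSpec(seed=39))
        merged, rep = merge_pipeline(recipient, [])
        assert rep.reactions_transferred == 0
        assert set(merged.reactions) == set(recipient.reactions)
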