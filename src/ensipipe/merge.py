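"""Homology-guided metabolic-model expansion.

A draft (recipient) reconstruction is expanded from curated donor models in
three steps:

1. **Orthology pruning** — donor genes without an ortholog in the recipient
   organism are deleted; reactions whose GPR becomes unsatisfiable are
   removed, surviving GPRs are simplified.
2. **Unique-reaction transfer** — each remaining donor reaction is compared
   to the recipient's reactions by canonical equation signature. Reactions
   identical to an existing one, or differing only by a proton or only in
   stoichiometric coefficients, are skipped; genuinely distinct reactions
   are copied with their bounds, and their GPR gene literals rewritten to
   the recipient's ortholog names.
3. **Dead-end pruning** — after all donors are merged, reactions touching
   dead-end metabolites (those that cannot be both produced and consumed
   under the declared directionalities) are removed iteratively to a
   fixpoint.

The participant interpretation of step 3 (remove every reaction a dead-end
metabolite participates in) is the default because it is idempotent; the
narrower producer-only behaviour is available via ``mode="producer"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd
from typing import Mapping, Sequence

from .errors import DataError, StageError
from .models import (MetabolicModel, Reaction, gpr_genes, rewrite_gpr,
                     simplify_gpr_removing)

logger = logging.getLogger(__name__)

DEFAULT_PROTON_IDS = frozenset({"h", "h+", "proton"})

IDENTICAL = "identical"
PROTON_VARIANT = "proton_variant"
STOICH_VARIANT = "stoich_variant"
DISTINCT = "distinct"


def _strip_compartment(met_id: str) -> str:
    """Drop a trailing _<compartment> or [<compartment>] suffix."""
    if met_id.endswith("]") and "[" in met_id:
        return met_id[:met_id.rindex("[")]
    if "_" in met_id:
        return met_id[:met_id.rindex("_")]
    return met_id


def is_proton(met_id: str, proton_ids: frozenset = DEFAULT_PROTON_IDS) -> bool:
    return _strip_compartment(met_id).lower() in proton_ids


def _normalized_coefficients(stoich: Mapping[str, float]) -> dict[str, Fraction]:
    fracs = {m: Fraction(c).limit_denominator(10**6) for m, c in stoich.items()}
    nums = [f.numerator for f in fracs.values()]
    dens = [f.denominator for f in fracs.values()]
    g = 0
    for n in nums:
        g = gcd(g, abs(n))
    l = 1
    for d in dens:
        l = l * d // gcd(l, d)
    scale = Fraction(l, g if g else 1)
    return {m: f * scale for m, f in fracs.items()}


def reaction_signature(r: Reaction, ignore_protons: bool = False,
                       ignore_coefficients: bool = False,
                       proton_ids: frozenset = DEFAULT_PROTON_IDS) -> str:
    """Canonical equation string. Metabolites are sorted per side,
    coefficients GCD-normalized, a backwards-only reaction is flipped, and a
    reversible reaction is oriented so its lexicographically smaller side is
    on the left — so equal signatures mean equal equations under the flags."""
    stoich = dict(r.stoichiometry)
    if ignore_protons:
        stoich = {m: c for m, c in stoich.items() if not is_proton(m, proton_ids)}
    if not stoich:
        return "<empty>"
    backwards_only = r.upper_bound <= 0 and r.lower_bound < 0
    if backwards_only:
        stoich = {m: -c for m, c in stoich.items()}
    coefs = _normalized_coefficients(stoich)

    def side(items) -> str:
        parts = []
        for m in sorted(items):
            c = abs(coefs[m])
            parts.append(m if (ignore_coefficients or c == 1) else f"{c} {m}")
        return " + ".join(parts)

    left = side([m for m, c in coefs.items() if c < 0])
    right = side([m for m, c in coefs.items() if c > 0])
    if r.reversible:
        if right < left:
            left, right = right, left
        arrow = "<=>"
    else:
        arrow = "=>"
    return f"{left} {arrow} {right}"


def classify_match(r1: Reaction, r2: Reaction,
                   proton_ids: frozenset = DEFAULT_PROTON_IDS) -> str:
    """Symmetric comparison of two reactions by equation.

    identical: full signatures equal. proton_variant: signatures equal once
    protons are dropped. stoich_variant: same metabolite sets (ignoring
    protons) but different coefficients. distinct: anything else."""
    if reaction_signature(r1) == reaction_signature(r2):
        return IDENTICAL
    if (reaction_signature(r1, ignore_protons=True, proton_ids=proton_ids)
            == reaction_signature(r2, ignore_protons=True, proton_ids=proton_ids)):
        return PROTON_VARIANT
    mets1 = {m for m in r1.stoichiometry if not is_proton(m, proton_ids)}
    mets2 = {m for m in r2.stoichiometry if not is_proton(m, proton_ids)}
    if mets1 == mets2:
        return STOICH_VARIANT
    return DISTINCT


@dataclass
class MergeReport:
    genes_deleted: int = 0
    reactions_removed_by_pruning: int = 0
    reactions_transferred: int = 0
    transfers_skipped_identical: int = 0
    transfers_skipped_proton: int = 0
    transfers_skipped_stoich: int = 0
    dead_end_reactions_removed: int = 0
    dead_end_metabolites_removed: int = 0
    transferred_reaction_ids: list = field(default_factory=list)
    dead_end_removed_reaction_ids: list = field(default_factory=list)
    per_donor: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, list) else v)
                for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# orthology pruning
# ---------------------------------------------------------------------------

def prune_by_orthology(donor: MetabolicModel,
                       ortholog_map: Mapping[str, str]) -> tuple[MetabolicModel, MergeReport]:
    """Delete donor genes without a recipient ortholog and the reactions
    their loss makes unsatisfiable; simplify surviving GPRs; drop orphan
    metabolites. The input model is not modified."""
    pruned = donor.copy()
    deleted = {g for g in pruned.genes if g not in ortholog_map}
    report = MergeReport(genes_deleted=len(deleted))
    pruned.genes -= deleted
    removed = []
    for rid in sorted(pruned.reactions):
        r = pruned.reactions[rid]
        if not r.gpr.strip():
            continue
        new_gpr = simplify_gpr_removing(r.gpr, deleted)
        if new_gpr is None:
            removed.append(rid)
        else:
            r.gpr = new_gpr
    for rid in removed:
        del pruned.reactions[rid]
    report.reactions_removed_by_pruning = len(removed)
    pruned.remove_orphan_metabolites()
    return pruned, report


# ---------------------------------------------------------------------------
# unique-reaction transfer
# ---------------------------------------------------------------------------

def transfer_unique_reactions(
    recipient: MetabolicModel,
    donor: MetabolicModel,
    ortholog_map: Mapping[str, str],
    proton_ids: frozenset = DEFAULT_PROTON_IDS,
) -> tuple[MetabolicModel, MergeReport]:
    """Copy donor reactions that are distinct from every reaction already in
    the (running) recipient. A donor reaction matching an existing one as
    identical / proton variant / stoichiometry variant is skipped and
    counted. Transferred GPRs are rewritten donor-gene -> recipient-ortholog
    (an unmapped literal is an error); bounds travel with the reaction; new
    metabolites and genes are added; an id collision gets a deterministic
    ``_transferred`` suffix."""
    merged = recipient.copy()
    report = MergeReport()
    for rid in sorted(donor.reactions):
        r = donor.reactions[rid]
        cls = DISTINCT
        for other in merged.reactions.values():
            c = classify_match(r, other, proton_ids)
            if c == IDENTICAL:
                cls = IDENTICAL
                break
            if c == PROTON_VARIANT and cls != IDENTICAL:
                cls = PROTON_VARIANT
            elif c == STOICH_VARIANT and cls == DISTINCT:
                cls = STOICH_VARIANT
        if cls == IDENTICAL:
            report.transfers_skipped_identical += 1
            continue
        if cls == PROTON_VARIANT:
            report.transfers_skipped_proton += 1
            continue
        if cls == STOICH_VARIANT:
            report.transfers_skipped_stoich += 1
            continue
        new = r.copy()
        try:
            new.gpr = rewrite_gpr(r.gpr, ortholog_map)
        except DataError as e:
            raise StageError(
                f"donor reaction {rid!r} survived pruning with an unmapped gene: {e}") from e
        if new.id in merged.reactions:
            new_id = f"{new.id}_transferred"
            logger.warning("reaction id collision: %s stored as %s", new.id, new_id)
            new.id = new_id
        for met in new.stoichiometry:
            if met not in merged.metabolites:
                merged.metabolites[met] = donor.metabolites[met]
        merged.genes |= gpr_genes(new.gpr)
        merged.reactions[new.id] = new
        report.reactions_transferred += 1
        report.transferred_reaction_ids.append(new.id)
    return merged, report


# ---------------------------------------------------------------------------
# dead-end metabolite pruning
# ---------------------------------------------------------------------------

def find_dead_end_metabolites(m: MetabolicModel) -> set[str]:
    """Metabolites that cannot be both produced and consumed. A reaction
    whose forward direction is open (ub > 0) produces its positive- and
    consumes its negative-coefficient participants; an open reverse
    direction (lb < 0) does the opposite. Exchange reactions count the same
    way through their bounds."""
    producible: set[str] = set()
    consumable: set[str] = set()
    for r in m.reactions.values():
        for met, coef in r.stoichiometry.items():
            if r.upper_bound > 0:
                (producible if coef > 0 else consumable).add(met)
            if r.lower_bound < 0:
                (producible if coef < 0 else consumable).add(met)
    return {mid for mid in m.metabolites if not (mid in producible and mid in consumable)}


def remove_dead_ends(m: MetabolicModel, mode: str = "participant"
                     ) -> tuple[MetabolicModel, list[str], list[str]]:
    """Iteratively remove reactions touching dead-end metabolites until a
    pass removes nothing. ``mode="participant"`` (default) removes every
    reaction a dead-end participates in; ``mode="producer"`` removes only
    reactions that can produce it. Removing the objective reaction is a hard
    error naming the metabolites responsible."""
    if mode not in ("participant", "producer"):
        raise DataError(f"unknown dead-end mode {mode!r}")
    out = m.copy()
    removed_reactions: list[str] = []
    removed_metabolites: list[str] = []
    while True:
        dead = find_dead_end_metabolites(out)
        to_remove = set()
        for rid, r in out.reactions.items():
            for met, coef in r.stoichiometry.items():
                if met not in dead:
                    continue
                if mode == "participant":
                    to_remove.add(rid)
                    break
                produces = (coef > 0 and r.upper_bound > 0) or (coef < 0 and r.lower_bound < 0)
                if produces:
                    to_remove.add(rid)
                    break
        if not to_remove:
            break
        if out.objective_reaction in to_remove:
            culprits = sorted(set(out.reactions[out.objective_reaction].stoichiometry) & dead)
            raise StageError(
                f"dead-end pruning would remove the objective reaction "
                f"{out.objective_reaction!r} via dead-end metabolites {culprits}")
        for rid in sorted(to_remove):
            del out.reactions[rid]
            removed_reactions.append(rid)
        removed_metabolites.extend(out.remove_orphan_metabolites())
    return out, removed_reactions, removed_metabolites


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def merge_pipeline(
    draft: MetabolicModel,
    donors: Sequence[tuple[MetabolicModel, Mapping[str, str]]],
    proton_ids: frozenset = DEFAULT_PROTON_IDS,
    dead_end_mode: str = "participant",
    dead_ends_per_donor: bool = False,
) -> tuple[MetabolicModel, MergeReport]:
    """Expand the draft from each donor in order (orthology pruning then
    unique-reaction transfer), and run dead-end pruning to a fixpoint once
    after all transfers (or after each donor with
    ``dead_ends_per_donor=True``)."""
    model = draft.copy()
    model.validate()
    total = MergeReport()
    for donor, ortho in donors:
        pruned, prune_rep = prune_by_orthology(donor, ortho)
        model, transfer_rep = transfer_unique_reactions(model, pruned, ortho, proton_ids)
        if dead_ends_per_donor:
            model, rxns, mets = remove_dead_ends(model, dead_end_mode)
            total.dead_end_reactions_removed += len(rxns)
            total.dead_end_metabolites_removed += len(mets)
            total.dead_end_removed_reaction_ids.extend(rxns)
        total.genes_deleted += prune_rep.genes_deleted
        total.reactions_removed_by_pruning += prune_rep.reactions_removed_by_pruning
        total.reactions_transferred += transfer_rep.reactions_transferred
        total.transfers_skipped_identical += transfer_rep.transfers_skipped_identical
        total.transfers_skipped_proton += transfer_rep.transfers_skipped_proton
        total.transfers_skipped_stoich += transfer_rep.transfers_skipped_stoich
        total.transferred_reaction_ids.extend(transfer_rep.transferred_reaction_ids)
        total.per_donor.append({
            "donor": donor.id,
            "genes_deleted": prune_rep.genes_deleted,
            "reactions_removed_by_pruning": prune_rep.reactions_removed_by_pruning,
            "reactions_transferred": transfer_rep.reactions_transferred,
            "transfers_skipped_identical": transfer_rep.transfers_skipped_identical,
            "transfers_skipped_proton": transfer_rep.transfers_skipped_proton,
            "transfers_skipped_stoich": transfer_rep.transfers_skipped_stoich,
        })
    if not dead_ends_per_donor:
        model, rxns, mets = remove_dead_ends(model, dead_end_mode)
        total.dead_end_reactions_removed += len(rxns)
        total.dead_end_metabolites_removed += len(mets)
        total.dead_end_removed_reaction_ids.extend(rxns)
    model.validate()
    return model, total
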