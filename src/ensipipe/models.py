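"""Genome-scale metabolic model container and GPR boolean rules.

The model is a plain stoichiometric structure: metabolites (with compartment
suffixes in their ids), reactions with signed stoichiometry (negative =
consumed, positive = produced), flux bounds, a boolean gene-protein-reaction
(GPR) rule per reaction, and one declared objective reaction. JSON is the
native serialization:

    {"id": ..., "genes": [...],
     "metabolites": [{"id","name","compartment"}],
     "reactions": [{"id","stoichiometry":{met:coef},"lower_bound",
                    "upper_bound","gpr","is_exchange"}],
     "objective": reaction_id}

GPR rules are strings over gene ids with ``and``/``or`` and parentheses; an
empty rule means the reaction is not gene-constrained and always available.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import DataError, GprParseError

# ---------------------------------------------------------------------------
# GPR parsing and evaluation
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|\band\b|\bor\b|[^\s()]+)", re.IGNORECASE)


def _tokenize(expr: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m:
            break
        tok = m.group(1)
        low = tok.lower()
        if tok == "(":
            kind = "lparen"
        elif tok == ")":
            kind = "rparen"
        elif low in ("and", "or"):
            kind = low
        else:
            kind = "gene"
        tokens.append((kind, tok, m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(expr: str):
    """Parse a GPR string into an AST of nested tuples:
    ``("gene", id)``, ``("and", [children])``, ``("or", [children])``;
    ``None`` for the empty rule. ``or`` binds looser than ``and``."""
    if expr is None or not expr.strip():
        return None
    tokens = _tokenize(expr)
    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else ("end", "", len(expr))

    def parse_or():
        nonlocal idx
        terms = [parse_and()]
        while peek()[0] == "or":
            idx += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and():
        nonlocal idx
        terms = [parse_atom()]
        while peek()[0] == "and":
            idx += 1
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else ("and", terms)

    def parse_atom():
        nonlocal idx
        kind, tok, pos = peek()
        if kind == "lparen":
            idx += 1
            node = parse_or()
            kind2, _, pos2 = peek()
            if kind2 != "rparen":
                raise GprParseError("expected ')'", pos2)
            idx += 1
            return node
        if kind == "gene":
            idx += 1
            return ("gene", tok)
        raise GprParseError(f"unexpected token {tok!r}" if tok else "unexpected end of expression", pos)

    tree = parse_or()
    kind, tok, pos = peek()
    if kind != "end":
        raise GprParseError(f"unexpected token {tok!r}", pos)
    return tree


def evaluate_gpr(gpr: str, present_genes: set[str]) -> bool:
    """Boolean GPR semantics; the empty rule is true (not gene-constrained)."""
    tree = parse_gpr(gpr)

    def ev(node) -> bool:
        if node is None:
            return True
        kind = node[0]
        if kind == "gene":
            return node[1] in present_genes
        vals = (ev(c) for c in node[1])
        return all(vals) if kind == "and" else any(vals)

    return ev(tree)


def gpr_genes(gpr: str) -> set[str]:
    tree = parse_gpr(gpr)
    out: set[str] = set()

    def walk(node):
        if node is None:
            return
        if node[0] == "gene":
            out.add(node[1])
        else:
            for c in node[1]:
                walk(c)

    walk(tree)
    return out


def _render(node) -> str:
    if node[0] == "gene":
        return node[1]
    joiner = f" {node[0]} "
    parts = []
    for c in node[1]:
        s = _render(c)
        if c[0] in ("and", "or") and c[0] != node[0]:
            s = f"({s})"
        parts.append(s)
    return joiner.join(parts)


def simplify_gpr_removing(gpr: str, deleted_genes: set[str]) -> str | None:
    """Rewrite a GPR with the deleted genes fixed to false and the result
    simplified. Returns the simplified rule string, ``""`` when the whole
    rule collapses to true (cannot happen here since genes only turn false),
    or ``None`` when the rule is unsatisfiable (reaction must go)."""
    tree = parse_gpr(gpr)
    if tree is None:
        return ""

    FALSE = ("false",)

    def simp(node):
        if node[0] == "gene":
            return FALSE if node[1] in deleted_genes else node
        children = [simp(c) for c in node[1]]
        if node[0] == "and":
            if any(c == FALSE for c in children):
                return FALSE
            kept = children
        else:  # or
            kept = [c for c in children if c != FALSE]
            if not kept:
                return FALSE
        return kept[0] if len(kept) == 1 else (node[0], kept)

    res = simp(tree)
    if res == FALSE:
        return None
    return _render(res)


def rewrite_gpr(gpr: str, gene_map: Mapping[str, str]) -> str:
    """Substitute every gene literal through ``gene_map``; a literal missing
    from the map is an error (silent dropping would fabricate biology)."""
    tree = parse_gpr(gpr)
    if tree is None:
        return ""

    def sub(node):
        if node[0] == "gene":
            g = node[1]
            if g not in gene_map:
                raise DataError(f"GPR references unmapped gene {g!r}")
            return ("gene", gene_map[g])
        return (node[0], [sub(c) for c in node[1]])

    return _render(sub(tree))


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.compartment:
            raise DataError(f"metabolite {self.id!r}: empty compartment")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict
    lower_bound: float
    upper_bound: float
    gpr: str = ""
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise DataError(f"reaction {self.id!r}: lower_bound > upper_bound")
        self.stoichiometry = {m: float(c) for m, c in self.stoichiometry.items() if c != 0}
        if not self.stoichiometry and not self.is_exchange:
            raise DataError(f"reaction {self.id!r}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return Reaction(id=self.id, stoichiometry=dict(self.stoichiometry),
                        lower_bound=self.lower_bound, upper_bound=self.upper_bound,
                        gpr=self.gpr, is_exchange=self.is_exchange)


@dataclass
class MetabolicModel:
    id: str
    genes: set = field(default_factory=set)
    reactions: dict = field(default_factory=dict)
    metabolites: dict = field(default_factory=dict)
    objective_reaction: str = ""

    def validate(self) -> None:
        if self.objective_reaction and self.objective_reaction not in self.reactions:
            raise DataError(f"objective reaction {self.objective_reaction!r} missing")
        for r in self.reactions.values():
            for m in r.stoichiometry:
                if m not in self.metabolites:
                    raise DataError(f"reaction {r.id!r} references unknown metabolite {m!r}")
            for g in gpr_genes(r.gpr):
                if g not in self.genes:
                    raise DataError(f"reaction {r.id!r} GPR references unknown gene {g!r}")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id, genes=set(self.genes),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            metabolites={mid: copy.copy(m) for mid, m in self.metabolites.items()},
            objective_reaction=self.objective_reaction)

    def remove_orphan_metabolites(self) -> list[str]:
        used: set[str] = set()
        for r in self.reactions.values():
            used |= set(r.stoichiometry)
        orphans = sorted(set(self.metabolites) - used)
        for m in orphans:
            del self.metabolites[m]
        return orphans

    # -- JSON serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "genes": sorted(self.genes),
            "metabolites": [{"id": m.id, "name": m.name, "compartment": m.compartment}
                            for m in sorted(self.metabolites.values(), key=lambda x: x.id)],
            "reactions": [{"id": r.id,
                           "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                           "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
                           "gpr": r.gpr, "is_exchange": r.is_exchange}
                          for r in sorted(self.reactions.values(), key=lambda x: x.id)],
            "objective": self.objective_reaction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolicModel":
        model = cls(
            id=d.get("id", "model"),
            genes=set(d.get("genes", [])),
            metabolites={m["id"]: Metabolite(id=m["id"], name=m.get("name", ""),
                                             compartment=m.get("compartment", "c"))
                         for m in d.get("metabolites", [])},
            reactions={r["id"]: Reaction(id=r["id"],
                                         stoichiometry=dict(r["stoichiometry"]),
                                         lower_bound=float(r["lower_bound"]),
                                         upper_bound=float(r["upper_bound"]),
                                         gpr=r.get("gpr", ""),
                                         is_exchange=bool(r.get("is_exchange", False)))
                       for r in d.get("reactions", [])},
            objective_reaction=d.get("objective", ""),
        )
        model.validate()
        return model

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MetabolicModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
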