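"""Seeded synthetic fixtures with planted ground truth.

Every input the pipeline consumes can be generated here with known answers:
scaffold sets with chosen length/GC/coverage structure, genome pairs with a
planted substitution divergence (so the true ANI is ``100 * (1 -
divergence)`` exactly — substitution-only, no indels), reciprocal hit tables
whose best-hit structure is unambiguous (decoys strictly dominated in
bitscore, ties never planted), presence/absence matrices with planted
core/unique/island structure, and recipient/donor metabolic-model pairs with
planted match classes, transferable pathways and dead-end chains.

The generators emulate the *statistical* structure the pipeline assumes, not
biology: no codon structure, no gene content realism, no phylogenetic
signal. Same seed + same spec regenerates byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import Scaffold, write_fasta_scaffolds
from .errors import ConfigurationError
from .fba import MediumSpec
from .homology import SimilarityHit, write_hit_table
from .models import MetabolicModel, Metabolite, Reaction
from .pangenome import GeneLocation, PresenceAbsenceMatrix
from .symbiosis import HmmHit

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ModelSpec:
    """Planted structure of the recipient/donor model pair."""

    n_dead_end_chains: int = 1
    dead_end_chain_length: int = 3
    n_proton_variants: int = 1
    n_stoich_variants: int = 1
    n_identical: int = 1
    n_new_pathways: int = 1  # each pathway = two transferable reactions
    n_prunable: int = 1

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ConfigurationError(f"model spec field {f.name} must be >= 0")
        if self.n_dead_end_chains and self.dead_end_chain_length < 1:
            raise ConfigurationError("dead_end_chain_length must be >= 1")


@dataclass
class FixtureSpec:
    seed: int = 0
    # assembly
    n_scaffolds: int = 5
    length_range: tuple = (5000, 20000)
    gc_target: float = 0.6
    coverage_range: tuple = (20.0, 200.0)
    # divergent pair
    divergence: float = 0.02
    # hit tables
    n_orthologs: int = 20
    ortholog_identity: float = 85.0
    ortholog_identity_spread: float = 1.0
    ortholog_coverage: float = 100.0
    ortholog_evalue: float = 1e-50
    n_decoys: int = 2
    # presence/absence
    n_strains: int = 4
    strain_names: tuple | None = None
    n_core_families: int = 10
    n_unique_families: int = 3
    shared_blocks: tuple = ()  # ((strain indices), count), focal strain is index 0
    island_spec: tuple = ()  # (scaffold_index, first_gene_rank, n_genes)
    # metabolic models
    model_spec: ModelSpec = field(default_factory=ModelSpec)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_scaffolds < 0 or self.n_orthologs < 0 or self.n_decoys < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.n_core_families < 0 or self.n_unique_families < 0:
            raise ConfigurationError("family counts must be >= 0")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("length_range must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ConfigurationError("gc_target must be in [0, 1]")
        if not 0.0 <= self.divergence <= 1.0:
            raise ConfigurationError("divergence must be in [0, 1]")
        clo, chi = self.coverage_range
        if not (0 <= clo <= chi):
            raise ConfigurationError("coverage_range must satisfy 0 <= lo <= hi")
        if self.n_strains < 2:
            raise ConfigurationError("presence/absence fixtures need >= 2 strains")
        if self.strain_names is not None and len(self.strain_names) != self.n_strains:
            raise ConfigurationError("strain_names length must equal n_strains")
        for idx_tuple, count in self.shared_blocks:
            if count < 0 or any(not 0 <= i < self.n_strains for i in idx_tuple):
                raise ConfigurationError(f"invalid shared block {(idx_tuple, count)}")
        self.model_spec.validate()

    @property
    def strains(self) -> list[str]:
        if self.strain_names is not None:
            return list(self.strain_names)
        return [f"S{i + 1}" for i in range(self.n_strains)]


# ---------------------------------------------------------------------------
# assemblies and divergent genome pairs
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def gen_assembly(spec: FixtureSpec) -> list[Scaffold]:
    """Scaffolds with uniform lengths in ``length_range``, per-base GC equal
    to ``gc_target`` in expectation, and uniform coverage."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    clo, chi = spec.coverage_range
    out = []
    for i in range(spec.n_scaffolds):
        length = int(rng.integers(lo, hi + 1))
        cov = float(rng.uniform(clo, chi))
        seq = _decode(_random_sequence(rng, length, spec.gc_target))
        out.append(Scaffold(id=f"scaffold_{i + 1}", sequence=seq, coverage=cov))
    return out


def gen_divergent_pair(spec: FixtureSpec) -> tuple[list[str], list[str], float]:
    """A genome and a copy with independent per-base substitutions at rate
    ``divergence`` (replacement uniform over the three alternatives; no
    indels). The planted ANI is exactly ``1 - divergence``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    genome_a, genome_b = [], []
    for _ in range(spec.n_scaffolds):
        length = int(rng.integers(lo, hi + 1))
        a = _random_sequence(rng, length, spec.gc_target)
        mask = rng.random(length) < spec.divergence
        shift = rng.integers(1, 4, size=length).astype(np.uint8)
        b = np.where(mask, (a + shift) % 4, a).astype(np.uint8)
        genome_a.append(_decode(a))
        genome_b.append(_decode(b))
    return genome_a, genome_b, 1.0 - spec.divergence


# ---------------------------------------------------------------------------
# reciprocal hit tables
# ---------------------------------------------------------------------------

def gen_hit_tables(spec: FixtureSpec) -> tuple[list[SimilarityHit], list[SimilarityHit], list[tuple]]:
    """Hit tables in which the planted ortholog pairs are reciprocal best
    hits at the configured identity/coverage/e-value, and every decoy hit is
    strictly dominated in bitscore (never tied). Each planted pair is
    recoverable by BBH at thresholds at or below the planted levels."""
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_orthologs
    qlens = rng.integers(200, 401, size=n)
    idents = np.clip(rng.uniform(spec.ortholog_identity - spec.ortholog_identity_spread,
                                 spec.ortholog_identity + spec.ortholog_identity_spread,
                                 size=n), 0.0, 100.0)
    hits_ab: list[SimilarityHit] = []
    hits_ba: list[SimilarityHit] = []
    planted: list[tuple] = []
    for i in range(n):
        a, b = f"A_{i + 1:04d}", f"B_{i + 1:04d}"
        qlen = int(qlens[i])
        alen = max(1, round(spec.ortholog_coverage / 100.0 * qlen))
        ident = float(round(idents[i], 2))
        score = 400.0 + i
        for hits, q, s in ((hits_ab, a, b), (hits_ba, b, a)):
            hits.append(SimilarityHit(
                query_id=q, subject_id=s, percent_identity=ident,
                alignment_length=alen, evalue=spec.ortholog_evalue,
                bitscore=score, query_length=qlen, subject_length=qlen))
        planted.append((a, b, ident))
    # decoys: strictly worse bitscore, pointing at other proteins
    if n > 1:
        for i in range(n):
            for k in range(spec.n_decoys):
                j = (i + k + 1) % n
                if j == i:
                    continue
                qlen = int(qlens[i])
                decoy_score = 150.0 - (i * spec.n_decoys + k) * 1e-3
                ident = float(round(rng.uniform(30, 60), 2))
                alen = max(1, int(0.5 * qlen))
                hits_ab.append(SimilarityHit(
                    query_id=f"A_{i + 1:04d}", subject_id=f"B_{j + 1:04d}",
                    percent_identity=ident, alignment_length=alen,
                    evalue=1e-8, bitscore=decoy_score,
                    query_length=qlen, subject_length=int(qlens[j])))
                hits_ba.append(SimilarityHit(
                    query_id=f"B_{i + 1:04d}", subject_id=f"A_{j + 1:04d}",
                    percent_identity=ident, alignment_length=alen,
                    evalue=1e-8, bitscore=decoy_score,
                    query_length=qlen, subject_length=int(qlens[j])))
    return hits_ab, hits_ba, planted


# ---------------------------------------------------------------------------
# presence/absence matrices with planted core / unique / island structure
# ---------------------------------------------------------------------------

@dataclass
class PangenomeFixture:
    matrix: PresenceAbsenceMatrix
    locations: list  # GeneLocation of every focal-strain gene, in order
    gene_map: dict  # family -> focal gene id
    core_truth: set
    unique_truth: set
    island_truth: list  # (scaffold_id, first_gene_rank, last_gene_rank, n_genes)


_GENE_LEN = 900
_GENE_SPACING = 1500
_SCATTER_SPACING = 12  # slots between scattered unique genes (>> any sane gap)


def gen_presence_absence(spec: FixtureSpec) -> PangenomeFixture:
    """Matrix with exactly ``n_core_families`` all-present rows, exactly
    ``n_unique_families`` focal-only rows and the configured shared blocks.
    Island entries place unique-family genes contiguously at declared gene
    ranks of declared scaffolds; remaining unique genes are scattered with
    wide spacing so the planted islands are the only clusters."""
    strains = spec.strains
    focal = strains[0]
    rng = np.random.default_rng(spec.seed + 2)

    families: list[str] = []
    rows: list[list[bool]] = []
    core = [f"core_{i + 1:05d}" for i in range(spec.n_core_families)]
    for fam in core:
        families.append(fam)
        rows.append([True] * len(strains))
    unique = [f"unique_{i + 1:05d}" for i in range(spec.n_unique_families)]
    for fam in unique:
        families.append(fam)
        rows.append([s == focal for s in strains])
    for block_no, (idx_tuple, count) in enumerate(spec.shared_blocks):
        present = set(idx_tuple)
        for i in range(count):
            families.append(f"shared{block_no + 1}_{i + 1:05d}")
            rows.append([k in present for k in range(len(strains))])
    presence = pd.DataFrame(rows, index=families, columns=strains)
    matrix = PresenceAbsenceMatrix.from_frame(presence)

    # ---- focal gene layout -------------------------------------------------
    focal_families = [f for f, row in zip(families, rows) if row[0]]
    n_focal = len(focal_families)
    n_scaf = max(1, spec.n_scaffolds)
    per_scaffold = -(-n_focal // n_scaf)  # ceil
    # one slot per focal gene: (scaffold index, rank within scaffold)
    slots = [(s, r) for s in range(n_scaf) for r in range(per_scaffold)][:n_focal]
    n_ranks = per_scaffold

    # islands claim their declared slots
    slot_set = set(slots)
    claimed: dict[tuple, str] = {}
    island_truth = []
    spans_per_scaffold: dict[int, list[tuple]] = {}
    unique_iter = iter(unique)
    for scaf_idx, first_rank, n_genes in spec.island_spec:
        if not 0 <= scaf_idx < n_scaf:
            raise ConfigurationError(f"island scaffold index {scaf_idx} out of range")
        if first_rank < 0 or first_rank + n_genes > n_ranks:
            raise ConfigurationError("island span falls outside the scaffold gene ranks")
        for lo, hi in spans_per_scaffold.get(scaf_idx, []):
            if first_rank <= hi and lo <= first_rank + n_genes - 1:
                raise ConfigurationError("overlapping island spans")
        spans_per_scaffold.setdefault(scaf_idx, []).append(
            (first_rank, first_rank + n_genes - 1))
        for r in range(first_rank, first_rank + n_genes):
            if (scaf_idx, r) not in slot_set:
                raise ConfigurationError("island span exceeds the focal gene count")
            try:
                fam = next(unique_iter)
            except StopIteration:
                raise ConfigurationError(
                    "island_spec requires more unique families than n_unique_families") from None
            claimed[(scaf_idx, r)] = fam
        island_truth.append((f"scaffold_{scaf_idx + 1}", first_rank,
                             first_rank + n_genes - 1, n_genes))

    # Scatter the remaining unique families at an even stride over the free
    # slots. With planted islands the stride must be wide enough that no
    # accidental cluster rivals them; without islands any stride is fine.
    remaining_unique = list(unique_iter)
    free = [
        (scaf_idx, rank) for scaf_idx, rank in slots
        if (scaf_idx, rank) not in claimed
        and not any(lo - _SCATTER_SPACING <= rank <= hi + _SCATTER_SPACING
                    for lo, hi in spans_per_scaffold.get(scaf_idx, []))]
    if remaining_unique:
        if not free:
            raise ConfigurationError("no free gene slots left for unique families")
        stride = len(free) // len(remaining_unique)
        if stride < 1:
            raise ConfigurationError(
                "more unique families than available gene slots")
        if spec.island_spec and stride < _SCATTER_SPACING:
            raise ConfigurationError(
                "not enough isolated gene slots to scatter the non-island unique "
                "families without rivalling the planted islands; increase "
                "n_core_families or n_scaffolds")
        for i, fam in enumerate(remaining_unique):
            claimed[free[i * stride]] = fam

    # everything else fills in deterministic order
    fill_iter = iter([f for f in focal_families if f not in unique])
    assignment: dict[tuple, str] = {}
    for slot in slots:
        assignment[slot] = claimed.get(slot) or next(fill_iter)

    locations, gene_map = [], {}
    rep_gene: dict[str, dict[str, str]] = {}
    for (scaf_idx, rank) in slots:
        fam = assignment[(scaf_idx, rank)]
        gid = f"{focal}_{scaf_idx + 1:02d}_{rank + 1:05d}"
        start = rank * _GENE_SPACING + 1
        locations.append(GeneLocation(gene_id=gid, scaffold_id=f"scaffold_{scaf_idx + 1}",
                                      start=start, end=start + _GENE_LEN - 1,
                                      strand="+" if rng.random() < 0.5 else "-"))
        gene_map[fam] = gid
        rep_gene.setdefault(fam, {})[focal] = gid
    matrix.representative_gene = rep_gene

    return PangenomeFixture(matrix=matrix, locations=locations, gene_map=gene_map,
                            core_truth=set(core), unique_truth=set(unique),
                            island_truth=island_truth)


# ---------------------------------------------------------------------------
# metabolic model pair with planted merge ground truth
# ---------------------------------------------------------------------------

@dataclass
class MergeGroundTruth:
    identical_ids: list
    proton_variant_ids: list
    stoich_variant_ids: list
    pruned_reaction_ids: list
    pruned_gene_ids: list
    transfer_ids: list  # donor reactions a correct merge transfers
    dead_end_removed_ids: list  # transferred reactions the dead-end pass removes
    dead_end_metabolites: list
    final_n_genes: int
    final_n_reactions: int
    final_n_metabolites: int
    growth_source: str  # carbon exchange on which the final model grows
    no_growth_source: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "MergeGroundTruth":
        return cls(**d)


def gen_model(spec: FixtureSpec) -> tuple[MetabolicModel, MetabolicModel, MergeGroundTruth]:
    """Recipient draft, donor, and the planted merge ground truth.

    The recipient is a glucose-to-biomass chain (growth-capable on its
    glucose exchange, not on the second planted source). The donor carries
    copies of recipient reactions (identical), proton-variant and
    stoichiometry-variant duplicates, transferable two-reaction pathways
    over fresh metabolites, dead-end chains, and reactions constrained by
    unmapped genes (pruned by orthology)."""
    ms = spec.model_spec
    K = max(1, ms.n_identical + ms.n_proton_variants + ms.n_stoich_variants)

    recipient = MetabolicModel(id="draft")
    def met(model, mid, comp):
        model.metabolites[mid] = Metabolite(id=mid, compartment=comp)

    met(recipient, "glc_e", "e"); met(recipient, "glc_c", "c"); met(recipient, "src2_e", "e")
    for j in range(1, K + 1):
        met(recipient, f"m{j}_c", "c")
    recipient.genes = {"gT"} | {f"gC{j}" for j in range(1, K + 1)}
    chain_mets = ["glc_c"] + [f"m{j}_c" for j in range(1, K + 1)]
    recipient.reactions["EX_glc_e"] = Reaction(
        id="EX_glc_e", stoichiometry={"glc_e": -1}, lower_bound=-10, upper_bound=1000,
        is_exchange=True)
    recipient.reactions["EX_src2_e"] = Reaction(
        id="EX_src2_e", stoichiometry={"src2_e": -1}, lower_bound=-10, upper_bound=1000,
        is_exchange=True)
    recipient.reactions["T_glc"] = Reaction(
        id="T_glc", stoichiometry={"glc_e": -1, "glc_c": 1},
        lower_bound=0, upper_bound=1000, gpr="gT")
    for j in range(1, K + 1):
        recipient.reactions[f"C{j}"] = Reaction(
            id=f"C{j}", stoichiometry={chain_mets[j - 1]: -1, chain_mets[j]: 1},
            lower_bound=0, upper_bound=1000, gpr=f"gC{j}")
    recipient.reactions["BIOMASS"] = Reaction(
        id="BIOMASS", stoichiometry={chain_mets[K]: -1},
        lower_bound=0, upper_bound=1000)
    recipient.objective_reaction = "BIOMASS"
    recipient.validate()

    donor = MetabolicModel(id="donor")
    ortholog_map: dict[str, str] = {}
    truth = dict(identical_ids=[], proton_variant_ids=[], stoich_variant_ids=[],
                 pruned_reaction_ids=[], pruned_gene_ids=[], transfer_ids=[],
                 dead_end_removed_ids=[], dead_end_metabolites=[])
    for mid in chain_mets:
        met(donor, mid, "c")
    met(donor, "h_c", "c")

    def donor_rxn(rid, stoich, gene, mapped_to=None):
        if gene:
            donor.genes.add(gene)
            if mapped_to is not None:
                ortholog_map[gene] = mapped_to
        donor.reactions[rid] = Reaction(id=rid, stoichiometry=stoich,
                                        lower_bound=0, upper_bound=1000, gpr=gene or "")

    link = 1
    for i in range(ms.n_identical):
        rid = f"DUP_ident_{i + 1}"
        donor_rxn(rid, {chain_mets[link - 1]: -1, chain_mets[link]: 1},
                  f"gDi{i + 1}", f"gNi{i + 1}")
        truth["identical_ids"].append(rid)
        link += 1
    for i in range(ms.n_proton_variants):
        rid = f"DUP_proton_{i + 1}"
        donor_rxn(rid, {chain_mets[link - 1]: -1, chain_mets[link]: 1, "h_c": 1},
                  f"gDp{i + 1}", f"gNp{i + 1}")
        truth["proton_variant_ids"].append(rid)
        link += 1
    for i in range(ms.n_stoich_variants):
        rid = f"DUP_stoich_{i + 1}"
        donor_rxn(rid, {chain_mets[link - 1]: -1, chain_mets[link]: 2},
                  f"gDs{i + 1}", f"gNs{i + 1}")
        truth["stoich_variant_ids"].append(rid)
        link += 1
    new_gene_names = []
    for p in range(ms.n_new_pathways):
        met(donor, f"alt{p + 1}_c", "c")
        make, use = f"NEW_make_{p + 1}", f"NEW_use_{p + 1}"
        donor_rxn(make, {"glc_c": -1, f"alt{p + 1}_c": 1}, f"gDn{p + 1}a", f"gNn{p + 1}a")
        donor_rxn(use, {f"alt{p + 1}_c": -1, chain_mets[K]: 1}, f"gDn{p + 1}b", f"gNn{p + 1}b")
        truth["transfer_ids"] += [make, use]
        new_gene_names += [f"gNn{p + 1}a", f"gNn{p + 1}b"]
    for c in range(ms.n_dead_end_chains):
        prev = "glc_c"
        for l in range(1, ms.dead_end_chain_length + 1):
            dmet = f"dead{c + 1}_{l}_c"
            met(donor, dmet, "c")
            rid = f"DEAD_{c + 1}_{l}"
            donor_rxn(rid, {prev: -1, dmet: 1}, f"gDd{c + 1}x{l}", f"gNd{c + 1}x{l}")
            truth["transfer_ids"].append(rid)
            truth["dead_end_removed_ids"].append(rid)
            truth["dead_end_metabolites"].append(dmet)
            new_gene_names.append(f"gNd{c + 1}x{l}")
            prev = dmet
    for q in range(ms.n_prunable):
        met(donor, f"prn{q + 1}_c", "c")
        rid = f"PRUNE_{q + 1}"
        donor_rxn(rid, {"glc_c": -1, f"prn{q + 1}_c": 1}, f"gDx{q + 1}", mapped_to=None)
        truth["pruned_reaction_ids"].append(rid)
        truth["pruned_gene_ids"].append(f"gDx{q + 1}")
    donor.validate()

    gt = MergeGroundTruth(
        **truth,
        final_n_genes=len(recipient.genes) + len(new_gene_names),
        final_n_reactions=len(recipient.reactions) + 2 * ms.n_new_pathways,
        final_n_metabolites=len(recipient.metabolites) + ms.n_new_pathways,
        growth_source="EX_glc_e", no_growth_source="EX_src2_e")
    return recipient, donor, gt


def gen_ortholog_map(spec: FixtureSpec) -> dict[str, str]:
    """The donor-gene -> recipient-gene map matching :func:`gen_model`."""
    _, donor, gt = gen_model(spec)
    pruned = set(gt.pruned_gene_ids)
    out = {}
    for g in sorted(donor.genes):
        if g in pruned:
            continue
        # gD<tag> -> gN<tag>: the planted naming convention
        out[g] = "gN" + g[2:]
    return out


def fixture_medium() -> MediumSpec:
    """Base medium for the planted models: both carbon exchanges declared,
    glucose open for growth tests."""
    return MediumSpec(
        exchange_bounds={"EX_glc_e": (-10.0, 1000.0), "EX_src2_e": (0.0, 1000.0)},
        carbon_exchange_ids={"EX_glc_e", "EX_src2_e"})


def gen_synthetic_reference_assembly() -> list[Scaffold]:
    """SYNTHETIC surrogate for the deposited M14 draft assembly.

    Constructs, deterministically and from scratch, a 45-scaffold assembly
    whose summary structure is planted to the published draft-genome
    statistics: 7,345,249 bp total, largest scaffold 4,400,487 bp (so
    N50 = 4,400,487 with L50 = 1), 12 scaffolds over 40 kbp holding 98.7%
    of the length, GC 61.47%, and uniform 118x coverage. The sequences are
    not real genomic sequence — only the length/GC/coverage structure is
    meaningful — so the fixture exercises the statistics code offline
    without the GenBank download.
    """
    total = 7_345_249
    lengths = [4_400_487]
    big_rest = 7_250_000 - 4_400_487  # 12 large scaffolds hold 7,250,000 bp
    lengths += [big_rest // 11 + (1 if i < big_rest % 11 else 0) for i in range(11)]
    small_total = total - 7_250_000
    lengths += [small_total // 33 + (1 if i < small_total % 33 else 0) for i in range(33)]
    assert sum(lengths) == total and len(lengths) == 45
    gc_total = 4_515_125  # 100 * gc / total rounds to 61.47
    scaffolds = []
    gc_assigned = 0
    for i, length in enumerate(lengths):
        if i == len(lengths) - 1:
            g = gc_total - gc_assigned
        else:
            g = round(gc_total * length / total)
        gc_assigned += g
        seq = "G" * g + "A" * (length - g)
        scaffolds.append(Scaffold(id=f"synthetic_ref_{i + 1:02d}", sequence=seq,
                                  coverage=118.0))
    return scaffolds


def build_toy_chain_model(uptake: float = 10.0) -> MetabolicModel:
    """Minimal uptake-limited chain: EX_A (lb -uptake) <-> A, A -> B,
    objective B -> 0. The optimum equals the uptake rate exactly."""
    m = MetabolicModel(id="toy_chain")
    m.metabolites = {"A_e": Metabolite(id="A_e", compartment="e"),
                     "B_c": Metabolite(id="B_c", compartment="c")}
    m.reactions = {
        "EX_A_e": Reaction(id="EX_A_e", stoichiometry={"A_e": -1},
                           lower_bound=-uptake, upper_bound=1000, is_exchange=True),
        "AB": Reaction(id="AB", stoichiometry={"A_e": -1, "B_c": 1},
                       lower_bound=0, upper_bound=1000),
        "OBJ": Reaction(id="OBJ", stoichiometry={"B_c": -1},
                        lower_bound=0, upper_bound=1000),
    }
    m.objective_reaction = "OBJ"
    m.validate()
    return m


# ---------------------------------------------------------------------------
# symbiosis and COG fixtures (deterministic, rule-table driven)
# ---------------------------------------------------------------------------

def make_symbiosis_fixture() -> tuple[list[HmmHit], list[HmmHit], dict]:
    """Seed-search and scan hit tables covering every rule-table accession
    and Pfam name once, plus a non-matching control; returns the expected
    label per query as the third element."""
    cases = [
        ("q_nodA_tigr", "TIGR04245", "TIGR04245_hmm", "NodA"),
        ("q_nodA_pfam", "", "NodA", "NodA"),
        ("q_nodB", "TIGR04243", "TIGR04243_hmm", "NodB"),
        ("q_nodC", "TIGR04242", "TIGR04242_hmm", "NodC"),
        ("q_nifH_tigr", "TIGR01287", "TIGR01287_hmm", "NifH"),
        ("q_nifH_pfam", "", "Fer4_NifH", "NifH"),
        ("q_nifD_1", "TIGR01282", "TIGR01282_hmm", "NifD"),
        ("q_nifD_2", "TIGR01860", "TIGR01860_hmm", "NifD"),
        ("q_nifD_3", "TIGR01861", "TIGR01861_hmm", "NifD"),
        ("q_nifK_1", "TIGR02932", "TIGR02932_hmm", "NifK"),
        ("q_nifK_2", "TIGR02931", "TIGR02931_hmm", "NifK"),
        ("q_nifK_3", "TIGR01286", "TIGR01286_hmm", "NifK"),
        ("q_control", "TIGR99999", "SomeOther_hmm", "none"),
    ]
    seed_hits, scan_hits, expected = [], [], {}
    for i, (query, acc, name, label) in enumerate(cases):
        # seed search: deliberately include a terrible e-value hit
        seed_hits.append(HmmHit(query_id=query, hmm_name="seed_profile",
                                hmm_accession="SEED00001",
                                evalue=5.0 if i % 2 else 1e-40, score=20.0 + i))
        scan_hits.append(HmmHit(query_id=query, hmm_name=name, hmm_accession=acc,
                                evalue=1e-30, score=300.0))
        # a dominated secondary hit that must never change the call
        scan_hits.append(HmmHit(query_id=query, hmm_name="Decoy_profile",
                                hmm_accession="TIGR00001", evalue=1e-5, score=50.0))
        expected[query] = label
    return seed_hits, scan_hits, expected


def fixture_cog_annotations(seed: int, n_genes: int = 300, n_strains: int = 2
                            ) -> list[dict]:
    """Per-strain gene -> COG-letter maps drawn from one shared category
    distribution, so pairwise Fisher tests are planted non-significant in
    expectation."""
    rng = np.random.default_rng(seed + 3)
    cats = list("CEGHIJKLMNOPT")
    weights = rng.dirichlet(np.ones(len(cats)) * 5.0)
    out = []
    for s in range(n_strains):
        genes = {f"st{s + 1}_g{i + 1:04d}": cats[int(rng.choice(len(cats), p=weights))]
                 for i in range(n_genes)}
        out.append(genes)
    return out


# ---------------------------------------------------------------------------
# bundle serialization: the same on-disk formats the pipeline reads
# ---------------------------------------------------------------------------

def write_fixture_bundle(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write a full fixture bundle (FASTA, coverage TSV, hit tables,
    pangenome CSV, GFF3 locations, model JSONs, ortholog map, medium YAML,
    symbiosis tblout files) plus a ``ground_truth.json`` sidecar. Returns
    the ground-truth dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scaffolds = gen_assembly(spec)
    write_fasta_scaffolds(scaffolds, outdir / "assembly.fasta")
    with open(outdir / "coverage.tsv", "w") as fh:
        for s in scaffolds:
            fh.write(f"{s.id}\t{s.coverage:.4f}\n")

    genome_a, genome_b, planted_ani = gen_divergent_pair(spec)
    write_fasta_scaffolds([Scaffold(id=f"A_{i + 1}", sequence=s, coverage=1)
                           for i, s in enumerate(genome_a)], outdir / "genomeA.fasta")
    write_fasta_scaffolds([Scaffold(id=f"B_{i + 1}", sequence=s, coverage=1)
                           for i, s in enumerate(genome_b)], outdir / "genomeB.fasta")

    hits_ab, hits_ba, planted_pairs = gen_hit_tables(spec)
    write_hit_table(hits_ab, outdir / "hits_ab.tsv")
    write_hit_table(hits_ba, outdir / "hits_ba.tsv")

    pan = gen_presence_absence(spec)
    pan.matrix.to_roary_csv(outdir / "gene_presence_absence.csv")
    with open(outdir / "focal_genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in pan.locations:
            fh.write(f"{loc.scaffold_id}\tensipipe\tCDS\t{loc.start}\t{loc.end}"
                     f"\t.\t{loc.strand}\t0\tID={loc.gene_id}\n")

    recipient, donor, merge_truth = gen_model(spec)
    recipient.to_json(outdir / "draft_model.json")
    donor.to_json(outdir / "donor_model.json")
    omap = gen_ortholog_map(spec)
    with open(outdir / "ortholog_map.tsv", "w") as fh:
        for k in sorted(omap):
            fh.write(f"{k}\t{omap[k]}\n")
    fixture_medium().to_yaml(outdir / "medium.yaml")
    with open(outdir / "panel.yaml", "w") as fh:
        fh.write("panel:\n- EX_glc_e\n- EX_src2_e\n")

    seed_hits, scan_hits, sym_expected = make_symbiosis_fixture()
    for name, hits in (("symbiosis_seed.tbl", seed_hits), ("symbiosis_scan.tbl", scan_hits)):
        with open(outdir / name, "w") as fh:
            fh.write("# target_name accession query_name accession evalue score\n")
            for h in hits:
                fh.write(f"{h.hmm_name} {h.hmm_accession or '-'} {h.query_id} - "
                         f"{h.evalue:g} {h.score:g}\n")

    cogs = fixture_cog_annotations(spec.seed)
    for i, ann in enumerate(cogs):
        with open(outdir / f"cog_strain{i + 1}.tsv", "w") as fh:
            for g in sorted(ann):
                fh.write(f"{g}\t{ann[g]}\n")

    truth = {
        "seed": spec.seed,
        "planted_ani_pct": 100.0 * planted_ani,
        "n_scaffolds": spec.n_scaffolds,
        "bbh_pairs": [[a, b] for a, b, _ in planted_pairs],
        "planted_mean_identity": (float(np.mean([i for _, _, i in planted_pairs]))
                                  if planted_pairs else None),
        "core_families": len(pan.core_truth),
        "unique_families": len(pan.unique_truth),
        "islands": [list(t) for t in pan.island_truth],
        "merge": merge_truth.to_dict(),
        "symbiosis_expected": sym_expected,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return truth
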