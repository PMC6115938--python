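"""Pangenome presence/absence analytics and COG-category comparison.

Works on a gene-family x strain boolean matrix (the pangenome CSV dialect:
``Gene, Non-unique Gene name, Annotation,`` then one column per strain whose
cells hold gene ids). Provides core-genome extraction, Venn partitions over
2-4 focal strains, focal-strain unique families, clustering of unique genes
into putative genomic islands along scaffolds, per-strain COG category
profiles, and pairwise Fisher exact comparison of those profiles.

The Fisher test is an exact two-sided test: with the margins fixed, the
p-value is the total hypergeometric probability of every table at most as
probable as the observed one. Weights are compared as exact integers, so no
floating-point tolerance enters the tail definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb, inf, nan
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

# the standard single-letter COG functional categories
COG_CATEGORIES = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


@dataclass
class PresenceAbsenceMatrix:
    """Gene-family x strain boolean table with optional representative genes."""

    families: list[str]
    strains: list[str]
    presence: pd.DataFrame  # bool, index=families, columns=strains
    representative_gene: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.families)) != len(self.families):
            raise DataError("duplicate family ids")
        if len(set(self.strains)) != len(self.strains):
            raise DataError("duplicate strain ids")
        self.presence = self.presence.astype(bool)
        if list(self.presence.index) != self.families or list(self.presence.columns) != self.strains:
            raise DataError("presence frame does not match declared families/strains")
        empty = self.presence.sum(axis=1) == 0
        if empty.any():
            raise DataError(f"families present in no strain: {list(self.presence.index[empty])[:5]}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   representative_gene: dict[str, dict[str, str]] | None = None
                   ) -> "PresenceAbsenceMatrix":
        return cls(families=list(frame.index), strains=list(frame.columns),
                   presence=frame, representative_gene=representative_gene or {})

    @classmethod
    def from_roary_csv(cls, path: str | Path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, dtype=str).fillna("")
        meta_cols = [c for c in df.columns if c in
                     ("Gene", "Non-unique Gene name", "Annotation")]
        if "Gene" not in meta_cols:
            raise DataError("pangenome CSV lacks a 'Gene' column")
        strain_cols = [c for c in df.columns if c not in meta_cols]
        presence = df[strain_cols].apply(lambda col: col.str.len() > 0)
        presence.index = df["Gene"].tolist()
        rep = {}
        for _, row in df.iterrows():
            rep[row["Gene"]] = {s: row[s] for s in strain_cols if row[s]}
        return cls.from_frame(presence, representative_gene=rep)

    def to_roary_csv(self, path: str | Path) -> None:
        out = pd.DataFrame({"Gene": self.families})
        out["Non-unique Gene name"] = ""
        out["Annotation"] = ""
        for s in self.strains:
            col = []
            for fam in self.families:
                if self.presence.at[fam, s]:
                    col.append(self.representative_gene.get(fam, {}).get(s, f"{fam}__{s}"))
                else:
                    col.append("")
            out[s] = col
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class GeneLocation:
    gene_id: str
    scaffold_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DataError(f"gene {self.gene_id}: invalid coordinates")
        if self.strand not in "+-":
            raise DataError(f"gene {self.gene_id}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class GenomicIsland:
    scaffold_id: str
    first_gene_index: int
    last_gene_index: int
    n_unique: int
    span_nt: int


@dataclass(frozen=True)
class CogProfile:
    strain_id: str
    counts: dict
    total_annotated: int


# ---------------------------------------------------------------------------
# matrix analytics
# ---------------------------------------------------------------------------

def core_families(m: PresenceAbsenceMatrix) -> set[str]:
    """Families present in every strain (the strict core genome)."""
    mask = m.presence.all(axis=1)
    return set(m.presence.index[mask])


def venn_partition(m: PresenceAbsenceMatrix, focal_strains: Sequence[str]) -> dict[frozenset, int]:
    """Counts of families per non-empty presence pattern over 2-4 focal
    strains. Keys are frozensets of the focal strains carrying the family;
    families absent from all focal strains are excluded."""
    if not 2 <= len(focal_strains) <= 4:
        raise ConfigurationError("venn_partition needs 2-4 focal strains")
    unknown = set(focal_strains) - set(m.strains)
    if unknown:
        raise DataError(f"unknown strains: {sorted(unknown)}")
    sub = m.presence[list(focal_strains)]
    counts: dict[frozenset, int] = {}
    for _, row in sub.iterrows():
        pattern = frozenset(s for s in focal_strains if row[s])
        if pattern:
            counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def unique_families(m: PresenceAbsenceMatrix, focal: str) -> set[str]:
    """Families present in the focal strain and in no other strain."""
    if focal not in m.strains:
        raise DataError(f"unknown strain {focal!r}")
    others = [s for s in m.strains if s != focal]
    mask = m.presence[focal]
    if others:
        mask = mask & ~m.presence[others].any(axis=1)
    return set(m.presence.index[mask])


def detect_islands(
    unique: set[str],
    gene_map: Mapping[str, str],
    locations: Sequence[GeneLocation],
    min_island_genes: int = 4,
    max_gap_genes: int = 3,
) -> list[GenomicIsland]:
    """Cluster focal-strain unique genes into putative genomic islands.

    Genes are ranked by position along each scaffold; maximal runs of unique
    genes in which consecutive unique genes are separated by at most
    ``max_gap_genes`` intervening non-unique genes become candidates, and
    candidates with at least ``min_island_genes`` unique genes are reported.
    """
    unique_gene_ids = set()
    for fam in unique:
        gid = gene_map.get(fam)
        if gid is None:
            logger.warning("unique family %s has no gene in the focal strain; skipped", fam)
            continue
        unique_gene_ids.add(gid)
    by_scaffold: dict[str, list[GeneLocation]] = {}
    for loc in locations:
        by_scaffold.setdefault(loc.scaffold_id, []).append(loc)
    located = {loc.gene_id for loc in locations}
    for gid in sorted(unique_gene_ids - located):
        logger.warning("unique gene %s has no location; skipped", gid)

    islands = []
    for scaffold_id in sorted(by_scaffold):
        genes = sorted(by_scaffold[scaffold_id], key=lambda g: (g.start, g.end, g.gene_id))
        run: list[int] = []  # indices (gene ranks) of unique genes in the current run
        def flush(run: list[int]):
            if len(run) >= min_island_genes:
                first, last = run[0], run[-1]
                islands.append(GenomicIsland(
                    scaffold_id=scaffold_id,
                    first_gene_index=first, last_gene_index=last,
                    n_unique=len(run),
                    span_nt=genes[last].end - genes[first].start + 1))
        for idx, g in enumerate(genes):
            if g.gene_id in unique_gene_ids:
                if run and idx - run[-1] - 1 > max_gap_genes:
                    flush(run)
                    run = []
                run.append(idx)
        flush(run)
    return islands


# ---------------------------------------------------------------------------
# COG profiles and Fisher exact comparison
# ---------------------------------------------------------------------------

def cog_profile(annotations: Mapping[str, str], strain_id: str = "",
                exclude_categories: frozenset = frozenset()) -> CogProfile:
    """Per-category counts from a gene -> category-letters map. A protein
    annotated with k categories increments each of the k (so category counts
    can sum past the protein count). Letters outside the standard alphabet
    are bucketed as ``unknown`` with a warning; ``exclude_categories`` (e.g.
    {"S"}) removes categories from both the counts and the annotated total."""
    counts: dict[str, int] = {}
    total = 0
    for gene, cats in annotations.items():
        letters = [c for c in cats.upper() if not c.isspace() and c != "-"]
        kept = []
        for c in letters:
            if c not in COG_CATEGORIES:
                logger.warning("gene %s: unknown COG letter %r", gene, c)
                c = "unknown"
            if c in exclude_categories:
                continue
            kept.append(c)
        if kept:
            total += 1
            for c in kept:
                counts[c] = counts.get(c, 0) + 1
    return CogProfile(strain_id=strain_id, counts=counts, total_annotated=total)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Exact two-sided Fisher test on a 2x2 table.

    Returns (odds_ratio, p). With margins fixed, weight(x) =
    C(r1, x) * C(r2, c1 - x); the two-sided p sums the weights of every table
    whose weight is <= the observed weight, divided by C(N, c1). Integer
    weights make the tail comparison exact. The odds ratio is ad/bc with the
    usual infinity/NaN conventions for zero cells.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise DataError("Fisher table cells must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise DataError("Fisher table must have at least one positive margin")
    r1, c1 = a + b, a + c
    if a * d == 0 and b * c == 0:
        odds = nan
    elif b * c == 0:
        odds = inf
    else:
        odds = (a * d) / (b * c)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    w_obs = comb(r1, a) * comb(n - r1, c1 - a)
    tail = sum(w for x in range(lo, hi + 1)
               if (w := comb(r1, x) * comb(n - r1, c1 - x)) <= w_obs)
    p = tail / comb(n, c1)
    return odds, float(p)


@dataclass(frozen=True)
class CogComparison:
    category: str
    count_a: int
    count_b: int
    odds_ratio: float
    p_value: float
    significant: bool


def compare_cog_profiles(a: CogProfile, b: CogProfile, alpha: float = 0.05,
                         bonferroni: bool = False) -> list[CogComparison]:
    """Per-category 2x2 Fisher tests between two strains' COG profiles.

    Each category tests [[count_a, total_a - count_a], [count_b,
    total_b - count_b]]. No multiple-testing correction by default (a
    Bonferroni flag divides alpha by the category count)."""
    if a.total_annotated == 0 or b.total_annotated == 0:
        raise DataError("cannot compare profiles with zero annotated proteins")
    cats = sorted(set(a.counts) | set(b.counts))
    thr = alpha / len(cats) if (bonferroni and cats) else alpha
    out = []
    for cat in cats:
        ca, cb = a.counts.get(cat, 0), b.counts.get(cat, 0)
        odds, p = fisher_exact_2x2([[ca, a.total_annotated - ca],
                                    [cb, b.total_annotated - cb]])
        out.append(CogComparison(category=cat, count_a=ca, count_b=cb,
                                 odds_ratio=odds, p_value=p,
                                 significant=p < thr))
    return out


def read_cog_annotations(path: str | Path) -> dict[str, str]:
    """Two-column TSV: gene id, COG category letters."""
    ann: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"COG annotation line has fewer than 2 columns: {line!r}")
            ann[parts[0]] = parts[1]
    return ann


def read_gene_locations_gff3(path: str | Path, feature_types: frozenset = frozenset({"CDS", "gene"})) -> list[GeneLocation]:
    """Gene coordinates from GFF3 (ID attribute, CDS/gene features)."""
    locs = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in feature_types:
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("locus_tag")
            if gid is None or gid in seen:
                continue
            seen.add(gid)
            locs.append(GeneLocation(gene_id=gid, scaffold_id=f[0],
                                     start=int(f[3]), end=int(f[4]),
                                     strand=f[6] if f[6] in "+-" else "+"))
    return locs
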