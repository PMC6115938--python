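"""Orthology and whole-genome identity metrics.

Three related measures are computed from pairwise similarity evidence:

* **BBH orthologs** — two proteins that are each other's highest-bitscore hit
  in reciprocal searches, subject to identity and query-coverage cutoffs
  (defaults 70% / 70%).
* **AAI** — the mean amino-acid identity over BBH ortholog pairs called at
  relaxed thresholds (40% identity, 70% coverage, e-value <= 1e-12), each
  pair contributing the mean of its two directional identities.
* **ANI** — a fragment-based nucleotide identity: the query genome is chopped
  into non-overlapping 1000-nt fragments, each fragment is aligned to its
  best location in the reference (edit-distance infix alignment), and the
  mean identity of fragments mapping at >= 70% identity is reported. The
  one-way values of both directions are averaged for genome pairs. Absolute
  values can differ slightly from minimizer-based ANI tools; the estimator
  here is transparent and exact on substitution-only divergence.

Putative species are single-linkage components of the graph joining strains
whose ANI *and* AAI both reach the species threshold (96% by default; the
conventional boundary is 95-96%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np

from .errors import ConfigurationError, DataError, NoOrthologsError, UnmappableError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise protein alignment record (a tabular search hit)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    query_length: int
    subject_length: int

    def __post_init__(self) -> None:
        if self.query_length < 1 or self.subject_length < 1:
            raise DataError(f"hit {self.query_id}->{self.subject_id}: lengths must be >= 1")
        if self.evalue < 0:
            raise DataError(f"hit {self.query_id}->{self.subject_id}: negative e-value")

    @property
    def query_coverage_pct(self) -> float:
        return 100.0 * self.alignment_length / self.query_length


@dataclass(frozen=True)
class OrthologPair:
    idA: str
    idB: str
    identityAB: float
    identityBA: float

    @property
    def mean_identity(self) -> float:
        return (self.identityAB + self.identityBA) / 2.0


@dataclass(frozen=True)
class AniResult:
    one_way_ab: float
    one_way_ba: float
    averaged: float
    n_fragments_mapped: int


@dataclass(frozen=True)
class SpeciesPartition:
    clusters: tuple[frozenset, ...]
    threshold_ani: float
    threshold_aai: float


# ---------------------------------------------------------------------------
# hit-table IO: standard 12-column tabular alignment format, optionally the
# 14-column dialect with qlen/slen appended, else a sequence-length sidecar.
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path, lengths: Mapping[str, int] | None = None) -> list[SimilarityHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise DataError(f"{path}:{lineno}: expected >= 12 tab-separated columns")
            q, s = f[0], f[1]
            if len(f) >= 14:
                qlen, slen = int(f[12]), int(f[13])
            elif lengths is not None:
                try:
                    qlen, slen = lengths[q], lengths[s]
                except KeyError as e:
                    raise DataError(f"{path}:{lineno}: no length for sequence {e}") from None
            else:
                raise DataError(f"{path}:{lineno}: 12-column table requires a length sidecar")
            hits.append(SimilarityHit(
                query_id=q, subject_id=s,
                percent_identity=float(f[2]), alignment_length=int(f[3]),
                evalue=float(f[10]), bitscore=float(f[11]),
                query_length=qlen, subject_length=slen))
    return hits


def write_hit_table(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """14-column dialect: the standard 12 columns plus qlen and slen.
    Unused coordinate columns are written as zeros."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, h.percent_identity, h.alignment_length,
                0, 0, 0, 0, 0, 0, h.evalue, h.bitscore,
                h.query_length, h.subject_length])) + "\n")


# ---------------------------------------------------------------------------
# BBH and AAI
# ---------------------------------------------------------------------------

def _dedupe(hits: Iterable[SimilarityHit]) -> list[SimilarityHit]:
    best: dict[tuple[str, str], SimilarityHit] = {}
    dropped = 0
    for h in hits:
        key = (h.query_id, h.subject_id)
        prev = best.get(key)
        if prev is None or h.bitscore > prev.bitscore:
            if prev is not None:
                dropped += 1
            best[key] = h
        elif prev is not None:
            dropped += 1
    if dropped:
        logger.info("deduplicated %d repeated (query,subject) hit rows", dropped)
    return list(best.values())


def _hit_rank_key(h: SimilarityHit):
    # highest bitscore, then lowest e-value, then longest alignment,
    # then lexicographically smallest subject id: fully deterministic.
    return (-h.bitscore, h.evalue, -h.alignment_length, h.subject_id)


def best_hits(hits: Iterable[SimilarityHit]) -> dict[str, SimilarityHit]:
    """Best hit per query under the deterministic ranking."""
    best: dict[str, SimilarityHit] = {}
    for h in _dedupe(hits):
        prev = best.get(h.query_id)
        if prev is None or _hit_rank_key(h) < _hit_rank_key(prev):
            best[h.query_id] = h
    return best


def bidirectional_best_hits(
    hitsAB: Sequence[SimilarityHit],
    hitsBA: Sequence[SimilarityHit],
    min_identity: float = 70.0,
    min_coverage_pct: float = 70.0,
    require_both_coverages: bool = False,
) -> list[OrthologPair]:
    """Reciprocal best hits passing identity/coverage cutoffs in both
    directions. Coverage is alignment_length over the querying protein's
    length; ``require_both_coverages`` additionally applies the cutoff with
    the subject length in each direction."""
    bestAB = best_hits(hitsAB)
    bestBA = best_hits(hitsBA)
    pairs = []
    for a, hab in sorted(bestAB.items()):
        b = hab.subject_id
        hba = bestBA.get(b)
        if hba is None or hba.subject_id != a:
            continue
        ok = True
        for h in (hab, hba):
            if h.percent_identity < min_identity or h.query_coverage_pct < min_coverage_pct:
                ok = False
            if require_both_coverages and 100.0 * h.alignment_length / h.subject_length < min_coverage_pct:
                ok = False
        if ok:
            pairs.append(OrthologPair(idA=a, idB=b,
                                      identityAB=hab.percent_identity,
                                      identityBA=hba.percent_identity))
    return pairs


def compute_aai(
    hitsAB: Sequence[SimilarityHit],
    hitsBA: Sequence[SimilarityHit],
    min_identity: float = 40.0,
    min_coverage_pct: float = 70.0,
    max_evalue: float = 1e-12,
) -> float:
    """Average amino-acid identity over BBH orthologs at the relaxed
    thresholds; each pair contributes the mean of its directional
    identities. Raises when no pair qualifies — an AAI of 0 would be a
    statement, not a failure."""
    fAB = [h for h in hitsAB if h.evalue <= max_evalue]
    fBA = [h for h in hitsBA if h.evalue <= max_evalue]
    pairs = bidirectional_best_hits(fAB, fBA, min_identity, min_coverage_pct)
    if not pairs:
        raise NoOrthologsError("no ortholog pairs pass the AAI thresholds")
    return float(np.mean([p.mean_identity for p in pairs]))


# ---------------------------------------------------------------------------
# fragment-based ANI
# ---------------------------------------------------------------------------

def _fragments(genome: Sequence[str], fragment_length: int) -> list[str]:
    frags = []
    for seq in genome:
        seq = seq.upper()
        for i in range(0, len(seq) - fragment_length + 1, fragment_length):
            frags.append(seq[i:i + fragment_length])
    return frags


def compute_one_way_ani(
    query_genome: Sequence[str],
    reference_genome: Sequence[str],
    fragment_length: int = 1000,
    min_fragment_identity: float = 70.0,
) -> tuple[float, int]:
    """One-way ANI: chop the query into non-overlapping fragments, align each
    to its best location in the reference (infix edit-distance alignment),
    keep fragments at >= ``min_fragment_identity`` identity, return their mean
    identity in percent and the mapped-fragment count."""
    if fragment_length < 100:
        raise ConfigurationError("fragment_length must be >= 100")
    if not query_genome or not reference_genome:
        raise DataError("both genomes must be non-empty")
    frags = _fragments(query_genome, fragment_length)
    if not frags:
        raise UnmappableError("query has no fragment of the requested length")
    refs = [s.upper() for s in reference_genome]
    identities = []
    for frag in frags:
        best_dist = fragment_length + 1
        for ref in refs:
            d = edlib.align(frag, ref, mode="HW", task="distance",
                            k=best_dist - 1)["editDistance"]
            if d != -1 and d < best_dist:
                best_dist = d
                if best_dist == 0:
                    break
        ident = 100.0 * (fragment_length - best_dist) / fragment_length
        if ident >= min_fragment_identity:
            identities.append(ident)
    if not identities:
        raise UnmappableError("no fragment mapped at the identity cutoff")
    return float(np.mean(identities)), len(identities)


def averaged_ani(
    a: Sequence[str],
    b: Sequence[str],
    fragment_length: int = 1000,
    min_fragment_identity: float = 70.0,
) -> AniResult:
    """Two one-way ANI values and their arithmetic mean."""
    try:
        ab, n_ab = compute_one_way_ani(a, b, fragment_length, min_fragment_identity)
    except UnmappableError as e:
        raise UnmappableError(f"direction A->B unmappable: {e}") from e
    try:
        ba, n_ba = compute_one_way_ani(b, a, fragment_length, min_fragment_identity)
    except UnmappableError as e:
        raise UnmappableError(f"direction B->A unmappable: {e}") from e
    return AniResult(one_way_ab=ab, one_way_ba=ba,
                     averaged=(ab + ba) / 2.0, n_fragments_mapped=n_ab + n_ba)


# ---------------------------------------------------------------------------
# species clustering and group-specific ortholog sets
# ---------------------------------------------------------------------------

def cluster_species(
    ani_matrix: Mapping[str, Mapping[str, float]],
    aai_matrix: Mapping[str, Mapping[str, float]] | None,
    threshold: float = 96.0,
    require_both: bool = True,
) -> SpeciesPartition:
    """Single-linkage species partition: connect strains whose ANI and AAI
    both reach ``threshold`` (missing AAI entries pass, logged); clusters are
    the connected components. With ``require_both=False`` either measure
    passing creates an edge."""
    strains = sorted(ani_matrix)
    for i in strains:
        for j in strains:
            if abs(ani_matrix[i][j] - ani_matrix[j][i]) > 1e-9:
                raise DataError(f"ANI matrix asymmetric at ({i},{j})")
            if aai_matrix is not None and i in aai_matrix and j in aai_matrix.get(i, {}):
                if abs(aai_matrix[i][j] - aai_matrix[j][i]) > 1e-9:
                    raise DataError(f"AAI matrix asymmetric at ({i},{j})")
    g = nx.Graph()
    g.add_nodes_from(strains)
    for ix, i in enumerate(strains):
        for j in strains[ix + 1:]:
            ani_ok = ani_matrix[i][j] >= threshold
            if aai_matrix is None or j not in aai_matrix.get(i, {}):
                if aai_matrix is not None:
                    logger.info("no AAI value for (%s,%s); treating as pass", i, j)
                aai_ok = True
            else:
                aai_ok = aai_matrix[i][j] >= threshold
            edge = (ani_ok and aai_ok) if require_both else (ani_ok or aai_ok)
            if edge:
                g.add_edge(i, j)
    clusters = tuple(sorted((frozenset(c) for c in nx.connected_components(g)),
                            key=lambda c: sorted(c)))
    return SpeciesPartition(clusters=clusters, threshold_ani=threshold,
                            threshold_aai=threshold)


def shared_specific_sets(
    ortholog_clusters: Mapping[str, frozenset | set],
    in_group: set[str],
    out_group: set[str],
) -> set[str]:
    """Families present in every in-group strain and absent from every
    out-group strain (e.g. proteins common and specific to the arsenic
    oxidizers in a mixed strain panel)."""
    if not in_group:
        raise DataError("in_group must be non-empty")
    if in_group & out_group:
        raise DataError("in_group and out_group must be disjoint")
    covered = set()
    for members in ortholog_clusters.values():
        covered |= set(members)
    missing = (in_group | out_group) - covered
    if missing:
        raise DataError(f"strains not covered by any cluster: {sorted(missing)}")
    return {fam for fam, members in ortholog_clusters.items()
            if in_group <= set(members) and not (set(members) & out_group)}


def write_matrix_tsv(matrix: Mapping[str, Mapping[str, float]], path: str | Path) -> None:
    strains = sorted(matrix)
    with open(path, "w") as fh:
        fh.write("strain\t" + "\t".join(strains) + "\n")
        for i in strains:
            fh.write(i + "\t" + "\t".join(f"{matrix[i][j]:.4f}" for j in strains) + "\n")
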