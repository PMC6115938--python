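"""Rule-based classification of nodulation and nitrogen-fixation proteins.

Two-stage HMM-search bookkeeping over externally produced hit tables: a
sensitive seed-profile search collects candidate proteins (every hit,
regardless of e-value), and each candidate's scan against the full combined
profile database is reduced to its top-scoring hit. The top hit alone
assigns the label:

====== =========================================================
label  top hit (TIGRFAM accession, or Pfam profile name)
====== =========================================================
NodA   TIGR04245, or Pfam name ``NodA``
NodB   TIGR04243
NodC   TIGR04242
NifH   TIGR01287, or Pfam name ``Fer4_NifH``
NifD   TIGR01282, TIGR01860, TIGR01861
NifK   TIGR02932, TIGR02931, TIGR01286
====== =========================================================

Anything else is ``none``. Presence of the nodABC (nifHDK) operon requires
all three member labels to be present.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import DataError

LABELS = ("NodA", "NodB", "NodC", "NifH", "NifD", "NifK")

# label -> (TIGRFAM accessions, Pfam profile names)
RULE_TABLE: dict[str, tuple[frozenset, frozenset]] = {
    "NodA": (frozenset({"TIGR04245"}), frozenset({"NodA"})),
    "NodB": (frozenset({"TIGR04243"}), frozenset()),
    "NodC": (frozenset({"TIGR04242"}), frozenset()),
    "NifH": (frozenset({"TIGR01287"}), frozenset({"Fer4_NifH"})),
    "NifD": (frozenset({"TIGR01282", "TIGR01860", "TIGR01861"}), frozenset()),
    "NifK": (frozenset({"TIGR02932", "TIGR02931", "TIGR01286"}), frozenset()),
}


@dataclass(frozen=True)
class HmmHit:
    query_id: str
    hmm_name: str
    hmm_accession: str
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if not (self.hmm_name or self.hmm_accession):
            raise DataError("HMM hit needs a profile name or accession")
        if self.score != self.score or self.score in (float("inf"), float("-inf")):
            raise DataError("HMM hit score must be finite")


@dataclass(frozen=True)
class SymbiosisCall:
    query_id: str
    label: str  # one of LABELS or "none"
    top_hit: HmmHit


def collect_candidates(seed_search_hits: Iterable[HmmHit]) -> set[str]:
    """Every query id appearing in the seed-profile search output — no
    e-value filtering at this stage, deliberately."""
    return {h.query_id for h in seed_search_hits}


def top_hit_per_query(scan_hits: Iterable[HmmHit]) -> dict[str, HmmHit]:
    """Highest-scoring hit per query; ties go to the lower e-value, then the
    lexicographically smaller accession (then name), deterministically."""
    def key(h: HmmHit):
        return (-h.score, h.evalue, h.hmm_accession, h.hmm_name)

    best: dict[str, HmmHit] = {}
    for h in scan_hits:
        prev = best.get(h.query_id)
        if prev is None or key(h) < key(prev):
            best[h.query_id] = h
    return best


def _label_for(hit: HmmHit) -> str:
    acc = hit.hmm_accession.split(".")[0]  # tolerate versioned accessions
    for label, (tigr_accs, pfam_names) in RULE_TABLE.items():
        if acc in tigr_accs or hit.hmm_name in pfam_names:
            return label
    return "none"


def classify(top_hits: Mapping[str, HmmHit]) -> list[SymbiosisCall]:
    """Apply the rule table to each query's top hit."""
    return [SymbiosisCall(query_id=q, label=_label_for(h), top_hit=h)
            for q, h in sorted(top_hits.items())]


def summarize_presence(calls: Iterable[SymbiosisCall]) -> dict[str, bool]:
    """Per-label presence, plus the nodABC / nifHDK conjunctions."""
    present = {label: False for label in LABELS}
    for call in calls:
        if call.label in present:
            present[call.label] = True
    present["nodABC"] = all(present[l] for l in ("NodA", "NodB", "NodC"))
    present["nifHDK"] = all(present[l] for l in ("NifH", "NifD", "NifK"))
    return present


def read_tblout(path: str | Path) -> list[HmmHit]:
    """Parse HMMER3 tblout: whitespace-separated, ``#`` comments; columns are
    target name, target accession, query name, query accession, then the
    full-sequence e-value and score. For a profile-database scan the target
    is the HMM and the query is the protein."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 6:
                raise DataError(f"{path}:{lineno}: truncated tblout line")
            acc = "" if f[1] == "-" else f[1]
            hits.append(HmmHit(query_id=f[2], hmm_name=f[0], hmm_accession=acc,
                               evalue=float(f[4]), score=float(f[5])))
    return hits


def write_calls_tsv(calls: Iterable[SymbiosisCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tlabel\ttop_hmm_name\ttop_hmm_accession\tevalue\tscore\n")
        for c in calls:
            h = c.top_hit
            fh.write(f"{c.query_id}\t{c.label}\t{h.hmm_name}\t{h.hmm_accession}"
                     f"\t{h.evalue:g}\t{h.score:g}\n")
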