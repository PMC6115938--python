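"""Scaffold filtering and assembly statistics.

Draft assemblies arrive as FASTA scaffolds with a fold-coverage value per
scaffold (either from a two-column sidecar TSV or encoded in SPAdes-style
``_cov_<x>`` header suffixes). Scaffolds below the coverage or length cutoffs
are discarded before any downstream analysis; the remaining set is summarized
with the usual assembly statistics (total length, GC%, N50/L50, and the count
and length fraction of scaffolds above a size threshold).

GC% is computed over unambiguous bases only: N is excluded from both the
numerator and the denominator. N50 is the length of the scaffold at which the
cumulative sum of lengths, taken in descending length order, first reaches
half the total length; L50 is that scaffold's rank. Equal-length scaffolds
are ordered by id so both statistics are deterministic.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import ConfigurationError, DataError

_VALID = set("ACGTN")
_NORMALIZE = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})
_COV_RE = re.compile(r"_cov_([0-9]+(?:\.[0-9]+)?)")


@dataclass(frozen=True)
class Scaffold:
    """A named DNA sequence with a fold-coverage value."""

    id: str
    sequence: str
    coverage: float = 0.0

    def __post_init__(self) -> None:
        seq = self.sequence.upper().translate(_NORMALIZE)
        if not seq:
            raise DataError(f"scaffold {self.id!r} has an empty sequence")
        bad = set(seq) - _VALID
        if bad:
            raise DataError(f"scaffold {self.id!r} has invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        if self.coverage < 0:
            raise DataError(f"scaffold {self.id!r} has negative coverage")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssemblyStats:
    total_length: int
    gc_percent: float
    n_scaffolds: int
    n50: int
    l50: int
    count_over_threshold: int
    fraction_length_over_threshold: float
    mean_coverage: float
    size_threshold: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_scaffolds(
    scaffolds: Sequence[Scaffold],
    min_coverage: float = 10.0,
    min_length: int = 200,
) -> list[Scaffold]:
    """Drop scaffolds with coverage below ``min_coverage`` or length below
    ``min_length``; both boundaries are inclusive keeps (strict "less than"
    removal). Order is preserved and the input is not modified."""
    if min_coverage < 0 or min_length < 0:
        raise ConfigurationError("filter thresholds must be non-negative")
    return [s for s in scaffolds
            if s.coverage >= min_coverage and len(s) >= min_length]


def compute_stats(scaffolds: Sequence[Scaffold], size_threshold: int = 40000) -> AssemblyStats:
    """Assembly statistics over a non-empty scaffold set.

    ``count_over_threshold`` and the corresponding length fraction use a
    strict ``>`` comparison ("over" the threshold). Mean coverage is the
    length-weighted mean; per-scaffold weighting is a different convention
    and the two disagree on uneven assemblies.
    """
    if not scaffolds:
        raise DataError("cannot compute statistics of an empty assembly")
    lengths = [len(s) for s in scaffolds]
    total = sum(lengths)
    gc = at = 0
    for s in scaffolds:
        seq = s.sequence
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    denom = gc + at
    gc_percent = 100.0 * gc / denom if denom else 0.0

    # N50/L50 over descending lengths, id as deterministic tie-break.
    ranked = sorted(scaffolds, key=lambda s: (-len(s), s.id))
    half = total / 2
    cum = 0
    n50 = l50 = 0
    for rank, s in enumerate(ranked, start=1):
        cum += len(s)
        if cum >= half:
            n50, l50 = len(s), rank
            break

    over = [len(s) for s in scaffolds if len(s) > size_threshold]
    mean_cov = sum(s.coverage * len(s) for s in scaffolds) / total
    return AssemblyStats(
        total_length=total,
        gc_percent=gc_percent,
        n_scaffolds=len(scaffolds),
        n50=n50,
        l50=l50,
        count_over_threshold=len(over),
        fraction_length_over_threshold=100.0 * sum(over) / total,
        mean_coverage=mean_cov,
        size_threshold=size_threshold,
    )


def read_coverage_tsv(path: str | Path) -> dict[str, float]:
    cov: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"coverage TSV line has fewer than 2 columns: {line!r}")
            cov[parts[0]] = float(parts[1])
    return cov


def coverage_from_header(name: str) -> float | None:
    """Parse a SPAdes-style ``_cov_<x>`` suffix; None if absent."""
    m = _COV_RE.search(name)
    return float(m.group(1)) if m else None


def read_fasta_scaffolds(path: str | Path, coverage_tsv: str | Path | None = None) -> list[Scaffold]:
    """Load scaffolds from FASTA; coverage from the sidecar TSV when given,
    else from ``_cov_`` header suffixes, else 0."""
    cov_map = read_coverage_tsv(coverage_tsv) if coverage_tsv else {}
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        cov = cov_map.get(rec.id)
        if cov is None:
            cov = coverage_from_header(rec.id)
        out.append(Scaffold(id=rec.id, sequence=str(rec.seq), coverage=cov if cov is not None else 0.0))
    if not out:
        raise DataError(f"no sequences in {path}")
    return out


def write_fasta_scaffolds(scaffolds: Iterable[Scaffold], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for s in scaffolds:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.sequence), width):
                fh.write(s.sequence[i:i + width] + "\n")


def write_stats_report(stats: AssemblyStats, tsv_path: str | Path | None = None,
                       json_path: str | Path | None = None) -> None:
    d = stats.to_dict()
    if tsv_path:
        with open(tsv_path, "w") as fh:
            fh.write("\t".join(d.keys()) + "\n")
            fh.write("\t".join(str(v) for v in d.values()) + "\n")
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")
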