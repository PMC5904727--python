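"""Stringent read-level filter: host subtraction, then perfect foreign assignment.

The recommended guard against artifactual "foreign" RNA calls in a
sequencing study is to first discard every read that matches the
ingesting organism's genome/transcriptome (and, optionally, additional
contaminant reference sets) within a small mismatch budget, and only
then assign the surviving reads to foreign references - requiring
perfect matches.  Host subtraction always precedes foreign assignment,
so no read can be both host-removed and foreign-assigned.

Matching is ungapped full-length Hamming on both strands, consistent
with :mod:`xenomir.seq_match`; indels are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seq_match import (
    MatchCategory,
    MatchReport,
    NucSequence,
    _encode,
    _window_mismatch_counts,
    reverse_complement,
)

DEFAULT_READ_LENGTH_RANGE = (15, 35)


@dataclass(frozen=True)
class Read:
    read_id: str
    seq: NucSequence
    origin: str | None = None  # synthetic ground-truth label, if any


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.read_id for r in self.reads]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate read ids")

    def __len__(self) -> int:
        return len(self.reads)

    def ids(self) -> list[str]:
        return [r.read_id for r in self.reads]


@dataclass(frozen=True)
class FilterConfig:
    """host_max_mismatches is the subtraction budget; foreign matches are
    always required to be perfect (0 mismatches), which is the point of
    the procedure and not configurable."""

    host_max_mismatches: int = 2
    min_read_length: int = 15
    max_read_length: int = 35

    def __post_init__(self) -> None:
        if self.host_max_mismatches < 0:
            raise ValueError("host_max_mismatches must be >= 0")
        if self.min_read_length < 1 or self.max_read_length < self.min_read_length:
            raise ValueError("invalid read length range")


@dataclass(frozen=True)
class SubtractionResult:
    retained: ReadSet
    removed: ReadSet
    # best host hit per removed read id
    host_hits: dict[str, MatchReport]


def _best_host_hit(
    read: Read, encoded_refs: list[tuple[NucSequence, np.ndarray]]
) -> MatchReport | None:
    """Minimum-mismatch full-length placement of a read over all references."""
    fwd = _encode(read.seq.residues)
    rev = _encode(reverse_complement(read.seq.residues))
    L = len(read.seq)
    best: tuple[int, int, int, int] | None = None  # (mm, ref_idx, start, strand_rank)
    for idx, (ref, ref_arr) in enumerate(encoded_refs):
        if L > len(ref_arr):
            continue
        for strand_rank, arr in enumerate((fwd, rev)):
            mm = _window_mismatch_counts(arr, ref_arr)
            j = int(mm.argmin())
            key = (int(mm[j]), idx, j, strand_rank)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    mismatches, idx, start, strand_rank = best
    ref = encoded_refs[idx][0]
    category = MatchCategory.EXACT_FULL if mismatches == 0 else MatchCategory.NEAR
    return MatchReport(
        read.read_id, ref.id, category, start, start + L, "+-"[strand_rank],
        mismatches, L,
    )


def host_subtract(
    reads: ReadSet,
    host_refs: Sequence[NucSequence],
    cfg: FilterConfig | None = None,
    extra_refs: Sequence[NucSequence] = (),
) -> SubtractionResult:
    """Partition reads into (retained, removed) by host similarity.

    A read is removed iff its best full-length placement on any host or
    extra subtraction reference (both strands) has at most
    ``host_max_mismatches`` mismatches.  The best host hit of each
    removed read is recorded.
    """
    cfg = cfg or FilterConfig()
    refs = list(host_refs) + list(extra_refs)
    if not refs:
        raise ValueError("at least one host reference required")
    encoded = [(r, _encode(r.residues)) for r in refs]
    retained: list[Read] = []
    removed: list[Read] = []
    hits: dict[str, MatchReport] = {}
    for read in reads.reads:
        hit = _best_host_hit(read, encoded)
        if hit is not None and hit.mismatches is not None and hit.mismatches <= cfg.host_max_mismatches:
            removed.append(read)
            hits[read.read_id] = hit
        else:
            retained.append(read)
    return SubtractionResult(ReadSet(retained), ReadSet(removed), hits)


UNASSIGNED = "unassigned"
ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class Assignment:
    read_id: str
    status: str  # assigned | ambiguous | unassigned
    references: tuple[str, ...]


def foreign_assign(
    retained: ReadSet, foreign_refs: Sequence[NucSequence]
) -> list[Assignment]:
    """Assign retained reads to foreign references by perfect match only.

    A read maps to every foreign reference containing it verbatim on
    either strand.  One hit -> assigned; several references -> ambiguous
    (reported, not resolved); none -> unassigned.
    """
    out: list[Assignment] = []
    for read in retained.reads:
        fwd = read.seq.residues
        rev = reverse_complement(fwd)
        hits = tuple(
            ref.id for ref in foreign_refs
            if fwd in ref.residues or rev in ref.residues
        )
        if not hits:
            out.append(Assignment(read.read_id, UNASSIGNED, ()))
        elif len(hits) == 1:
            out.append(Assignment(read.read_id, ASSIGNED, hits))
        else:
            out.append(Assignment(read.read_id, AMBIGUOUS, hits))
    return out


def filter_summary(
    removed: ReadSet, assignments: Sequence[Assignment]
) -> dict[str, int]:
    """Category tallies; the categories partition the input read set."""
    n_removed = len(removed)
    n_assigned = sum(1 for a in assignments if a.status == ASSIGNED)
    n_ambiguous = sum(1 for a in assignments if a.status == AMBIGUOUS)
    n_unassigned = sum(1 for a in assignments if a.status == UNASSIGNED)
    return {
        "input": n_removed + len(assignments),
        "host_removed": n_removed,
        "foreign_assigned": n_assigned,
        "ambiguous": n_ambiguous,
        "unassigned": n_unassigned,
    }
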