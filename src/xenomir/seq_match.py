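"""Ungapped matching of short candidate sequences against host references.

A putative foreign miRNA detected in host sequencing data is suspect if
its sequence also occurs in the host.  Matches are graded into four
categories:

* ``EXACT_FULL`` - the full candidate occurs verbatim in a reference
  (either strand);
* ``NEAR`` - the full candidate aligns to some reference window with a
  small number of substitutions (default at most 1);
* ``PARTIAL`` - candidate and reference share a perfect stretch of at
  least ``partial_min_stretch`` nucleotides (default 15);
* ``NONE`` - none of the above.

All matching is ungapped (Hamming); coordinates are 0-based half-open on
the reference forward strand, with minus-strand hits flagged by strand
``-``.  The implementations are deliberately brute force - candidate
sequences are ~20 nt and references are desk scale - and double as the
reference behaviour for any accelerated variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

_ALLOWED = set("ACGTU")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class MatchCategory(str, Enum):
    EXACT_FULL = "EXACT_FULL"
    NEAR = "NEAR"
    PARTIAL = "PARTIAL"
    NONE = "NONE"


# precedence when picking the single best category across references:
# a full-length hit (even with a mismatch) outranks a shared fragment
_CATEGORY_RANK = {
    MatchCategory.EXACT_FULL: 0,
    MatchCategory.NEAR: 1,
    MatchCategory.PARTIAL: 2,
    MatchCategory.NONE: 3,
}


def normalize_residues(raw: str) -> str:
    """Uppercase, map RNA U to DNA T, reject anything else.

    Ambiguity codes (N, R, Y, ...) are rejected: the match categories
    are defined on exact base identity. The reported error position is
    1-based.
    """
    text = "".join(raw.split())
    if not text:
        raise ValueError("empty sequence")
    up = text.upper()
    for i, ch in enumerate(up):
        if ch not in _ALLOWED:
            raise ValueError(f"disallowed character {ch!r} at position {i + 1}")
    return up.replace("U", "T")


@dataclass(frozen=True)
class NucSequence:
    """A normalized nucleotide sequence (DNA alphabet, U folded to T)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatchConfig:
    partial_min_stretch: int = 15
    near_max_mismatches: int = 1
    search_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.partial_min_stretch < 1:
            raise ValueError("partial_min_stretch must be >= 1")
        if self.near_max_mismatches < 0:
            raise ValueError("near_max_mismatches must be >= 0")


@dataclass(frozen=True)
class MatchReport:
    """Outcome of matching one candidate against host reference(s)."""

    candidate_id: str
    reference_id: str | None
    category: MatchCategory
    ref_start: int | None = None
    ref_end: int | None = None
    strand: str | None = None
    mismatches: int | None = None
    matched_length: int = 0

    def __post_init__(self) -> None:
        if self.category is MatchCategory.NONE:
            if self.ref_start is not None or self.ref_end is not None:
                raise ValueError("NONE reports carry no coordinates")
        else:
            if self.ref_start is None or self.ref_end is None:
                raise ValueError("coordinates required for a match")
            if not 0 <= self.ref_start < self.ref_end:
                raise ValueError("invalid coordinates")
            if self.strand not in ("+", "-"):
                raise ValueError("strand must be '+' or '-'")


def _encode(residues: str) -> np.ndarray:
    return np.frombuffer(residues.encode("ascii"), dtype=np.uint8)


def _none_report(candidate_id: str) -> MatchReport:
    return MatchReport(candidate_id, None, MatchCategory.NONE)


def exact_search(
    candidate: NucSequence, reference: NucSequence, cfg: MatchConfig | None = None
) -> list[MatchReport]:
    """All full-length, zero-mismatch occurrences of the candidate.

    Plus-strand hits come first, then minus-strand hits (occurrences of
    the reverse complement), each in left-to-right reference order.
    """
    cfg = cfg or MatchConfig()
    L = len(candidate)
    if L > len(reference):
        raise ValueError("candidate longer than reference")

    def occurrences(needle: str) -> list[int]:
        hay = reference.residues
        out, i = [], hay.find(needle)
        while i != -1:
            out.append(i)
            i = hay.find(needle, i + 1)
        return out

    reports = [
        MatchReport(candidate.id, reference.id, MatchCategory.EXACT_FULL,
                    s, s + L, "+", 0, L)
        for s in occurrences(candidate.residues)
    ]
    if cfg.search_both_strands:
        rc = reverse_complement(candidate.residues)
        reports += [
            MatchReport(candidate.id, reference.id, MatchCategory.EXACT_FULL,
                        s, s + L, "-", 0, L)
            for s in occurrences(rc)
        ]
    return reports


def _longest_common_substring(a: str, b: str) -> tuple[int, int]:
    """(length, b_start) of the longest substring of ``a`` found in ``b``.

    Ties resolve to the smallest b_start. Classic O(len(a) * len(b))
    dynamic programme, vectorised over b.
    """
    if not a or not b:
        return 0, 0
    A, B = _encode(a), _encode(b)
    prev = np.zeros(len(B), dtype=np.int32)
    best_len, best_start = 0, 0
    shifted = np.empty(len(B), dtype=np.int32)
    for i in range(len(A)):
        shifted[0] = 0
        shifted[1:] = prev[:-1]
        cur = (shifted + 1) * (B == A[i])
        row_max = int(cur.max())
        if row_max:
            j = int(cur.argmax())  # first maximum -> smallest start for that length
            start = j - row_max + 1
            if row_max > best_len or (row_max == best_len and start < best_start):
                best_len, best_start = row_max, start
        prev = cur
    return best_len, best_start


def longest_perfect_stretch(
    candidate: NucSequence, reference: NucSequence, cfg: MatchConfig | None = None
) -> MatchReport:
    """Longest perfectly shared stretch; PARTIAL when it reaches threshold.

    Both strands are considered when enabled; ties break toward the
    smallest reference start, then the plus strand.
    """
    cfg = cfg or MatchConfig()
    hits: list[tuple[int, int, int]] = []  # (length, ref_start, strand_rank)
    ln, st = _longest_common_substring(candidate.residues, reference.residues)
    if ln:
        hits.append((ln, st, 0))
    if cfg.search_both_strands:
        ln, st = _longest_common_substring(
            reverse_complement(candidate.residues), reference.residues
        )
        if ln:
            hits.append((ln, st, 1))
    if not hits:
        return _none_report(candidate.id)
    length, start, strand_rank = min(hits, key=lambda t: (-t[0], t[1], t[2]))
    if length < cfg.partial_min_stretch:
        return _none_report(candidate.id)
    return MatchReport(
        candidate.id, reference.id, MatchCategory.PARTIAL,
        start, start + length, "+-"[strand_rank], 0, length,
    )


def _window_mismatch_counts(cand: np.ndarray, ref: np.ndarray) -> np.ndarray:
    windows = np.lib.stride_tricks.sliding_window_view(ref, len(cand))
    return (windows != cand).sum(axis=1)


def best_windowed_match(
    candidate: NucSequence, reference: NucSequence, cfg: MatchConfig | None = None
) -> MatchReport:
    """Minimum-Hamming full-length alignment of the candidate.

    Slides the candidate over every same-length reference window (both
    strands when enabled). 0 mismatches -> EXACT_FULL; between 1 and
    ``near_max_mismatches`` -> NEAR; otherwise NONE. Ties break toward
    the smallest reference start, then the plus strand.
    """
    cfg = cfg or MatchConfig()
    L = len(candidate)
    if L > len(reference):
        raise ValueError("candidate longer than reference")
    ref = _encode(reference.residues)
    mm_fwd = _window_mismatch_counts(_encode(candidate.residues), ref)
    best: tuple[int, int, int] | None = None  # (mismatches, ref_start, strand_rank)

    def consider(mm: np.ndarray, strand_rank: int) -> None:
        nonlocal best
        j = int(mm.argmin())
        cand_best = (int(mm[j]), j, strand_rank)
        if best is None or (cand_best[0], cand_best[1], cand_best[2]) < best:
            best = cand_best

    consider(mm_fwd, 0)
    if cfg.search_both_strands:
        mm_rev = _window_mismatch_counts(
            _encode(reverse_complement(candidate.residues)), ref
        )
        consider(mm_rev, 1)

    assert best is not None
    mismatches, start, strand_rank = best
    if mismatches == 0:
        category = MatchCategory.EXACT_FULL
    elif mismatches <= cfg.near_max_mismatches:
        category = MatchCategory.NEAR
    else:
        return _none_report(candidate.id)
    return MatchReport(
        candidate.id, reference.id, category,
        start, start + L, "+-"[strand_rank], mismatches, L,
    )


def contains(outer: NucSequence, inner: NucSequence) -> tuple[bool, int | None]:
    """Whether ``inner`` is a forward-strand substring of ``outer``.

    Returns (found, 0-based offset of the first occurrence or None).
    """
    offset = outer.residues.find(inner.residues)
    return (offset != -1), (offset if offset != -1 else None)


def classify_host_match(
    candidate: NucSequence,
    references: Sequence[NucSequence],
    cfg: MatchConfig | None = None,
) -> MatchReport:
    """Best match category for a candidate across a host reference set.

    Precedence EXACT_FULL > NEAR > PARTIAL > NONE; within a category the
    report with the longest match, then fewest mismatches, then smallest
    reference start wins.
    """
    cfg = cfg or MatchConfig()
    if not references:
        raise ValueError("at least one reference required")
    reports: list[MatchReport] = []
    for ref in references:
        if len(candidate) <= len(ref):
            reports.append(best_windowed_match(candidate, ref, cfg))
        reports.append(longest_perfect_stretch(candidate, ref, cfg))
    real = [r for r in reports if r.category is not MatchCategory.NONE]
    if not real:
        return _none_report(candidate.id)
    return min(
        real,
        key=lambda r: (
            _CATEGORY_RANK[r.category],
            -r.matched_length,
            r.mismatches if r.mismatches is not None else 0,
            r.ref_start,
        ),
    )


def classify_all(
    candidates: Iterable[NucSequence],
    references: Sequence[NucSequence],
    cfg: MatchConfig | None = None,
) -> list[MatchReport]:
    return [classify_host_match(c, references, cfg) for c in candidates]
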