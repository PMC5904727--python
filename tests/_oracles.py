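"""Independent brute-force oracles for the sequence matchers.

Pure-Python, loop-based reimplementations used only to check the
vectorised matchers; they share no code with the implementation.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def oracle_exact_occurrences(candidate: str, reference: str) -> list[tuple[int, str]]:
    """All (start, strand) full-length perfect placements, + strand first."""
    hits = []
    for strand, probe in (("+", candidate), ("-", revcomp(candidate))):
        for i in range(len(reference) - len(probe) + 1):
            if reference[i:i + len(probe)] == probe:
                hits.append((i, strand))
    return hits


def oracle_longest_common_substring(candidate: str, reference: str) -> int:
    """Length of the longest substring of candidate present in reference."""
    for k in range(len(candidate), 0, -1):
        for i in range(len(candidate) - k + 1):
            if candidate[i:i + k] in reference:
                return k
    return 0


def oracle_longest_shared_stretch(candidate: str, reference: str) -> int:
    """Both-strand variant of the longest shared stretch."""
    return max(
        oracle_longest_common_substring(candidate, reference),
        oracle_longest_common_substring(revcomp(candidate), reference),
    )


def oracle_min_hamming(candidate: str, reference: str) -> int:
    """Minimum mismatches over all full-length windows, both strands."""
    best = len(candidate) + 1
    for probe in (candidate, revcomp(candidate)):
        for i in range(len(reference) - len(probe) + 1):
            window = reference[i:i + len(probe)]
            mm = sum(1 for a, b in zip(probe, window) if a != b)
            if mm < best:
                best = mm
    return best


def oracle_min_hamming_with_pos(candidate: str, reference: str) -> tuple[int, int, str]:
    """(mismatches, ref_start, strand) of the best window; ties toward
    the smallest start, then the + strand."""
    best: tuple[int, int, int] | None = None
    for rank, probe in enumerate((candidate, revcomp(candidate))):
        for i in range(len(reference) - len(probe) + 1):
            window = reference[i:i + len(probe)]
            mm = sum(1 for a, b in zip(probe, window) if a != b)
            key = (mm, i, rank)
            if best is None or key < best:
                best = key
    assert best is not None
    return best[0], best[1], "+-"[best[2]]
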