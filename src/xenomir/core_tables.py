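"""Count-table screening arithmetic for putative foreign (xeno) miRNAs.

Small RNA-seq studies of biofluids occasionally report plant-annotated
miRNAs in human samples.  Before any biological interpretation, the raw
mapped-count table has to survive elementary screening: merging duplicate
sequencing runs, translating a reads-per-million (rpm) expression cutoff
into raw counts for the average library, permissive inclusion criteria
(a few reads in a minimal fraction of samples), and a background cutoff
on the per-candidate median.  This module implements that arithmetic on
a candidate x sample integer matrix.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("plasma", "cell", "other")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation.

    ``library_id`` groups duplicate sequencing runs of one physical
    library; ``total_reads`` is the number of reads sequenced (not
    mapped) and is only needed for the average-rpm variant.
    """

    sample_id: str
    library_id: str
    study: str
    sample_type: str = "other"
    total_reads: int | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"sample_type must be one of {SAMPLE_TYPES}, got {self.sample_type!r}"
            )
        if self.total_reads is not None and self.total_reads <= 0:
            raise ValueError("total_reads must be positive when given")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and normalization constants for the count screen.

    rpm_cutoff : expression cutoff in reads per million mapped reads.
    min_reads : per-sample raw count required for a sample to "have" a
        candidate (inclusion criterion).
    min_sample_fraction : fraction of samples that must reach min_reads.
    mean_reads_per_sample : average sequencing depth of a library
        (reads), used when translating between rpm and raw counts.
    mapping_fraction : fraction of sequenced reads that mapped; every
        rpm<->count translation takes its value from here explicitly, so
        a rough figure (e.g. 0.5) and a back-derived midpoint (0.475)
        are both expressed by passing a config holding that value.
    background_median_reads : per-candidate median raw-count threshold
        separating signal from background.
    """

    rpm_cutoff: float = 32.0
    min_reads: int = 3
    min_sample_fraction: float = 0.10
    mean_reads_per_sample: float = 12.5e6
    mapping_fraction: float = 0.475
    background_median_reads: float = 200

    def __post_init__(self) -> None:
        if self.rpm_cutoff < 0:
            raise ValueError("rpm_cutoff must be >= 0")
        if not 0 < self.min_sample_fraction <= 1:
            raise ValueError("min_sample_fraction must be in (0, 1]")
        if not 0 < self.mapping_fraction <= 1:
            raise ValueError("mapping_fraction must be in (0, 1]")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.mean_reads_per_sample <= 0:
            raise ValueError("mean_reads_per_sample must be positive")


@dataclass(frozen=True)
class CandidateSummary:
    """Per-candidate screening statistics (one summary-table row)."""

    candidate_id: str
    n_samples_at_min_reads: int
    mean_counts: float
    median_counts: float
    max_counts: float
    est_median_rpm: float
    avg_rpm: float | None = None


class CountMatrix:
    """Candidate x sample matrix of integer mapped-read counts.

    Thin validated wrapper around a pandas DataFrame (rows = candidate
    ids, columns = sample ids).  Counts are non-negative integers;
    identifiers are unique on both axes.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            raise ValueError("duplicate candidate identifiers")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        values = counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                if not np.all(np.equal(np.mod(values, 1), 0)):
                    raise ValueError("counts must be integers")
            if (values < 0).any():
                raise ValueError("counts must be non-negative")
        self._frame = counts.astype(np.int64)

    @property
    def candidates(self) -> list[str]:
        return list(self._frame.index)

    @property
    def samples(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def row(self, candidate_id: str) -> np.ndarray:
        if candidate_id not in self._frame.index:
            raise KeyError(f"unknown candidate {candidate_id!r}")
        return self._frame.loc[candidate_id].to_numpy()

    def total(self) -> int:
        return int(self._frame.to_numpy().sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:
        return f"CountMatrix({self.shape[0]} candidates x {self.shape[1]} samples)"


def _meta_by_sample(meta: Iterable[SampleMeta]) -> dict[str, SampleMeta]:
    out: dict[str, SampleMeta] = {}
    for m in meta:
        if m.sample_id in out:
            raise ValueError(f"duplicate metadata for sample {m.sample_id!r}")
        out[m.sample_id] = m
    return out


def merge_replicate_runs(
    counts: CountMatrix,
    meta: Iterable[SampleMeta],
    drop_incomplete: bool = True,
) -> tuple[CountMatrix, list[SampleMeta]]:
    """Sum duplicate sequencing runs of each library into one column.

    Libraries sequenced fewer times than the modal number of runs are
    dropped when ``drop_incomplete`` (their single run is not a reliable
    replicate of the study design).  Returns the merged matrix plus
    library-level metadata (one record per retained library, total_reads
    summed over its runs when available).
    """
    by_sample = _meta_by_sample(meta)
    frame = counts.to_frame()
    missing = [s for s in frame.columns if s not in by_sample]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    extra = [s for s in by_sample if s not in frame.columns]
    if extra:
        raise ValueError(f"metadata for unknown samples: {extra}")

    runs_per_lib: dict[str, list[str]] = {}
    for sample in frame.columns:
        runs_per_lib.setdefault(by_sample[sample].library_id, []).append(sample)

    modal_runs = Counter(len(v) for v in runs_per_lib.values()).most_common(1)[0][0]
    kept = {
        lib: samples
        for lib, samples in runs_per_lib.items()
        if not drop_incomplete or len(samples) >= modal_runs
    }
    if not kept:
        raise ValueError("no libraries left after excluding incomplete replicates")

    merged = pd.DataFrame(
        {lib: frame[samples].sum(axis=1) for lib, samples in kept.items()},
        index=frame.index,
    )
    lib_meta: list[SampleMeta] = []
    for lib, samples in kept.items():
        first = by_sample[samples[0]]
        totals = [by_sample[s].total_reads for s in samples]
        total = sum(t for t in totals if t is not None) if any(t is not None for t in totals) else None
        lib_meta.append(
            SampleMeta(
                sample_id=lib,
                library_id=lib,
                study=first.study,
                sample_type=first.sample_type,
                total_reads=total,
            )
        )
    return CountMatrix(merged), lib_meta


def reads_for_rpm_cutoff(cfg: ScreenConfig) -> float:
    """Raw mapped reads corresponding to the rpm cutoff in the average sample.

    rpm_cutoff x mean_reads_per_sample x mapping_fraction / 1e6: e.g. a
    32 rpm cutoff at 12.5 million reads with about half the reads mapped
    is about 200 mapped reads.
    """
    return cfg.rpm_cutoff * cfg.mean_reads_per_sample * cfg.mapping_fraction / 1e6


def estimate_rpm(count: float, cfg: ScreenConfig) -> float:
    """Reads-per-million estimate for a raw count in the average sample.

    Inverse of :func:`reads_for_rpm_cutoff`:
    count / (mean_reads_per_sample x mapping_fraction) x 1e6.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    denom = cfg.mean_reads_per_sample * cfg.mapping_fraction
    if denom <= 0:
        raise ValueError("normalization constants must be positive")
    return count / denom * 1e6


def summarize_candidate(
    counts: CountMatrix,
    candidate_id: str,
    cfg: ScreenConfig,
    meta: Iterable[SampleMeta] | None = None,
) -> CandidateSummary:
    """One summary-table row for a candidate.

    Mean/median/max are over all samples (median of an even number of
    samples is the mean of the two central values, so half-integers are
    expected).  ``avg_rpm`` is filled only when per-sample total_reads
    are supplied through ``meta`` for every sample.
    """
    row = counts.row(candidate_id)
    n_at_min = int((row >= cfg.min_reads).sum())
    median = float(np.median(row)) if row.size else 0.0
    mean = float(row.mean()) if row.size else 0.0
    mx = float(row.max()) if row.size else 0.0

    avg_rpm: float | None = None
    if meta is not None:
        by_sample = _meta_by_sample(meta)
        totals = [by_sample[s].total_reads if s in by_sample else None for s in counts.samples]
        if totals and all(t is not None for t in totals):
            avg_rpm = float(np.mean([c / t * 1e6 for c, t in zip(row, totals)]))

    return CandidateSummary(
        candidate_id=candidate_id,
        n_samples_at_min_reads=n_at_min,
        mean_counts=mean,
        median_counts=median,
        max_counts=mx,
        est_median_rpm=estimate_rpm(median, cfg),
        avg_rpm=avg_rpm,
    )


def summarize_all(
    counts: CountMatrix, cfg: ScreenConfig, meta: Iterable[SampleMeta] | None = None
) -> list[CandidateSummary]:
    meta_list = list(meta) if meta is not None else None
    return [summarize_candidate(counts, c, cfg, meta_list) for c in counts.candidates]


def min_samples_required(cfg: ScreenConfig, n_samples: int) -> int:
    """Ceiling of the sample-fraction threshold (10% of 23 samples -> 3)."""
    # tiny epsilon so binary-representation noise (0.1 * 10) does not
    # push an exact boundary over the ceiling
    return max(1, math.ceil(cfg.min_sample_fraction * n_samples - 1e-9))


def inclusion_screen(
    counts: CountMatrix,
    cfg: ScreenConfig,
    annotated: Iterable[str],
) -> list[str]:
    """Permissive candidate filter.

    A candidate is included when it has >= cfg.min_reads mapped reads in
    at least ceil(min_sample_fraction x n_samples) samples AND its
    mature sequence is discoverable (id present in ``annotated``).
    Result is ordered by samples-at-threshold descending, then mean
    descending, then id.
    """
    if not counts.samples:
        raise ValueError("count matrix has no samples")
    annotated_set = set(annotated)
    need = min_samples_required(cfg, len(counts.samples))
    rows: list[tuple[int, float, str]] = []
    frame = counts.to_frame()
    at_min = (frame.to_numpy() >= cfg.min_reads).sum(axis=1)
    means = frame.to_numpy().mean(axis=1)
    for cand, n, m in zip(counts.candidates, at_min, means):
        if n >= need and cand in annotated_set:
            rows.append((int(n), float(m), cand))
    rows.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return [cand for _, _, cand in rows]


def background_screen(
    summaries: Sequence[CandidateSummary], cfg: ScreenConfig
) -> list[str]:
    """Candidates whose median raw count is strictly above background."""
    return [
        s.candidate_id
        for s in summaries
        if s.median_counts > cfg.background_median_reads
    ]


def subset_by_sample_type(
    counts: CountMatrix, meta: Iterable[SampleMeta], sample_type: str
) -> CountMatrix:
    """Restrict columns to samples of one type; all candidate rows kept."""
    if sample_type not in SAMPLE_TYPES:
        raise ValueError(f"sample_type must be one of {SAMPLE_TYPES}")
    by_sample = _meta_by_sample(meta)
    keep = [s for s in counts.samples if by_sample.get(s) and by_sample[s].sample_type == sample_type]
    if not keep:
        raise ValueError(f"no samples of type {sample_type!r}")
    return CountMatrix(counts.to_frame()[keep])


def count_samples_by_type(meta: Iterable[SampleMeta]) -> dict[str, int]:
    """Audit helper: number of libraries of each sample type.

    Counts distinct libraries (not sequencing runs), so a study whose
    libraries were each sequenced twice contributes each library once.
    """
    seen: dict[str, str] = {}
    for m in meta:
        key = f"{m.study}/{m.library_id}"
        if key in seen and seen[key] != m.sample_type:
            raise ValueError(f"conflicting sample_type for library {key}")
        seen[key] = m.sample_type
    out: dict[str, int] = {t: 0 for t in SAMPLE_TYPES}
    for t in seen.values():
        out[t] += 1
    return out
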