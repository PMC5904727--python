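"""Synthetic study generator with ground truth for every pipeline stage.

Emulates the statistical structure that makes xenomiR artifact screening
testable without any download:

* count matrices in which most candidates show sporadic, low,
  Poisson-distributed background counts (contamination / sequencing
  error-like) while a few host-derived candidates are consistently
  abundant in every library;
* per-library duplicate sequencing runs (library totals split
  binomially across runs) and two study layouts with different sample
  types (a large all-plasma study, a small mixed cells + plasma study);
* candidate / host / foreign reference FASTA material with planted
  host-side regions at controlled match levels (verbatim copy, shared
  15-nt block only, full-length copy with exactly one substitution, or
  nothing);
* labelled read sets mixing host-origin reads (with a bounded number of
  injected substitutions), verbatim foreign-origin reads, and random
  noise reads.

Every draw flows from a single integer seed, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import AnnotationRecord
from .core_tables import CountMatrix, SampleMeta
from .seq_match import NucSequence, reverse_complement, _encode, _window_mismatch_counts
from .stringent_filter import Read, ReadSet

_BASES = "ACGT"

MATCH_LEVELS = ("exact", "partial15", "near1", "none")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the generator; defaults mirror the large-study layout
    (190-odd plasma libraries each sequenced twice, one rRNA-like
    host-derived candidate around a thousand reads per library, sparse
    background around 0.2 reads per candidate-sample)."""

    seed: int = 0
    n_libraries: int = 190
    runs_per_library: int = 2
    n_incomplete_libraries: int = 0  # libraries with a single run (dropped at merge)
    n_candidates: int = 20
    n_host_derived: int = 1
    background_rate: float = 0.2
    host_abundance_mean: float = 1100.0
    study: str = "study1"
    sample_type: str = "plasma"
    batch_multiplier: float = 1.0  # per-study scale on the background rate
    candidate_length_range: tuple[int, int] = (20, 24)
    host_flank_length: int = 120
    n_host_references: int = 3
    n_foreign_references: int = 2
    mismatch_plant_levels: tuple[str, ...] | None = None
    read_length_range: tuple[int, int] = (18, 26)
    n_reads: int = 1000
    fraction_host_reads: float = 0.6
    fraction_foreign_reads: float = 0.3
    host_read_max_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.n_libraries < 1 or self.n_candidates < 1:
            raise ValueError("need at least one library and one candidate")
        if self.runs_per_library < 1:
            raise ValueError("runs_per_library must be >= 1")
        if not 0 <= self.n_host_derived <= self.n_candidates:
            raise ValueError("n_host_derived out of range")
        if self.background_rate < 0 or self.host_abundance_mean < 0:
            raise ValueError("rates must be >= 0")
        f = self.fraction_host_reads + self.fraction_foreign_reads
        if not (0 <= self.fraction_host_reads <= 1 and 0 <= self.fraction_foreign_reads <= 1 and f <= 1 + 1e-12):
            raise ValueError("read fractions must lie in [0,1] and sum to <= 1")
        if self.mismatch_plant_levels is not None:
            bad = set(self.mismatch_plant_levels) - set(MATCH_LEVELS)
            if bad:
                raise ValueError(f"unknown match levels: {sorted(bad)}")
        if self.read_length_range[0] < 15:
            raise ValueError("reads shorter than 15 nt are too promiscuous to match")


@dataclass
class GroundTruth:
    """What the generator actually planted, for exact recovery checks."""

    candidate_class: dict[str, str] = field(default_factory=dict)  # host_derived | background
    candidate_match_level: dict[str, str] = field(default_factory=dict)
    planted_regions: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    library_totals: pd.DataFrame | None = None  # candidate x library, pre-split
    read_origin: dict[str, str] = field(default_factory=dict)  # host | foreign | noise
    expected_read_category: dict[str, str] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _cycle_base(base: str) -> str:
    """Deterministic substitution: the next base in ACGT order."""
    return _BASES[(_BASES.index(base) + 1) % 4]


def candidate_ids(cfg: SimConfig) -> list[str]:
    return [f"cand_{i:03d}" for i in range(cfg.n_candidates)]


def resolve_match_levels(cfg: SimConfig) -> list[str]:
    """Per-candidate planted host-match level.

    Host-derived candidates are planted verbatim (they ARE host
    sequences - the MIR2910-like case); background candidates cycle
    through none / partial / near so every category is exercised.
    """
    if cfg.mismatch_plant_levels is not None:
        if len(cfg.mismatch_plant_levels) != cfg.n_candidates:
            raise ValueError("mismatch_plant_levels must have one entry per candidate")
        return list(cfg.mismatch_plant_levels)
    levels = []
    cycle = ("none", "partial15", "near1")
    for i in range(cfg.n_candidates):
        if i < cfg.n_host_derived:
            levels.append("exact")
        else:
            levels.append(cycle[(i - cfg.n_host_derived) % 3])
    return levels


def simulate_count_study(
    cfg: SimConfig,
) -> tuple[CountMatrix, list[SampleMeta], GroundTruth]:
    """Run-level count matrix with sporadic background + abundant host rows.

    Library totals are drawn per candidate (Poisson at the background
    rate scaled by the batch multiplier, or at the host abundance mean
    for host-derived candidates) and then split uniformly-multinomially
    across that library's sequencing runs, so summing a library's runs
    recovers its total exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    cands = candidate_ids(cfg)
    libs = [f"{cfg.study}_lib{j:03d}" for j in range(cfg.n_libraries)]

    totals = np.empty((cfg.n_candidates, cfg.n_libraries), dtype=np.int64)
    gt = GroundTruth()
    for i, cand in enumerate(cands):
        if i < cfg.n_host_derived:
            totals[i] = rng.poisson(cfg.host_abundance_mean, size=cfg.n_libraries)
            gt.candidate_class[cand] = "host_derived"
        else:
            totals[i] = rng.poisson(
                cfg.background_rate * cfg.batch_multiplier, size=cfg.n_libraries
            )
            gt.candidate_class[cand] = "background"
    gt.library_totals = pd.DataFrame(totals, index=cands, columns=libs)

    if cfg.n_incomplete_libraries > cfg.n_libraries:
        raise ValueError("more incomplete libraries than libraries")
    incomplete = set(
        rng.choice(cfg.n_libraries, size=cfg.n_incomplete_libraries, replace=False)
    )

    columns: dict[str, np.ndarray] = {}
    meta: list[SampleMeta] = []
    for j, lib in enumerate(libs):
        n_runs = 1 if j in incomplete else cfg.runs_per_library
        if n_runs == 1:
            split = totals[:, j][:, None]
        else:
            pvals = np.full(n_runs, 1.0 / n_runs)
            split = np.stack(
                [rng.multinomial(int(t), pvals) for t in totals[:, j]], axis=0
            )
        for r in range(n_runs):
            sample = f"{lib}_r{r + 1}"
            columns[sample] = split[:, r]
            meta.append(
                SampleMeta(
                    sample_id=sample,
                    library_id=lib,
                    study=cfg.study,
                    sample_type=cfg.sample_type,
                )
            )
    frame = pd.DataFrame(columns, index=cands)
    return CountMatrix(frame), meta, gt


def simulate_two_study_design(
    seed: int,
) -> tuple[
    tuple[CountMatrix, list[SampleMeta], GroundTruth],
    tuple[CountMatrix, list[SampleMeta], GroundTruth],
]:
    """The two-study layout: a large all-plasma study whose 192 libraries
    were each sequenced twice (2 of them only once), and a small
    single-run study of 17 cell samples plus 6 plasma samples."""
    big = SimConfig(
        seed=seed, study="plasma_study", n_libraries=192, runs_per_library=2,
        n_incomplete_libraries=2, sample_type="plasma",
    )
    study_a = simulate_count_study(big)

    cells = SimConfig(
        seed=seed + 1, study="mixed_study", n_libraries=17, runs_per_library=1,
        sample_type="cell", host_abundance_mean=370.0, batch_multiplier=2.0,
    )
    plasma = SimConfig(
        seed=seed + 2, study="mixed_study", n_libraries=6, runs_per_library=1,
        sample_type="plasma", host_abundance_mean=1200.0,
    )
    m_cells, meta_cells, gt_cells = simulate_count_study(cells)
    m_plasma, meta_plasma, gt_plasma = simulate_count_study(plasma)
    # same candidate rows, disjoint sample columns; relabel plasma libraries
    fc = m_cells.to_frame()
    fp = m_plasma.to_frame()
    fp.columns = [c.replace("_lib", "_plib") for c in fp.columns]
    meta_plasma = [
        SampleMeta(
            sample_id=m.sample_id.replace("_lib", "_plib"),
            library_id=m.library_id.replace("_lib", "_plib"),
            study=m.study, sample_type=m.sample_type, total_reads=m.total_reads,
        )
        for m in meta_plasma
    ]
    gt = GroundTruth(candidate_class=gt_cells.candidate_class)
    study_b = (
        CountMatrix(pd.concat([fc, fp], axis=1)),
        meta_cells + meta_plasma,
        gt,
    )
    return study_a, study_b


def _plant(
    host_parts: list[str],
    pos: int,
    insert: str,
) -> int:
    host_parts.append(insert)
    return pos + len(insert)


def simulate_references(
    cfg: SimConfig,
) -> tuple[list[NucSequence], list[NucSequence], list[NucSequence], GroundTruth]:
    """Candidate, host, and foreign reference sequences with planted matches.

    Per candidate, its configured level plants into one host reference:
    ``exact`` a verbatim copy, ``partial15`` a window sharing exactly its
    first 15 nt (every later position deliberately substituted, so the
    stretch cannot silently extend into a near-match), ``near1`` a
    full-length copy with exactly one substitution at the middle
    position, ``none`` nothing.  Foreign references jointly contain all
    candidates verbatim.
    """
    rng = np.random.default_rng(cfg.seed + 10_007)
    cands: list[NucSequence] = []
    gt = GroundTruth()
    lo, hi = cfg.candidate_length_range
    for cand_id in candidate_ids(cfg):
        length = int(rng.integers(lo, hi + 1))
        cands.append(NucSequence(cand_id, _random_seq(rng, length)))

    levels = resolve_match_levels(cfg)
    for c, level in zip(cands, levels):
        gt.candidate_match_level[c.id] = level

    host_parts: dict[int, list[str]] = {i: [] for i in range(cfg.n_host_references)}
    host_pos: dict[int, int] = {i: 0 for i in range(cfg.n_host_references)}
    host_ids = [f"synthetic_host_ref_{i + 1}" for i in range(cfg.n_host_references)]

    for idx, (cand, level) in enumerate(zip(cands, levels)):
        ref_idx = idx % cfg.n_host_references
        flank = _random_seq(rng, cfg.host_flank_length)
        host_pos[ref_idx] = _plant(host_parts[ref_idx], host_pos[ref_idx], flank)
        seq = cand.residues
        insert: str | None
        if level == "exact":
            insert = seq
        elif level == "near1":
            mid = len(seq) // 2
            insert = seq[:mid] + _cycle_base(seq[mid]) + seq[mid + 1:]
        elif level == "partial15":
            tail = "".join(_cycle_base(b) for b in seq[15:])
            insert = seq[:15] + tail
        else:
            insert = None
        if insert is not None:
            # antisense plants for every other exact/near candidate keep the
            # minus-strand path exercised
            strand = "-" if (level in ("exact", "near1") and idx % 2 == 1) else "+"
            planted = reverse_complement(insert) if strand == "-" else insert
            start = host_pos[ref_idx]
            host_pos[ref_idx] = _plant(host_parts[ref_idx], start, planted)
            gt.planted_regions[cand.id] = (
                host_ids[ref_idx], start, start + len(planted), strand
            )
    for i in range(cfg.n_host_references):
        host_parts[i].append(_random_seq(rng, cfg.host_flank_length))

    hosts = [
        NucSequence(host_ids[i], "".join(host_parts[i]))
        for i in range(cfg.n_host_references)
    ]

    foreign_parts: dict[int, list[str]] = {i: [] for i in range(cfg.n_foreign_references)}
    for idx, cand in enumerate(cands):
        ref_idx = idx % cfg.n_foreign_references
        foreign_parts[ref_idx].append(_random_seq(rng, cfg.host_flank_length // 2))
        foreign_parts[ref_idx].append(cand.residues)
    foreigns = []
    for i in range(cfg.n_foreign_references):
        foreign_parts[i].append(_random_seq(rng, cfg.host_flank_length // 2))
        foreigns.append(NucSequence(f"synthetic_foreign_ref_{i + 1}", "".join(foreign_parts[i])))

    gt.candidate_class = {
        c.id: ("host_derived" if i < cfg.n_host_derived else "background")
        for i, c in enumerate(cands)
    }
    return cands, hosts, foreigns, gt


def _min_hamming_both_strands(seq: str, refs: Sequence[NucSequence]) -> int:
    """Generator-side check (numpy window scan) used for rejection sampling."""
    best = len(seq) + 1
    for variant in (seq, reverse_complement(seq)):
        arr = _encode(variant)
        for ref in refs:
            if len(arr) > len(ref.residues):
                continue
            mm = _window_mismatch_counts(arr, _encode(ref.residues))
            best = min(best, int(mm.min()))
    return best


def _occurs_perfectly(seq: str, refs: Sequence[NucSequence]) -> int:
    rc = reverse_complement(seq)
    return sum(1 for r in refs if seq in r.residues or rc in r.residues)


def simulate_reads(
    cfg: SimConfig,
    host_refs: Sequence[NucSequence],
    foreign_refs: Sequence[NucSequence],
) -> tuple[ReadSet, GroundTruth]:
    """Labelled read mix: host-origin, foreign-origin, and noise reads.

    Host reads are windows of host references with 0..host_read_max
    substitutions injected (so they always fall within the subtraction
    budget).  Foreign reads are verbatim windows of foreign references,
    rejection-sampled so none also matches a host reference within the
    budget (otherwise their filter category would be genuinely host).
    Noise reads are random sequences, rejection-sampled away from both
    reference sets.  Expected filter categories are recorded per read.
    """
    rng = np.random.default_rng(cfg.seed + 20_011)
    gt = GroundTruth()
    reads: list[Read] = []
    n_host = int(round(cfg.n_reads * cfg.fraction_host_reads))
    n_foreign = int(round(cfg.n_reads * cfg.fraction_foreign_reads))
    n_noise = cfg.n_reads - n_host - n_foreign
    lo, hi = cfg.read_length_range

    def window(ref: NucSequence, length: int) -> str:
        start = int(rng.integers(0, len(ref.residues) - length + 1))
        w = ref.residues[start:start + length]
        return w if rng.random() < 0.5 else reverse_complement(w)

    k = 0
    for _ in range(n_host):
        ref = host_refs[int(rng.integers(len(host_refs)))]
        length = int(rng.integers(lo, hi + 1))
        seq = list(window(ref, length))
        n_mm = int(rng.integers(0, cfg.host_read_max_mismatches + 1))
        for pos in rng.choice(length, size=n_mm, replace=False):
            seq[pos] = _cycle_base(seq[pos])
        rid = f"read_{k:05d}"
        k += 1
        reads.append(Read(rid, NucSequence(rid, "".join(seq)), origin="host"))
        gt.read_origin[rid] = "host"
        gt.expected_read_category[rid] = "host_removed"

    for _ in range(n_foreign):
        while True:
            ref = foreign_refs[int(rng.integers(len(foreign_refs)))]
            length = int(rng.integers(lo, hi + 1))
            seq = window(ref, length)
            if _min_hamming_both_strands(seq, host_refs) > cfg.host_read_max_mismatches:
                break
        rid = f"read_{k:05d}"
        k += 1
        reads.append(Read(rid, NucSequence(rid, seq), origin="foreign"))
        gt.read_origin[rid] = "foreign"
        n_refs = _occurs_perfectly(seq, foreign_refs)
        gt.expected_read_category[rid] = "ambiguous" if n_refs > 1 else "foreign_assigned"

    for _ in range(n_noise):
        while True:
            length = int(rng.integers(lo, hi + 1))
            seq = _random_seq(rng, length)
            if (
                _min_hamming_both_strands(seq, host_refs) > cfg.host_read_max_mismatches
                and _occurs_perfectly(seq, foreign_refs) == 0
            ):
                break
        rid = f"read_{k:05d}"
        k += 1
        reads.append(Read(rid, NucSequence(rid, seq), origin="noise"))
        gt.read_origin[rid] = "noise"
        gt.expected_read_category[rid] = "unassigned"

    return ReadSet(reads), gt


def simulate_annotations(
    candidates: Sequence[NucSequence], gt: GroundTruth
) -> list[AnnotationRecord]:
    """Neutral annotation table for synthetic candidates.

    Every candidate is treated as a currently annotated miRNA of unknown
    biotype, so triage outcomes are driven purely by counts and host
    matches - the hardest setting for the no-false-xenomiR property.
    """
    return [
        AnnotationRecord(
            candidate_id=c.id,
            sequence=c.residues,
            in_current_mirbase=True,
            plant_biotype="UNKNOWN",
            claimed_species="synthetic",
        )
        for c in candidates
    ]
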