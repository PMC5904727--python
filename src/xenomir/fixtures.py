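"""Packaged screening fixture: the 15 recurrent putative plant miRNAs.

The 15 candidate mature sequences that pass the permissive inclusion
screen in the two public plasma studies, together with their published
per-study count summaries, annotation status (miRBase membership and
plant biotype), and host-match category (exact / partial >= 15 nt /
1-mismatch near match / none, with one antisense case).

Host reference sequences are SYNTHETIC stand-ins: deterministic random
flanks with each candidate's documented match level planted, built so
the classifier reproduces the published category pattern without any
database download.  They are not the real human transcripts (18S rRNA
etc.) the categories were originally established against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import AnnotationRecord
from .core_tables import CandidateSummary, ScreenConfig, estimate_rpm
from .seq_match import NucSequence, reverse_complement
from .synthetic import _cycle_base, _random_seq

_FIXTURE_SEED = 20180228


@dataclass(frozen=True)
class FixtureCandidate:
    candidate_id: str
    sequence: str  # mature sequence as published (RNA alphabet)
    studies: str  # big-plasma study, mixed study, or both
    in_current_mirbase: bool
    plant_biotype: str
    host_match_level: str  # exact | exact_antisense | near1 | partial15 | none
    # published count summary (n samples with >=3 reads, mean, median, max)
    n_samples_at_min_reads: int
    mean_counts: float
    median_counts: float
    max_counts: float


TABLE_CANDIDATES: tuple[FixtureCandidate, ...] = (
    FixtureCandidate("peu-MIR2910", "UAGUUGGUGGAGCGAUUUGUC", "both", False,
                     "RRNA_FRAGMENT", "exact", 190, 1143.4, 1072.5, 2020),
    FixtureCandidate("peu-MIR2916", "UGGGGACUCGAAGACGAUCAUAU", "plasma", True,
                     "RRNA_FRAGMENT", "partial15", 190, 119.7, 115, 315),
    FixtureCandidate("tae-MIR2005", "GGGUGUAUAGCUCAGUUGG", "both", False,
                     "MITOCHONDRIAL", "partial15", 178, 8.7, 9, 23),
    FixtureCandidate("peu-MIR2914", "CAUGGUGGUGACGGGUGACGGAG", "both", False,
                     "RRNA_FRAGMENT", "partial15", 169, 14.3, 9, 348),
    FixtureCandidate("tae-MIR2018", "GCCCGUCUAGCUCAGUUGGU", "both", False,
                     "MULTI_TRANSCRIPT", "partial15", 167, 5.9, 6, 14),
    FixtureCandidate("ath-MIRf10482-akr", "UCUACUCGACUAGGUGGUCGAGUGG", "plasma", False,
                     "UNKNOWN", "partial15", 161, 7.3, 6, 29),
    FixtureCandidate("ppt-MIR896", "GUCAAUUUGGCCGAGUGGUUAAGGC", "plasma", False,
                     "TRNA_FRAGMENT", "partial15", 147, 4.6, 4, 15),
    FixtureCandidate("ptc-MIRf12412-akr", "GCUGGGAUUACAGGCGUGAGCCACC", "both", False,
                     "UNMAPPED_IN_CLAIMED_SPECIES", "exact", 47, 2.7, 2, 18),
    FixtureCandidate("peu-MIR2911", "GGCCGGGGGACGGGCUGGGA", "plasma", False,
                     "RRNA_FRAGMENT", "near1", 42, 2.6, 2, 10),
    FixtureCandidate("ppt-MIR894", "CGUUUCACGUCGGGUUCACC", "plasma", True,
                     "MULTI_TRANSCRIPT", "none", 39, 2.3, 2, 18),
    FixtureCandidate("ptc-MIRf12524-akr", "CCUGUAAUCCCAGCUACUCGGG", "both", False,
                     "UNMAPPED_IN_CLAIMED_SPECIES", "exact", 28, 1.8, 1, 5),
    FixtureCandidate("ath-MIRf10045-akr", "UCUACUCGACCUGGUGGUCGAGUGGU", "mixed", False,
                     "UNKNOWN", "partial15", 4, 5, 4, 10),
    FixtureCandidate("ath-MIRf10046-akr", "CUCGACCUGGUGGUCGAGUGGU", "mixed", False,
                     "UNKNOWN", "partial15", 4, 5, 4, 10),
    FixtureCandidate("peu-MIR2915", "CCCGUCUAGCUCAGUUGGUA", "mixed", False,
                     "TRNA_FRAGMENT", "partial15", 3, 5, 4.5, 8),
    FixtureCandidate("ptc-MIRf10804-akr", "CCUGUAAUCCCAGCACUUUGG", "mixed", False,
                     "MICROSATELLITE", "exact_antisense", 17, 26, 26, 60),
)


def fixture_candidates() -> list[NucSequence]:
    return [NucSequence(c.candidate_id, c.sequence) for c in TABLE_CANDIDATES]


def fixture_annotations() -> list[AnnotationRecord]:
    return [
        AnnotationRecord(
            candidate_id=c.candidate_id,
            sequence=c.sequence,
            in_current_mirbase=c.in_current_mirbase,
            plant_biotype=c.plant_biotype,
            claimed_species=c.candidate_id.split("-")[0],
        )
        for c in TABLE_CANDIDATES
    ]


def fixture_summaries(cfg: ScreenConfig | None = None) -> list[CandidateSummary]:
    """Published per-candidate count summaries as CandidateSummary rows."""
    cfg = cfg or ScreenConfig()
    return [
        CandidateSummary(
            candidate_id=c.candidate_id,
            n_samples_at_min_reads=c.n_samples_at_min_reads,
            mean_counts=c.mean_counts,
            median_counts=c.median_counts,
            max_counts=c.max_counts,
            est_median_rpm=estimate_rpm(c.median_counts, cfg),
        )
        for c in TABLE_CANDIDATES
    ]


def expected_categories() -> dict[str, str]:
    """Documented host-match category per fixture candidate."""
    mapping = {
        "exact": "EXACT_FULL",
        "exact_antisense": "EXACT_FULL",
        "near1": "NEAR",
        "partial15": "PARTIAL",
        "none": "NONE",
    }
    return {c.candidate_id: mapping[c.host_match_level] for c in TABLE_CANDIDATES}


def build_fixture_host_references(n_refs: int = 3, flank: int = 100) -> list[NucSequence]:
    """Deterministic synthetic host references with planted match regions.

    ``exact`` candidates are planted verbatim; ``exact_antisense`` as the
    reverse complement; ``near1`` as a full-length copy with exactly one
    substitution in the middle; ``partial15`` as a candidate-length
    window whose first 15 nt are shared and whose remaining positions
    are all deliberately substituted (so the shared stretch cannot drift
    into a near-match); ``none`` plants nothing.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    parts: list[list[str]] = [[] for _ in range(n_refs)]
    for idx, cand in enumerate(TABLE_CANDIDATES):
        ref_idx = idx % n_refs
        parts[ref_idx].append(_random_seq(rng, flank))
        seq = NucSequence(cand.candidate_id, cand.sequence).residues
        level = cand.host_match_level
        if level == "exact":
            insert = seq
        elif level == "exact_antisense":
            insert = reverse_complement(seq)
        elif level == "near1":
            mid = len(seq) // 2
            insert = seq[:mid] + _cycle_base(seq[mid]) + seq[mid + 1:]
        elif level == "partial15":
            insert = seq[:15] + "".join(_cycle_base(b) for b in seq[15:])
        else:
            insert = None
        if insert is not None:
            parts[ref_idx].append(insert)
    refs = []
    for i in range(n_refs):
        parts[i].append(_random_seq(rng, flank))
        refs.append(NucSequence(f"synthetic_host_ref_{i + 1}", "".join(parts[i])))
    return refs
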