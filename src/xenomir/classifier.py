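"""Per-candidate triage: counts + annotation + host match -> verdict.

The triage cascade encodes the argument used against dietary-xenomiR
claims: a candidate that occurs (near-)verbatim in the ingesting
organism is most simply a host sequence; one annotated as an rRNA/tRNA
degradation fragment is not a miRNA in the first place; one whose median
count sits below the background threshold is noise.  Only a candidate
that is an annotated miRNA, absent from the host, and consistently above
background remains a plausible xenomiR.

Host evidence is evaluated before biotype, which is evaluated before
abundance; the order is fixed (not configurable) so verdicts stay
comparable across runs.  PARTIAL host matches are recorded as evidence
but never decide a verdict on their own.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .core_tables import CandidateSummary, ScreenConfig
from .seq_match import MatchCategory, MatchReport

PLANT_BIOTYPES = (
    "MIRNA",
    "RRNA_FRAGMENT",
    "TRNA_FRAGMENT",
    "MITOCHONDRIAL",
    "MICROSATELLITE",
    "MULTI_TRANSCRIPT",
    "UNMAPPED_IN_CLAIMED_SPECIES",
    "UNKNOWN",
)

_NONMIRNA_BIOTYPES = frozenset(
    {"RRNA_FRAGMENT", "TRNA_FRAGMENT", "MITOCHONDRIAL", "MICROSATELLITE"}
)


class VerdictLabel(str, Enum):
    HOST_SEQUENCE = "HOST_SEQUENCE"
    LIKELY_NONMIRNA_FRAGMENT = "LIKELY_NONMIRNA_FRAGMENT"
    DATABASE_CONTAMINANT = "DATABASE_CONTAMINANT"
    BELOW_BACKGROUND = "BELOW_BACKGROUND"
    PLAUSIBLE_XENOMIR = "PLAUSIBLE_XENOMIR"
    UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class AnnotationRecord:
    candidate_id: str
    sequence: str
    in_current_mirbase: bool
    plant_biotype: str
    claimed_species: str = ""

    def __post_init__(self) -> None:
        if self.plant_biotype not in PLANT_BIOTYPES:
            raise ValueError(
                f"plant_biotype must be one of {PLANT_BIOTYPES}, got {self.plant_biotype!r}"
            )


@dataclass(frozen=True)
class Verdict:
    candidate_id: str
    label: VerdictLabel
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("evidence must be non-empty")


def triage(
    summary: CandidateSummary,
    annotation: AnnotationRecord,
    host_match: MatchReport,
    cfg: ScreenConfig,
) -> Verdict:
    """Single-candidate verdict from the fixed decision cascade.

    1. host EXACT_FULL + not mapping to the claimed species -> the
       database entry itself is contaminated with a host sequence;
    2. host EXACT_FULL or NEAR -> host sequence;
    3. non-miRNA biotype (rRNA/tRNA fragment, mitochondrial,
       microsatellite) -> degradation fragment / non-miRNA;
    4. median count at or below background -> background noise;
    5. annotated miRNA, no host match, above background -> plausible;
    6. otherwise unresolved.
    """
    ids = {summary.candidate_id, annotation.candidate_id, host_match.candidate_id}
    if len(ids) != 1:
        raise ValueError(f"inputs refer to different candidates: {sorted(ids)}")

    above_background = summary.median_counts > cfg.background_median_reads
    evidence = [
        f"host_match:{host_match.category.value}"
        + (f" ({host_match.reference_id}, strand {host_match.strand})"
           if host_match.reference_id else ""),
        f"biotype:{annotation.plant_biotype}",
        f"mirbase:{'yes' if annotation.in_current_mirbase else 'no'}",
        f"median_counts:{summary.median_counts:g} "
        f"({'above' if above_background else 'at_or_below'} background "
        f"{cfg.background_median_reads:g})",
    ]

    cat = host_match.category
    if cat is MatchCategory.EXACT_FULL and annotation.plant_biotype == "UNMAPPED_IN_CLAIMED_SPECIES":
        evidence.append("rule:exact host match + unmapped in claimed species")
        label = VerdictLabel.DATABASE_CONTAMINANT
    elif cat in (MatchCategory.EXACT_FULL, MatchCategory.NEAR):
        evidence.append("rule:full-length host match within mismatch budget")
        if annotation.plant_biotype in _NONMIRNA_BIOTYPES:
            evidence.append("note:also annotated as a non-miRNA fragment")
        label = VerdictLabel.HOST_SEQUENCE
    elif annotation.plant_biotype in _NONMIRNA_BIOTYPES:
        evidence.append("rule:annotated as a non-miRNA biotype")
        label = VerdictLabel.LIKELY_NONMIRNA_FRAGMENT
    elif not above_background:
        evidence.append("rule:median count at or below background threshold")
        label = VerdictLabel.BELOW_BACKGROUND
    elif annotation.in_current_mirbase and cat is MatchCategory.NONE:
        evidence.append("rule:annotated miRNA, no host match, above background")
        label = VerdictLabel.PLAUSIBLE_XENOMIR
    else:
        evidence.append("rule:no decisive evidence either way")
        label = VerdictLabel.UNRESOLVED

    return Verdict(summary.candidate_id, label, tuple(evidence))


@dataclass(frozen=True)
class TriageTable:
    """Verdict table plus per-label tallies (the report footer)."""

    rows: pd.DataFrame
    label_counts: dict[str, int]


def triage_report(verdicts: Sequence[Verdict]) -> TriageTable:
    """Tabulate verdicts in input order with a per-label count footer."""
    rows = pd.DataFrame(
        [
            {
                "candidate_id": v.candidate_id,
                "label": v.label.value,
                "evidence": "; ".join(v.evidence),
            }
            for v in verdicts
        ],
        columns=["candidate_id", "label", "evidence"],
    )
    counts = Counter(v.label.value for v in verdicts)
    footer = {label.value: counts.get(label.value, 0) for label in VerdictLabel}
    return TriageTable(rows=rows, label_counts=footer)
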