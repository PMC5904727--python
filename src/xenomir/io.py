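"""File formats and configuration.

TSV throughout (matching the supplementary-table style of the source
count data), UTF-8, Unix newlines.  FASTA/FASTQ parsing goes through
Biopython; sequences are normalized to the DNA alphabet on load (RNA U
folded to T).  Output writing is staged to a temporary name and moved
into place, and every artifact is listed in a checksum manifest so
reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .core_tables import CandidateSummary, CountMatrix, SampleMeta, ScreenConfig
from .classifier import AnnotationRecord
from .seq_match import MatchConfig, NucSequence
from .stringent_filter import FilterConfig, Read, ReadSet
from .synthetic import SimConfig


# ---------------------------------------------------------------- sequences

def read_fasta(path: str | os.PathLike) -> list[NucSequence]:
    """Load a multi-record FASTA; ids are headers up to first whitespace."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out: list[NucSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        try:
            out.append(NucSequence(rec.id, str(rec.seq)))
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(seqs: Iterable[NucSequence], path: str | os.PathLike, width: int = 70) -> None:
    lines: list[str] = []
    for s in seqs:
        lines.append(f">{s.id}")
        for i in range(0, len(s.residues), width):
            lines.append(s.residues[i:i + width])
    _atomic_write_text(path, "\n".join(lines) + "\n")


def read_reads(
    path: str | os.PathLike, cfg: FilterConfig | None = None
) -> ReadSet:
    """Load reads from FASTA or FASTQ (format by extension; quality ignored).

    Reads outside the configured length window are rejected: very short
    reads match references too promiscuously for perfect-match logic.
    """
    cfg = cfg or FilterConfig()
    suffix = Path(path).suffix.lower()
    fmt = "fastq" if suffix in (".fastq", ".fq") else "fasta"
    reads: list[Read] = []
    for rec in SeqIO.parse(str(path), fmt):
        seq = NucSequence(rec.id, str(rec.seq))
        if not cfg.min_read_length <= len(seq) <= cfg.max_read_length:
            raise ValueError(
                f"{path}: read {rec.id!r} length {len(seq)} outside "
                f"[{cfg.min_read_length}, {cfg.max_read_length}]"
            )
        reads.append(Read(rec.id, seq))
    if not reads:
        raise ValueError(f"{path}: no reads found")
    return ReadSet(reads)


def write_reads_fastq(reads: ReadSet, path: str | os.PathLike) -> None:
    lines: list[str] = []
    for r in reads.reads:
        lines += [f"@{r.read_id}", r.seq.residues, "+", "I" * len(r.seq)]
    _atomic_write_text(path, "\n".join(lines) + "\n")


# ------------------------------------------------------------------ tables

def read_count_table(path: str | os.PathLike) -> CountMatrix:
    """TSV count table: first column candidate id, one column per sample.

    Blank cells mean zero (a candidate simply absent from a sample's
    table); non-integer cells are an error.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame = frame.fillna("").apply(lambda col: col.str.strip())
    parsed: dict[str, list[int]] = {}
    for col in frame.columns:
        vals = []
        for row, cell in frame[col].items():
            if cell == "":
                vals.append(0)
                continue
            try:
                vals.append(int(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer count {cell!r} at row {row!r}, column {col!r}"
                ) from None
        parsed[col] = vals
    return CountMatrix(pd.DataFrame(parsed, index=frame.index))


def write_count_table(matrix: CountMatrix, path: str | os.PathLike) -> None:
    frame = matrix.to_frame()
    frame.index.name = "candidate_id"
    _atomic_write_text(path, frame.to_csv(sep="\t", lineterminator="\n"))


def read_sample_meta(path: str | os.PathLike) -> list[SampleMeta]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "library_id", "study", "sample_type"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        total = row.get("total_reads", "")
        out.append(
            SampleMeta(
                sample_id=row["sample_id"],
                library_id=row["library_id"],
                study=row["study"],
                sample_type=row["sample_type"],
                total_reads=int(total) if str(total).strip() else None,
            )
        )
    return out


def write_sample_meta(meta: Sequence[SampleMeta], path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "library_id": m.library_id,
                "study": m.study,
                "sample_type": m.sample_type,
                "total_reads": "" if m.total_reads is None else m.total_reads,
            }
            for m in meta
        ]
    )
    _atomic_write_text(path, frame.to_csv(sep="\t", index=False, lineterminator="\n"))


SUMMARY_COLUMNS = [
    "candidate_id",
    "n_samples_at_min_reads",
    "mean_counts",
    "median_counts",
    "max_counts",
    "est_median_rpm",
    "avg_rpm",
]


def summaries_frame(summaries: Sequence[CandidateSummary]) -> pd.DataFrame:
    """Summary rows with the published column set, display-rounded to 1 dp."""
    return pd.DataFrame(
        [
            {
                "candidate_id": s.candidate_id,
                "n_samples_at_min_reads": s.n_samples_at_min_reads,
                "mean_counts": round(s.mean_counts, 1),
                "median_counts": s.median_counts,
                "max_counts": s.max_counts,
                "est_median_rpm": round(s.est_median_rpm, 1),
                "avg_rpm": "" if s.avg_rpm is None else round(s.avg_rpm, 1),
            }
            for s in summaries
        ],
        columns=SUMMARY_COLUMNS,
    )


def read_summaries(path: str | os.PathLike) -> list[CandidateSummary]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in frame.iterrows():
        out.append(
            CandidateSummary(
                candidate_id=row["candidate_id"],
                n_samples_at_min_reads=int(row["n_samples_at_min_reads"]),
                mean_counts=float(row["mean_counts"]),
                median_counts=float(row["median_counts"]),
                max_counts=float(row["max_counts"]),
                est_median_rpm=float(row["est_median_rpm"]),
                avg_rpm=float(row["avg_rpm"]) if str(row.get("avg_rpm", "")).strip() else None,
            )
        )
    return out


def read_annotations(path: str | os.PathLike) -> list[AnnotationRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in frame.iterrows():
        out.append(
            AnnotationRecord(
                candidate_id=row["candidate_id"],
                sequence=row["sequence"],
                in_current_mirbase=str(row["in_current_mirbase"]).strip().lower()
                in ("true", "yes", "1"),
                plant_biotype=row["plant_biotype"],
                claimed_species=row.get("claimed_species", ""),
            )
        )
    return out


def write_annotations(records: Sequence[AnnotationRecord], path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        [
            {
                "candidate_id": r.candidate_id,
                "sequence": r.sequence,
                "in_current_mirbase": str(r.in_current_mirbase).lower(),
                "plant_biotype": r.plant_biotype,
                "claimed_species": r.claimed_species,
            }
            for r in records
        ]
    )
    _atomic_write_text(path, frame.to_csv(sep="\t", index=False, lineterminator="\n"))


# ------------------------------------------------------------------ config

@dataclass(frozen=True)
class RunConfig:
    """All per-stage configs in one structure, mirroring the YAML layout."""

    screen: ScreenConfig = field(default_factory=ScreenConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    sim: SimConfig = field(default_factory=SimConfig)


_SECTION_TYPES = {
    "screen": ScreenConfig,
    "match": MatchConfig,
    "filter": FilterConfig,
    "sim": SimConfig,
}


def load_config(path: str | os.PathLike | None) -> RunConfig:
    """Load a YAML config with sections screen / match / filter / sim.

    Unknown sections or keys are rejected outright; a silently ignored
    typo in a threshold name would change scientific results.
    """
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: config must be a mapping of sections")
    unknown = set(raw) - set(_SECTION_TYPES)
    if unknown:
        raise ValueError(f"{path}: unknown config sections {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        payload = raw.get(section, {}) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - valid
        if bad:
            raise ValueError(f"{path}: unknown keys in [{section}]: {sorted(bad)}")
        # YAML lists for tuple-typed fields
        payload = {
            k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
        }
        kwargs[section] = cls(**payload)
    return RunConfig(**kwargs)


# ----------------------------------------------------------------- outputs

def _atomic_write_text(path: str | os.PathLike, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_outputs(
    tables: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike
) -> pd.DataFrame:
    """Write named tables as TSV plus a sha256 manifest; returns the manifest.

    File names are the table names plus ``.tsv``; rerunning with
    identical inputs reproduces identical checksums.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(tables):
        text = tables[name].to_csv(sep="\t", index=False, lineterminator="\n")
        fname = f"{name}.tsv"
        _atomic_write_text(out_dir / fname, text)
        digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
        entries.append({"file": fname, "sha256": digest})
    manifest = pd.DataFrame(entries, columns=["file", "sha256"])
    _atomic_write_text(
        out_dir / "MANIFEST.tsv",
        manifest.to_csv(sep="\t", index=False, lineterminator="\n"),
    )
    return manifest
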