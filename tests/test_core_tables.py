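"""Count-table screening arithmetic: merging, rpm translation, screens."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xenomir.core_tables import (
    CountMatrix,
    SampleMeta,
    ScreenConfig,
    background_screen,
    count_samples_by_type,
    estimate_rpm,
    inclusion_screen,
    merge_replicate_runs,
    min_samples_required,
    reads_for_rpm_cutoff,
    subset_by_sample_type,
    summarize_all,
    summarize_candidate,
)


def _matrix(data: dict[str, list[int]], candidates: list[str]) -> CountMatrix:
    return CountMatrix(pd.DataFrame(data, index=candidates))


class TestCountMatrix:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            _matrix({"s1": [-1]}, ["c1"])

    def test_rejects_fractional_counts(self):
        with pytest.raises(ValueError, match="integer"):
            CountMatrix(pd.DataFrame({"s1": [1.5]}, index=["c1"]))

    def test_rejects_duplicate_ids(self):
        frame = pd.DataFrame([[1], [2]], index=["c1", "c1"], columns=["s1"])
        with pytest.raises(ValueError, match="duplicate candidate"):
            CountMatrix(frame)

    def test_unknown_candidate_row_lookup(self, toy_matrix):
        with pytest.raises(KeyError):
            toy_matrix.row("nope")


class TestMergeReplicateRuns:
    def test_two_runs_sum(self):
        counts = _matrix({"L_r1": [5], "L_r2": [7]}, ["c1"])
        meta = [
            SampleMeta("L_r1", "L", "s", "plasma"),
            SampleMeta("L_r2", "L", "s", "plasma"),
        ]
        merged, lib_meta = merge_replicate_runs(counts, meta)
        assert merged.to_frame().loc["c1", "L"] == 12
        assert [m.sample_id for m in lib_meta] == ["L"]

    def test_incomplete_libraries_dropped(self, rng):
        """192 libraries where 2 have a single run -> 190 merged columns."""
        data, meta = {}, []
        for j in range(192):
            lib = f"lib{j:03d}"
            n_runs = 1 if j < 2 else 2
            for r in range(n_runs):
                sid = f"{lib}_r{r}"
                data[sid] = [int(rng.integers(0, 10))]
                meta.append(SampleMeta(sid, lib, "s", "plasma"))
        merged, lib_meta = merge_replicate_runs(_matrix(data, ["c1"]), meta)
        assert len(merged.samples) == 190
        assert len(lib_meta) == 190

    def test_single_run_identity_when_drop_disabled(self):
        counts = _matrix({"a": [3], "b": [4]}, ["c1"])
        meta = [SampleMeta("a", "a", "s", "plasma"), SampleMeta("b", "b", "s", "plasma")]
        merged, _ = merge_replicate_runs(counts, meta, drop_incomplete=False)
        assert merged.to_frame().rename(columns=str).equals(counts.to_frame())

    def test_conserves_reads_over_retained_libraries(self, rng):
        n_cand, n_lib = 5, 8
        data, meta = {}, []
        for j in range(n_lib):
            lib = f"lib{j}"
            for r in range(2):
                sid = f"{lib}_r{r}"
                data[sid] = list(rng.integers(0, 50, size=n_cand))
                meta.append(SampleMeta(sid, lib, "s", "plasma"))
        counts = _matrix(data, [f"c{i}" for i in range(n_cand)])
        merged, _ = merge_replicate_runs(counts, meta)
        assert merged.total() == counts.total()

    def test_sample_without_metadata_errors(self):
        counts = _matrix({"a": [1]}, ["c1"])
        with pytest.raises(ValueError, match="without metadata"):
            merge_replicate_runs(counts, [])

    def test_metadata_for_unknown_sample_errors(self):
        counts = _matrix({"a": [1]}, ["c1"])
        meta = [
            SampleMeta("a", "a", "s", "plasma"),
            SampleMeta("ghost", "g", "s", "plasma"),
        ]
        with pytest.raises(ValueError, match="unknown samples"):
            merge_replicate_runs(counts, meta)


class TestRpmArithmetic:
    def test_cutoff_translation_is_linear(self):
        cfg = ScreenConfig(rpm_cutoff=64, mapping_fraction=0.5)
        assert reads_for_rpm_cutoff(cfg) == pytest.approx(400.0)

    def test_zero_cutoff(self):
        assert reads_for_rpm_cutoff(ScreenConfig(rpm_cutoff=0)) == 0

    def test_estimate_rpm_zero(self, screen_cfg):
        assert estimate_rpm(0, screen_cfg) == 0

    def test_estimate_rpm_rejects_negative(self, screen_cfg):
        with pytest.raises(ValueError):
            estimate_rpm(-1, screen_cfg)

    @given(
        rpm=st.floats(0.001, 1e4),
        reads=st.floats(1e5, 1e8),
        frac=st.floats(0.01, 1.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_roundtrip_cutoff_and_estimate(self, rpm, reads, frac):
        """estimate_rpm inverts reads_for_rpm_cutoff for any positive config."""
        cfg = ScreenConfig(
            rpm_cutoff=rpm, mean_reads_per_sample=reads, mapping_fraction=frac
        )
        assert estimate_rpm(reads_for_rpm_cutoff(cfg), cfg) == pytest.approx(rpm)


class TestSummarize:
    def test_hand_checkable_row(self, toy_matrix, screen_cfg):
        s = summarize_candidate(toy_matrix, "candA", screen_cfg)
        assert s.n_samples_at_min_reads == 2
        assert s.mean_counts == 2.5
        assert s.median_counts == 2.5  # even count: mean of central values
        assert s.max_counts == 4

    def test_all_zero_candidate(self, toy_matrix, screen_cfg):
        s = summarize_candidate(toy_matrix, "candZero", screen_cfg)
        assert (s.n_samples_at_min_reads, s.mean_counts, s.median_counts, s.max_counts) == (0, 0, 0, 0)

    def test_unknown_candidate_errors(self, toy_matrix, screen_cfg):
        with pytest.raises(KeyError):
            summarize_candidate(toy_matrix, "nope", screen_cfg)

    def test_avg_rpm_uses_per_sample_totals(self, screen_cfg):
        counts = _matrix({"a": [10], "b": [30]}, ["c1"])
        meta = [
            SampleMeta("a", "a", "s", "plasma", total_reads=1_000_000),
            SampleMeta("b", "b", "s", "plasma", total_reads=3_000_000),
        ]
        s = summarize_candidate(counts, "c1", screen_cfg, meta)
        assert s.avg_rpm == pytest.approx(10.0)  # mean of 10 rpm and 10 rpm

    def test_agrees_with_brute_force_on_random_matrices(self, rng, screen_cfg):
        """Sort-based median / linear-scan max recomputation, random shapes."""
        for _ in range(10):
            n_cand = int(rng.integers(1, 50))
            n_samp = int(rng.integers(1, 200))
            frame = pd.DataFrame(
                rng.integers(0, 100, size=(n_cand, n_samp)),
                index=[f"c{i}" for i in range(n_cand)],
                columns=[f"s{j}" for j in range(n_samp)],
            )
            matrix = CountMatrix(frame)
            cand = f"c{int(rng.integers(n_cand))}"
            vals = sorted(frame.loc[cand])
            mid = len(vals) // 2
            median = vals[mid] if len(vals) % 2 else (vals[mid - 1] + vals[mid]) / 2
            mx = 0
            for v in vals:
                if v > mx:
                    mx = v
            s = summarize_candidate(matrix, cand, screen_cfg)
            assert s.median_counts == median
            assert s.max_counts == mx
            assert s.mean_counts == pytest.approx(sum(vals) / len(vals))
            assert s.n_samples_at_min_reads == sum(v >= 3 for v in vals)


class TestInclusionScreen:
    def test_ceiling_thresholds(self, screen_cfg):
        assert min_samples_required(screen_cfg, 10) == 1
        assert min_samples_required(screen_cfg, 23) == 3  # ceil(2.3)
        assert min_samples_required(screen_cfg, 190) == 19

    def test_boundary_single_sample_included(self, screen_cfg):
        data = {f"s{j}": [3 if j == 0 else 0] for j in range(10)}
        counts = _matrix(data, ["c1"])
        assert inclusion_screen(counts, screen_cfg, {"c1"}) == ["c1"]

    def test_unannotated_candidate_excluded(self, screen_cfg):
        data = {f"s{j}": [5, 5] for j in range(10)}
        counts = _matrix(data, ["known", "orphan"])
        assert inclusion_screen(counts, screen_cfg, {"known"}) == ["known"]

    def test_empty_annotation_gives_empty_result(self, toy_matrix, screen_cfg):
        assert inclusion_screen(toy_matrix, screen_cfg, set()) == []

    def test_ordering(self, screen_cfg):
        # candHigh hits threshold in more samples; tie broken by mean, then id
        data = {
            "s1": [3, 3, 3],
            "s2": [3, 3, 3],
            "s3": [3, 0, 0],
            "s4": [9, 0, 0],
        }
        counts = _matrix(data, ["candHigh", "b_tie", "a_tie"])
        got = inclusion_screen(counts, screen_cfg, set(counts.candidates))
        assert got == ["candHigh", "a_tie", "b_tie"]

    def test_monotone_in_thresholds(self, rng):
        """Relaxing min_reads or the sample fraction never drops a candidate."""
        frame = pd.DataFrame(
            rng.integers(0, 6, size=(20, 30)),
            index=[f"c{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(30)],
        )
        counts = CountMatrix(frame)
        annotated = set(counts.candidates)
        base = set(inclusion_screen(counts, ScreenConfig(min_reads=3, min_sample_fraction=0.2), annotated))
        lower_reads = set(inclusion_screen(counts, ScreenConfig(min_reads=2, min_sample_fraction=0.2), annotated))
        lower_frac = set(inclusion_screen(counts, ScreenConfig(min_reads=3, min_sample_fraction=0.1), annotated))
        assert base <= lower_reads
        assert base <= lower_frac


class TestBackgroundScreen:
    def test_strict_inequality_at_cutoff(self, screen_cfg):
        data = {f"s{j}": [199, 200, 201] for j in range(4)}
        counts = _matrix(data, ["below", "at", "above"])
        summaries = summarize_all(counts, screen_cfg)
        assert background_screen(summaries, screen_cfg) == ["above"]

    def test_all_zero_medians_empty(self, toy_matrix, screen_cfg):
        summaries = summarize_all(toy_matrix, screen_cfg)
        assert background_screen(summaries, screen_cfg) == []

    def test_subset_of_inclusion_with_universal_annotation(self, rng, screen_cfg):
        frame = pd.DataFrame(
            rng.poisson(5, size=(10, 40)) * rng.integers(0, 80, size=(10, 1)),
            index=[f"c{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(40)],
        )
        counts = CountMatrix(frame)
        included = set(inclusion_screen(counts, screen_cfg, set(counts.candidates)))
        above = set(background_screen(summarize_all(counts, screen_cfg), screen_cfg))
        assert above <= included


class TestSubsetBySampleType:
    def test_plasma_subset(self, toy_matrix, toy_meta):
        sub = subset_by_sample_type(toy_matrix, toy_meta, "plasma")
        assert sub.samples == ["s1", "s2"]
        assert sub.candidates == toy_matrix.candidates  # all-zero rows kept

    def test_missing_type_errors(self, toy_matrix, toy_meta):
        with pytest.raises(ValueError, match="no samples"):
            subset_by_sample_type(toy_matrix, toy_meta, "other")

    def test_union_of_subsets_is_identity(self, toy_matrix, toy_meta):
        plasma = subset_by_sample_type(toy_matrix, toy_meta, "plasma")
        cell = subset_by_sample_type(toy_matrix, toy_meta, "cell")
        rejoined = pd.concat([plasma.to_frame(), cell.to_frame()], axis=1)
        assert rejoined[toy_matrix.samples].equals(toy_matrix.to_frame())


class TestSampleAudit:
    def test_counts_libraries_not_runs(self):
        meta = [
            SampleMeta("a_r1", "a", "s", "plasma"),
            SampleMeta("a_r2", "a", "s", "plasma"),
            SampleMeta("b_r1", "b", "s", "cell"),
        ]
        assert count_samples_by_type(meta) == {"plasma": 1, "cell": 1, "other": 0}

    def test_conflicting_type_for_library_errors(self):
        meta = [
            SampleMeta("a_r1", "a", "s", "plasma"),
            SampleMeta("a_r2", "a", "s", "cell"),
        ]
        with pytest.raises(ValueError, match="conflicting"):
            count_samples_by_type(meta)
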