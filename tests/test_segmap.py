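"""Segment inference, SNPLDB map construction and map statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csslkit import (
    build_snpldb_map,
    compare_maps,
    compute_map_stats,
    infer_line_segments,
    qc_filter_snps,
    segment_length_bp,
)
from csslkit.containers import DONOR, MISSING, RECURRENT, Segment
from csslkit.segmap import _absorb_short_runs, _majority_smooth, _runs

from conftest import make_map, make_matrix


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestQCFilter:
    def test_qual_boundary_is_strict(self):
        m = make_matrix(np.zeros((4, 3)))
        m.sites.loc[0, "qual"] = 29.9
        m.sites.loc[1, "qual"] = 30.0
        out = qc_filter_snps(m)
        assert list(out.sites["pos"]) == list(m.sites["pos"][1:])

    def test_missing_fraction_boundary(self):
        calls = np.zeros((100, 2), dtype=np.int8)
        calls[:21, 0] = MISSING  # 21% missing -> removed
        calls[:20, 1] = MISSING  # 20% missing -> retained
        out = qc_filter_snps(make_matrix(calls))
        assert out.n_sites == 1
        assert out.sites.loc[0, "pos"] == 20_000

    def test_mean_depth_threshold(self):
        m = make_matrix(np.zeros((4, 2)))
        m.sites.loc[0, "mean_dp"] = 1.49
        out = qc_filter_snps(m)
        assert out.n_sites == 1

    def test_all_pass_is_identity(self):
        m = make_matrix(np.zeros((4, 5)))
        out = qc_filter_snps(m)
        assert np.array_equal(out.calls, m.calls)
        assert out.sites.equals(m.sites)

    def test_empty_matrix_rejected(self):
        m = make_matrix(np.zeros((2, 1)))
        with pytest.raises(ValueError):
            qc_filter_snps(m.subset_sites(np.array([False])))


# ---------------------------------------------------------------------------
# breakpoint inference
# ---------------------------------------------------------------------------

def _infer_single(codes, window=15, min_sites=5, positions=None, chrom_length=None):
    m = make_matrix(np.asarray(codes, dtype=np.int8)[None, :], positions=positions,
                    chrom_length=chrom_length)
    return infer_line_segments(m, "L01", window=window, min_sites=min_sites)


class TestInferSegments:
    def test_clean_changepoint(self):
        codes = [0] * 50 + [2] * 50
        positions = np.arange(1, 101) * 10_000
        segs, bps = _infer_single(codes, positions=positions, chrom_length=1_000_000)
        assert [s.origin for s in segs] == ["recurrent", "donor"]
        mid = (50 * 10_000 + 51 * 10_000) // 2
        assert bps == [("Gm01", mid)]
        assert segs[0].start == 1 and segs[1].end == 1_000_000
        assert segs[0].end == mid and segs[1].start == mid + 1

    def test_isolated_noise_absorbed(self):
        codes = [0] * 50
        codes[24] = 2
        segs, bps = _infer_single(codes)
        assert len(segs) == 1 and segs[0].origin == "recurrent"
        assert bps == []

    def test_short_run_absorption_depends_on_min_sites(self):
        codes = [0] * 20 + [2] * 3 + [0] * 20
        segs5, _ = _infer_single(codes, window=1, min_sites=5)
        assert len(segs5) == 1 and segs5[0].origin == "recurrent"
        segs2, _ = _infer_single(codes, window=1, min_sites=2)
        assert [s.origin for s in segs2] == ["recurrent", "donor", "recurrent"]

    def test_all_missing_chromosome_reports_nocall(self):
        m = make_matrix(np.full((1, 10), MISSING, dtype=np.int8))
        segs, bps = infer_line_segments(m, "L01")
        assert len(segs) == 1 and segs[0].origin == "nocall"

    def test_agrees_with_naive_rule_oracle(self):
        """Random <=30-site vectors: fast implementation equals a from-scratch
        list-based application of the smoothing and absorption rules."""
        rng = np.random.default_rng(123)
        for _ in range(300):
            n = int(rng.integers(5, 31))
            codes = rng.choice([0, 2], size=n, p=[0.7, 0.3]).astype(np.int8)
            window = int(rng.choice([1, 3, 5, 7]))
            min_sites = int(rng.integers(1, 5))
            segs, _ = _infer_single(codes, window=window, min_sites=min_sites)
            got = [(s.origin, s.n_sites) for s in segs]
            assert got == _oracle_runs(list(codes), window, min_sites)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    codes=st.lists(st.sampled_from([0, 1, 2]), min_size=2, max_size=30),
    window=st.sampled_from([1, 3, 5]),
    min_sites=st.integers(1, 4),
)
def test_inference_properties(codes, window, min_sites):
    """Segments tile the chromosome, alternate in origin, and match the
    rule oracle for arbitrary genotype vectors."""
    segs, bps = _infer_single(codes, window=window, min_sites=min_sites)
    assert segs[0].start == 1
    for a, b in zip(segs, segs[1:]):
        assert b.start == a.end + 1
        assert a.origin != b.origin
    assert len(bps) == len(segs) - 1
    got = [(s.origin, s.n_sites) for s in segs]
    assert got == _oracle_runs(list(codes), window, min_sites)


def _oracle_runs(codes, window, min_sites):
    """Independent re-statement of the smoothing/absorption rules on lists."""
    # centred majority vote, truncated windows, ties keep the original code
    half = window // 2
    smoothed = []
    for i in range(len(codes)):
        win = codes[max(0, i - half):i + half + 1]
        counts = {c: win.count(c) for c in set(win)}
        best = max(counts.values())
        winners = [c for c, k in counts.items() if k == best]
        smoothed.append(winners[0] if len(winners) == 1 else codes[i])
    # collapse to runs
    runs = []
    for c in smoothed:
        if runs and runs[-1][0] == c:
            runs[-1][1] += 1
        else:
            runs.append([c, 1])
    # absorb short runs, smallest first (ties to the left); flank with more
    # sites wins (tie left); fuse equal neighbours; single run always kept
    while len(runs) > 1:
        sizes = [n for _, n in runs]
        short = [i for i, n in enumerate(sizes) if n < min_sites]
        if not short:
            break
        i = min(short, key=lambda k: (sizes[k], k))
        if i == 0:
            j = 1
        elif i == len(runs) - 1:
            j = i - 1
        else:
            j = i - 1 if sizes[i - 1] >= sizes[i + 1] else i + 1
        runs[j][1] += runs[i][1]
        runs[j][0] = runs[j][0]
        del runs[i]
        merged = []
        for c, n in runs:
            if merged and merged[-1][0] == c:
                merged[-1][1] += n
            else:
                merged.append([c, n])
        runs = merged
    origin = {0: "recurrent", 1: "het", 2: "donor"}
    return [(origin[c], n) for c, n in runs]


# ---------------------------------------------------------------------------
# SNPLDB map
# ---------------------------------------------------------------------------

def _segments_of(matrix, **kw):
    by_line = {}
    for line in matrix.lines:
        segs, _ = infer_line_segments(matrix, line, **kw)
        by_line[line] = segs
    return by_line


class TestBuildMap:
    def test_no_breakpoints_one_marker_per_chromosome(self):
        by_line = {
            "A": [Segment("A", "c1", 1, 300, "recurrent"),
                  Segment("A", "c2", 1, 200, "recurrent")],
            "B": [Segment("B", "c1", 1, 300, "donor"),
                  Segment("B", "c2", 1, 200, "recurrent")],
        }
        pmap = build_snpldb_map(by_line, {"c1": 300, "c2": 200})
        assert len(pmap.markers) == 2
        assert [m.id for m in pmap.markers] == ["c1_LDB_1", "c2_LDB_1"]

    def test_distinct_breakpoints_partition_into_three(self):
        by_line = {
            "A": [Segment("A", "c1", 1, 100, "donor"),
                  Segment("A", "c1", 101, 300, "recurrent")],
            "B": [Segment("B", "c1", 1, 200, "recurrent"),
                  Segment("B", "c1", 201, 300, "donor")],
        }
        pmap = build_snpldb_map(by_line, {"c1": 300})
        assert [(m.start, m.end) for m in pmap.markers] == [(1, 100), (101, 200),
                                                            (201, 300)]
        codes = pmap.code_frame()
        assert list(codes.loc["A"]) == [DONOR, RECURRENT, RECURRENT]
        assert list(codes.loc["B"]) == [RECURRENT, RECURRENT, DONOR]

    def test_cosegregating_blocks_merge(self):
        # both lines break at 100 only -> blocks [1,100],[101,300] stay;
        # a boundary no line distinguishes is never created
        by_line = {
            "A": [Segment("A", "c1", 1, 100, "donor"),
                  Segment("A", "c1", 101, 300, "recurrent")],
            "B": [Segment("B", "c1", 1, 100, "recurrent"),
                  Segment("B", "c1", 101, 300, "donor")],
        }
        pmap = build_snpldb_map(by_line, {"c1": 300})
        assert len(pmap.markers) == 2

    def test_double_crossover_breaks_coarse_interval(self):
        """A donor island inside one line splits the block structure in three."""
        by_line = {
            "A": [Segment("A", "c1", 1, 120, "recurrent"),
                  Segment("A", "c1", 121, 180, "donor"),
                  Segment("A", "c1", 181, 300, "recurrent")],
            "B": [Segment("B", "c1", 1, 300, "recurrent")],
        }
        pmap = build_snpldb_map(by_line, {"c1": 300})
        assert len(pmap.markers) == 3
        assert list(pmap.code_frame().loc["A"]) == [RECURRENT, DONOR, RECURRENT]

    def test_tiling_and_naming(self, small_population):
        matrix, _ = small_population
        pmap = build_snpldb_map(_segments_of(matrix, window=1, min_sites=1),
                                matrix.chrom_lengths)
        for chrom, length in matrix.chrom_lengths.items():
            on = [m for m in pmap.markers if m.chrom == chrom]
            assert on[0].start == 1 and on[-1].end == length
            for a, b in zip(on, on[1:]):
                assert b.start == a.end + 1
            assert [m.id for m in on] == [f"{chrom}_LDB_{k + 1}"
                                          for k in range(len(on))]

    def test_inconsistent_chromosomes_rejected(self):
        by_line = {"A": [Segment("A", "cX", 1, 10, "donor")]}
        with pytest.raises(ValueError):
            build_snpldb_map(by_line, {"c1": 300})


class TestRoundTrip:
    def test_noiseless_inference_equals_truth(self, small_population):
        """Without observation noise the inferred segment map is the true one."""
        matrix, truth = small_population
        expected = {(s.line, s.chrom, s.start, s.end, s.origin)
                    for s in truth.segments}
        got = set()
        for line in matrix.lines:
            segs, _ = infer_line_segments(matrix, line, window=1, min_sites=1)
            got |= {(s.line, s.chrom, s.start, s.end, s.origin) for s in segs}
        assert got == expected


# ---------------------------------------------------------------------------
# map statistics
# ---------------------------------------------------------------------------

class TestMapStats:
    def test_interval_length_convention(self):
        assert segment_length_bp(45_288_662, 45_566_206) == 277_544  # 277.5 kb
        assert segment_length_bp(52_865_890, 53_515_092) == 649_202  # 0.65 Mb

    def test_all_recurrent_line(self):
        codes = np.array([[RECURRENT, RECURRENT], [DONOR, RECURRENT]])
        pmap = make_map(codes, bounds=[100, 300])
        stats = compute_map_stats(pmap)
        row = stats.per_line.set_index("line").loc["L01"]
        assert row["recovery_pct"] == 100.0
        assert row["n_donor_segments"] == 0

    def test_percentages_tile_to_100(self, small_population):
        matrix, _ = small_population
        pmap = build_snpldb_map(_segments_of(matrix, window=1, min_sites=1),
                                matrix.chrom_lengths)
        stats = compute_map_stats(pmap)
        total = (stats.per_line[["recovery_pct", "donor_pct", "het_pct",
                                 "nocall_pct"]].sum(axis=1))
        assert np.allclose(total, 100.0)

    def test_donor_segment_count_runs(self):
        codes = np.array([[DONOR, RECURRENT, DONOR, DONOR]])
        pmap = make_map(codes, bounds=[100, 200, 300, 400])
        stats = compute_map_stats(pmap)
        assert stats.per_line.loc[0, "n_donor_segments"] == 2

    def test_coverage_counts_any_carrier(self):
        codes = np.array([[DONOR, RECURRENT], [RECURRENT, RECURRENT]])
        pmap = make_map(codes, bounds=[100, 400])
        stats = compute_map_stats(pmap)
        assert stats.per_chrom.loc[0, "coverage_pct"] == pytest.approx(25.0)


# ---------------------------------------------------------------------------
# map comparison
# ---------------------------------------------------------------------------

class TestCompareMaps:
    def test_identical_maps(self):
        codes = np.array([[DONOR, RECURRENT], [RECURRENT, DONOR]])
        pmap = make_map(codes, bounds=[100, 300])
        rep = compare_maps(pmap, pmap)
        assert rep["new_segments"].sum() == 0
        assert rep["broken_sites"].sum() == 0

    def test_broken_coarse_segment_counts_extra_pieces(self):
        """One coarse donor segment overlapping three fine pieces -> 2 broken sites."""
        coarse = make_map(np.array([[DONOR]]), bounds=[600])
        fine = make_map(
            np.array([[DONOR, RECURRENT, DONOR, RECURRENT, DONOR, RECURRENT]]),
            bounds=[100, 200, 300, 400, 500, 600])
        rep = compare_maps(coarse, fine)
        assert rep.loc[0, "broken_sites"] == 2
        assert rep.loc[0, "new_segments"] == 0

    def test_fine_only_segment_is_new(self):
        coarse = make_map(np.array([[RECURRENT, RECURRENT]]), bounds=[300, 600])
        fine = make_map(np.array([[RECURRENT, DONOR]]), bounds=[300, 600])
        rep = compare_maps(coarse, fine)
        assert rep.loc[0, "new_segments"] == 1

    def test_misjudged_fraction(self):
        coarse = make_map(np.array([[DONOR, DONOR]]), bounds=[100, 200])
        fine = make_map(np.array([[DONOR, RECURRENT]]), bounds=[100, 200])
        rep = compare_maps(coarse, fine)
        assert rep.loc[0, "misjudged_pct"] == pytest.approx(50.0)

    def test_line_set_mismatch_rejected(self):
        a = make_map(np.array([[DONOR]]), bounds=[100], lines=["A"])
        b = make_map(np.array([[DONOR]]), bounds=[100], lines=["B"])
        with pytest.raises(ValueError):
            compare_maps(a, b)
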