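"""Donor-segment inference and SNPLDB physical-map construction.

From a QC-filtered genotype matrix this module reconstructs, per line, the
mosaic of recurrent/donor/heterozygous chromosome segments, takes the union
of all lines' recombination breakpoints to partition each chromosome into
co-segregating SNP blocks (SNPLDB markers), and computes the physical-map
summary statistics used to describe a CSSL panel (recurrent-genome recovery,
segment counts and lengths, donor coverage) plus a coarse-vs-fine map
comparison.

Coordinates are 1-based inclusive throughout; a segment's reported length is
``end - start`` in bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    CODE_OF_ORIGIN,
    DONOR,
    HET,
    MISSING,
    ORIGIN_OF_CODE,
    RECURRENT,
    GenotypeMatrix,
    Segment,
)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter_snps(
    matrix: GenotypeMatrix,
    min_qual: float = 30.0,
    max_missing: float = 0.2,
    min_mean_dp: float = 1.5,
) -> GenotypeMatrix:
    """Retain sites with QUAL >= min_qual, missing fraction <= max_missing and
    mean depth >= min_mean_dp; site order is preserved."""
    if matrix.n_sites == 0:
        raise ValueError("empty genotype matrix")
    keep = (
        (matrix.sites["qual"].to_numpy() >= min_qual)
        & (matrix.missing_fraction() <= max_missing)
        & (matrix.sites["mean_dp"].to_numpy() >= min_mean_dp)
    )
    return matrix.subset_sites(keep)


# ---------------------------------------------------------------------------
# per-line breakpoint inference
# ---------------------------------------------------------------------------

def _majority_smooth(codes: np.ndarray, window: int) -> np.ndarray:
    """Majority vote in a centred window of ``window`` non-missing sites.

    Ties leave the site's own code unchanged.  Windows are truncated at the
    chromosome ends.
    """
    n = len(codes)
    if window <= 1 or n == 0:
        return codes.copy()
    half = window // 2
    out = codes.copy()
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        win = codes[lo:hi]
        counts = np.bincount(win, minlength=3)
        best = counts.max()
        winners = np.flatnonzero(counts == best)
        if len(winners) == 1:
            out[i] = winners[0]
        # tie -> keep the original code
    return out


def _runs(codes: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (state, first_index, last_index)."""
    if len(codes) == 0:
        return []
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [len(codes) - 1]))
    return [(int(codes[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def _absorb_short_runs(
    runs: list[tuple[int, int, int]], min_sites: int
) -> list[tuple[int, int, int]]:
    """Absorb runs supported by < min_sites sites into the better flanking run.

    The shortest run is absorbed first (index ties to the left); the flank
    with more supporting sites wins, ties going left.  Equal-state neighbours
    are fused after each absorption and the process iterates to a fixed point.
    A chromosome consisting of a single run is kept regardless of support.
    """
    runs = list(runs)
    while len(runs) > 1:
        sizes = [e - s + 1 for _, s, e in runs]
        short = [i for i, n in enumerate(sizes) if n < min_sites]
        if not short:
            break
        i = min(short, key=lambda k: (sizes[k], k))
        if i == 0:
            target = 1
        elif i == len(runs) - 1:
            target = i - 1
        else:
            left_n = sizes[i - 1]
            right_n = sizes[i + 1]
            target = i - 1 if left_n >= right_n else i + 1
        state = runs[target][0]
        s = min(runs[i][1], runs[target][1])
        e = max(runs[i][2], runs[target][2])
        lo, hi = min(i, target), max(i, target)
        runs[lo:hi + 1] = [(state, s, e)]
        # fuse equal-state neighbours
        fused: list[tuple[int, int, int]] = []
        for r in runs:
            if fused and fused[-1][0] == r[0]:
                fused[-1] = (r[0], fused[-1][1], r[2])
            else:
                fused.append(r)
        runs = fused
    return runs


def infer_line_segments(
    matrix: GenotypeMatrix,
    line: str,
    window: int = 15,
    min_sites: int = 5,
) -> tuple[list[Segment], list[tuple[str, int]]]:
    """Infer one line's chromosome segments and recombination breakpoints.

    Per chromosome the non-missing calls are smoothed by sliding-window
    majority vote, collapsed into runs, and short runs are absorbed into
    their flanks.  Breakpoints fall at the floor midpoint between the last
    site of one run and the first site of the next; terminal segments extend
    to the chromosome ends.  An all-missing chromosome yields a single
    ``nocall`` segment rather than an error.

    Returns ``(segments, breakpoints)`` with breakpoints as (chrom, coordinate).
    """
    li = matrix.line_index(line)
    segments: list[Segment] = []
    breakpoints: list[tuple[str, int]] = []
    chrom_lengths = _chrom_spans(matrix)
    for chrom in matrix.chromosomes:
        pos, block = matrix.chrom_slice(chrom)
        calls = block[li]
        keep = calls != MISSING
        if not keep.any():
            segments.append(
                Segment(line=line, chrom=chrom, start=1,
                        end=int(chrom_lengths[chrom]), origin="nocall", n_sites=0)
            )
            continue
        p = pos[keep]
        c = calls[keep].astype(np.int64)
        smoothed = _majority_smooth(c, window)
        runs = _absorb_short_runs(_runs(smoothed), min_sites)
        for k, (state, si, ei) in enumerate(runs):
            start = 1 if k == 0 else (int(p[runs[k - 1][2]]) + int(p[si])) // 2 + 1
            end = (
                int(chrom_lengths[chrom])
                if k == len(runs) - 1
                else (int(p[ei]) + int(p[runs[k + 1][1]])) // 2
            )
            segments.append(
                Segment(line=line, chrom=chrom, start=start, end=end,
                        origin=ORIGIN_OF_CODE[state], n_sites=ei - si + 1)
            )
            if k > 0:
                breakpoints.append((chrom, start - 1))
    return segments, breakpoints


def _chrom_spans(matrix: GenotypeMatrix) -> dict[str, int]:
    """Chromosome lengths attached to the matrix, else the last site position."""
    lengths = getattr(matrix, "chrom_lengths", None)
    if lengths:
        return dict(lengths)
    return {c: int(matrix.sites.loc[matrix.sites["chrom"] == c, "pos"].max())
            for c in matrix.chromosomes}


# ---------------------------------------------------------------------------
# SNPLDB map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNPLDBMarker:
    """One co-segregation block used as a single multi-SNP marker."""

    id: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PhysicalMap:
    """Lines x SNPLDB markers consensus-code matrix."""

    markers: list[SNPLDBMarker]
    lines: list[str]
    codes: np.ndarray  # int8 (n_lines, n_markers)
    chrom_lengths: dict[str, int]

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.id, m.chrom, m.start, m.end) for m in self.markers],
            columns=["id", "chrom", "start", "end"],
        )

    def code_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.lines,
                            columns=[m.id for m in self.markers])

    def markers_on(self, chrom: str) -> list[int]:
        return [i for i, m in enumerate(self.markers) if m.chrom == chrom]

    def donor_segments(self, origin_code: int = DONOR) -> list[Segment]:
        """Per-line maximal runs of a given code, as genomic segments."""
        segs: list[Segment] = []
        by_chrom: dict[str, list[int]] = {}
        for i, m in enumerate(self.markers):
            by_chrom.setdefault(m.chrom, []).append(i)
        for li, line in enumerate(self.lines):
            for chrom, idx in by_chrom.items():
                run_start = None
                prev = None
                for j in idx:
                    if self.codes[li, j] == origin_code:
                        if run_start is None:
                            run_start = self.markers[j].start
                        prev = self.markers[j].end
                    elif run_start is not None:
                        segs.append(Segment(line=line, chrom=chrom, start=run_start,
                                            end=prev, origin=ORIGIN_OF_CODE[origin_code]))
                        run_start = None
                if run_start is not None:
                    segs.append(Segment(line=line, chrom=chrom, start=run_start,
                                        end=prev, origin=ORIGIN_OF_CODE[origin_code]))
        return segs


def build_snpldb_map(
    segments_by_line: dict[str, list[Segment]],
    chrom_lengths: dict[str, int],
    marker_prefix: str | None = None,
    external_blocks: list[tuple[str, int, int]] | None = None,
) -> PhysicalMap:
    """Partition each chromosome by the union of all lines' breakpoints.

    Adjacent blocks whose per-line code vectors agree across every line are
    merged (they co-segregate within the population), and each resulting
    block becomes one SNPLDB marker named ``<chrom>_LDB_<k>`` with ``k``
    1-based along the chromosome.  ``external_blocks`` may supply additional
    block boundaries (e.g. from an external germplasm panel) as
    (chrom, start, end) intervals whose edges are added to the partition.
    """
    lines = sorted(segments_by_line)
    if not lines:
        raise ValueError("no lines supplied")
    chrom_sets = {line: {s.chrom for s in segs} for line, segs in segments_by_line.items()}
    all_chroms = set(chrom_lengths)
    for line, cs in chrom_sets.items():
        if not cs <= all_chroms:
            raise ValueError(f"line {line} has segments on unknown chromosomes {cs - all_chroms}")

    # per-line, per-chromosome interval lookup
    per_line: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for line in lines:
        d: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in chrom_lengths:
            segs = sorted(
                (s for s in segments_by_line[line] if s.chrom == chrom),
                key=lambda s: s.start,
            )
            if segs:
                ends = np.array([s.end for s in segs], dtype=np.int64)
                codes = np.array([CODE_OF_ORIGIN[s.origin] for s in segs], dtype=np.int8)
            else:
                ends = np.array([chrom_lengths[chrom]], dtype=np.int64)
                codes = np.array([MISSING], dtype=np.int8)
            d[chrom] = (ends, codes)
        per_line[line] = d

    markers: list[SNPLDBMarker] = []
    code_cols: list[np.ndarray] = []
    for chrom, length in chrom_lengths.items():
        cuts = set()
        for line in lines:
            ends, _ = per_line[line][chrom]
            cuts.update(int(e) for e in ends[:-1])
        if external_blocks:
            for bc, bs, be in external_blocks:
                if bc == chrom:
                    if bs > 1:
                        cuts.add(int(bs) - 1)
                    if be < length:
                        cuts.add(int(be))
        bounds = np.array(sorted(cuts) + [length], dtype=np.int64)
        starts = np.concatenate(([1], bounds[:-1] + 1))
        # per-line code of each block: the segment covering its start
        block_codes = np.empty((len(lines), len(bounds)), dtype=np.int8)
        for li, line in enumerate(lines):
            ends, codes = per_line[line][chrom]
            block_codes[li] = codes[np.searchsorted(ends, starts)]
        # merge adjacent blocks with identical per-line vectors
        keep = [0]
        for j in range(1, len(bounds)):
            if not np.array_equal(block_codes[:, j], block_codes[:, keep[-1]]):
                keep.append(j)
        merged_starts = starts[keep]
        merged_ends = np.concatenate((merged_starts[1:] - 1, [length]))
        prefix = marker_prefix or chrom
        for k, (s, e) in enumerate(zip(merged_starts, merged_ends), start=1):
            markers.append(SNPLDBMarker(id=f"{prefix}_LDB_{k}", chrom=chrom,
                                        start=int(s), end=int(e)))
            code_cols.append(block_codes[:, keep[k - 1]])

    codes = np.column_stack(code_cols) if code_cols else np.empty((len(lines), 0), dtype=np.int8)
    return PhysicalMap(markers=markers, lines=lines, codes=codes,
                       chrom_lengths=dict(chrom_lengths))


# ---------------------------------------------------------------------------
# map statistics
# ---------------------------------------------------------------------------

@dataclass
class MapStats:
    """Physical-map summaries: per-line recovery and segment counts, lengths,
    per-chromosome marker counts and donor coverage."""

    per_line: pd.DataFrame
    per_chrom: pd.DataFrame
    donor_segment_lengths: np.ndarray

    @property
    def mean_recovery(self) -> float:
        return float(self.per_line["recovery_pct"].mean())

    @property
    def mean_segments_per_line(self) -> float:
        return float(self.per_line["n_donor_segments"].mean())

    @property
    def mean_donor_segment_length(self) -> float:
        if len(self.donor_segment_lengths) == 0:
            return 0.0
        return float(self.donor_segment_lengths.mean())

    @property
    def total_donor_segments(self) -> int:
        return int(self.per_line["n_donor_segments"].sum())


def segment_length_bp(start: int, end: int) -> int:
    """Reported interval length: end - start (bp)."""
    return end - start


def compute_map_stats(pmap: PhysicalMap) -> MapStats:
    """Recovery %, donor-segment counts/lengths and donor coverage per chromosome.

    Recovery counts recurrent-code marker length over the genome length;
    heterozygous and no-call marker lengths are tracked separately so the four
    percentages tile to 100.  Donor-segment statistics use donor-homozygous
    runs only.
    """
    genome_length = sum(pmap.chrom_lengths.values())
    if genome_length <= 0:
        raise ValueError("zero-length genome")
    lengths = np.array([m.length for m in pmap.markers], dtype=float)
    # tiling convention: marker lengths end-start sum short of chromosome ends;
    # use end - start + 1 for percentage tiling so shares add to exactly 100
    tile = np.array([m.end - m.start + 1 for m in pmap.markers], dtype=float)

    rows = []
    donor_lengths: list[float] = []
    donor_segs = pmap.donor_segments()
    seg_count = {line: 0 for line in pmap.lines}
    for s in donor_segs:
        seg_count[s.line] += 1
        donor_lengths.append(float(segment_length_bp(s.start, s.end)))
    for li, line in enumerate(pmap.lines):
        codes = pmap.codes[li]
        rec = tile[codes == RECURRENT].sum() / genome_length * 100
        don = tile[codes == DONOR].sum() / genome_length * 100
        het = tile[codes == HET].sum() / genome_length * 100
        miss = tile[codes == MISSING].sum() / genome_length * 100
        rows.append((line, rec, don, het, miss, seg_count[line]))
    per_line = pd.DataFrame(
        rows,
        columns=["line", "recovery_pct", "donor_pct", "het_pct", "nocall_pct",
                 "n_donor_segments"],
    )

    chrom_rows = []
    for chrom, length in pmap.chrom_lengths.items():
        idx = pmap.markers_on(chrom)
        n_markers = len(idx)
        covered = sum(
            pmap.markers[j].end - pmap.markers[j].start + 1
            for j in idx
            if (pmap.codes[:, j] == DONOR).any()
        )
        n_segs = sum(1 for s in donor_segs if s.chrom == chrom)
        chrom_rows.append((chrom, n_markers, n_segs, covered / length * 100))
    per_chrom = pd.DataFrame(
        chrom_rows, columns=["chrom", "n_markers", "n_donor_segments", "coverage_pct"]
    )
    return MapStats(per_line=per_line, per_chrom=per_chrom,
                    donor_segment_lengths=np.array(donor_lengths))


# ---------------------------------------------------------------------------
# map comparison
# ---------------------------------------------------------------------------

def compare_maps(coarse: PhysicalMap, fine: PhysicalMap) -> pd.DataFrame:
    """Coarse-vs-fine donor-segment comparison, per chromosome.

    * ``new_segments``: fine-map donor segments of a line with no overlap with
      any coarse-map donor segment of that line.
    * ``broken_sites``: for each coarse donor segment overlapping ``k >= 2``
      fine donor segments of the same line, ``k - 1`` is added.
    * ``misjudged_pct``: coarse donor territory not confirmed donor in the
      fine map, as a percentage of coarse donor territory on the chromosome.
    """
    if set(coarse.lines) != set(fine.lines):
        raise ValueError("maps cover different line sets")
    coarse_by = _index_segments(coarse.donor_segments())
    fine_by = _index_segments(fine.donor_segments())
    chroms = list(coarse.chrom_lengths)
    rows = []
    for chrom in chroms:
        new = broken = 0
        coarse_total = misjudged = 0
        for line in coarse.lines:
            csegs = coarse_by.get((line, chrom), [])
            fsegs = fine_by.get((line, chrom), [])
            for f in fsegs:
                if not any(f.overlaps(c) for c in csegs):
                    new += 1
            for c in csegs:
                k = sum(1 for f in fsegs if c.overlaps(f))
                if k >= 2:
                    broken += k - 1
                coarse_total += c.end - c.start + 1
                covered = _overlap_total(c, fsegs)
                misjudged += (c.end - c.start + 1) - covered
        rows.append(
            (chrom, new, broken,
             misjudged / coarse_total * 100 if coarse_total else 0.0)
        )
    return pd.DataFrame(rows, columns=["chrom", "new_segments", "broken_sites",
                                       "misjudged_pct"])


def _index_segments(segs: list[Segment]) -> dict[tuple[str, str], list[Segment]]:
    out: dict[tuple[str, str], list[Segment]] = {}
    for s in segs:
        out.setdefault((s.line, s.chrom), []).append(s)
    return out


def _overlap_total(seg: Segment, others: list[Segment]) -> int:
    total = 0
    for o in others:
        lo, hi = max(seg.start, o.start), min(seg.end, o.end)
        if lo <= hi:
            total += hi - lo + 1
    return total
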