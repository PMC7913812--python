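"""Shared in-memory containers for CSSL genotype data.

Genotype calls are coded as small integers throughout the package:

====  =========================================
code  meaning
====  =========================================
0     homozygous for the recurrent (cultivated) parent
1     heterozygous
2     homozygous for the donor (wild) parent
-1    missing / no call
====  =========================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RECURRENT: int = 0
HET: int = 1
DONOR: int = 2
MISSING: int = -1

#: genotype-code -> segment-origin label
ORIGIN_OF_CODE = {RECURRENT: "recurrent", HET: "het", DONOR: "donor", MISSING: "nocall"}
CODE_OF_ORIGIN = {v: k for k, v in ORIGIN_OF_CODE.items()}


@dataclass
class GenotypeMatrix:
    """Lines x SNP sites genotype matrix with per-site QC metadata.

    Parameters
    ----------
    sites
        One row per site with columns ``chrom``, ``pos`` (1-based), ``qual``
        and ``mean_dp``; sorted by (chrom, pos).
    lines
        Line identifiers, one per matrix row.
    calls
        ``int8`` array of shape ``(n_lines, n_sites)`` using the codes above.
    """

    sites: pd.DataFrame
    lines: list[str]
    calls: np.ndarray
    #: optional chromosome physical lengths; segment inference falls back to
    #: the last genotyped position when absent
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.lines), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, [RECURRENT, HET, DONOR, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError(f"sites on {chrom} are not position-sorted")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def line_index(self, line: str) -> int:
        try:
            return self.lines.index(line)
        except ValueError:
            raise KeyError(f"unknown line {line!r}") from None

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix keeping sites where ``mask`` is True (order preserved)."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            lines=list(self.lines),
            calls=self.calls[:, mask].copy(),
            chrom_lengths=self.chrom_lengths,
        )

    def chrom_slice(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Positions and the (n_lines, n_chrom_sites) call block for one chromosome."""
        idx = np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())
        return self.sites["pos"].to_numpy()[idx], self.calls[:, idx]

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Wide representation: one row per site, one column per line."""
        df = self.sites.copy()
        for i, line in enumerate(self.lines):
            df[line] = self.calls[i]
        return df


@dataclass(frozen=True)
class Segment:
    """A contiguous single-origin stretch of one line's chromosome.

    Coordinates are 1-based inclusive; ``n_sites`` counts the genotyped SNP
    sites supporting the call.
    """

    line: str
    chrom: str
    start: int
    end: int
    origin: str
    n_sites: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.origin not in CODE_OF_ORIGIN:
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def length(self) -> int:
        """Segment length under the end - start convention used for reporting."""
        return self.end - self.start

    def overlaps(self, other: "Segment") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    """Tabulate segments (one row each); empty input yields an empty table with headers."""
    cols = ["line", "chrom", "start", "end", "origin", "n_sites"]
    if not segments:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([s.__dict__ for s in segments])[cols]
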