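"""Qualitative-trait mapping by group-wise co-segregation across CSSLs.

Lines are grouped by a categorical phenotype (e.g. seed-coat colour); for
each non-reference category the genome composition of its lines is compared
against the reference (recurrent-parent-like) category.  A marker whose donor
carriers are exactly the lines of one category co-segregates with it.

The phenotype-genotype consistency statistic is
``C_P&G = n_pg / n_g * 100`` where ``n_g`` counts donor carriers of the
marker within the contrast and ``n_pg`` counts carriers whose phenotype
matches the contrasted category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DONOR
from .segmap import PhysicalMap

log = logging.getLogger(__name__)


@dataclass
class PhenoGroups:
    """Partition of lines by phenotype category."""

    by_category: dict[str, list[str]]

    @property
    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.by_category.items()}

    def category_of(self) -> dict[str, str]:
        return {line: cat for cat, ls in self.by_category.items() for line in ls}


def group_lines(phenotypes: pd.DataFrame, trait: str = "scc",
                line_col: str = "line") -> PhenoGroups:
    """Partition lines by category; lines with a missing label are excluded
    with a warning."""
    if trait not in phenotypes.columns:
        raise ValueError(f"trait column {trait!r} missing from phenotype table")
    by: dict[str, list[str]] = {}
    for _, row in phenotypes.iterrows():
        label = row[trait]
        if pd.isna(label):
            log.warning("line %s has no %s phenotype; excluded", row[line_col], trait)
            continue
        by.setdefault(str(label), []).append(str(row[line_col]))
    return PhenoGroups(by_category=by)


def cpg(n_pg: int, n_g: int) -> float:
    """Phenotype-genotype consistency percentage, rounded to whole percent."""
    if n_g < 1:
        raise ValueError("C_P&G is undefined for zero carriers (n_g = 0)")
    if not 0 <= n_pg <= n_g:
        raise ValueError("require 0 <= n_pg <= n_g")
    return round(n_pg / n_g * 100)


def find_cosegregating_markers(
    pmap: PhysicalMap,
    groups: PhenoGroups,
    reference_group: str,
) -> pd.DataFrame:
    """Score every marker against every non-reference category.

    Each contrast is pairwise: only the contrasted category's lines and the
    reference lines participate, which sidesteps epistatic masking between
    categories.  Heterozygous carriers count as non-carriers.  Markers with
    no donor carrier in a contrast are skipped (C undefined).  A marker is
    flagged co-segregating when C = 100% *and* every line of the category
    carries the donor haplotype.

    Returns one row per (marker, contrast) with n_pg, n_g, C and the flag.
    """
    if reference_group not in groups.by_category:
        raise ValueError(f"reference group {reference_group!r} not present")
    ref_lines = groups.by_category[reference_group]
    if not ref_lines:
        raise ValueError("reference group is empty")
    line_idx = {line: i for i, line in enumerate(pmap.lines)}
    rows = []
    for category, cat_lines in groups.by_category.items():
        if category == reference_group:
            continue
        contrast_lines = [l for l in cat_lines + ref_lines if l in line_idx]
        idx = np.array([line_idx[l] for l in contrast_lines])
        is_cat = np.array([l in set(cat_lines) for l in contrast_lines])
        sub = pmap.codes[idx]
        for j, marker in enumerate(pmap.markers):
            carrier = sub[:, j] == DONOR
            n_g = int(carrier.sum())
            if n_g == 0:
                continue
            n_pg = int((carrier & is_cat).sum())
            c = cpg(n_pg, n_g)
            coseg = c == 100 and bool(carrier[is_cat].all())
            rows.append((marker.id, f"{category}_vs_{reference_group}",
                         category, n_pg, n_g, c, coseg))
    return pd.DataFrame(
        rows,
        columns=["marker", "contrast", "category", "n_pg", "n_g", "cpg",
                 "cosegregating"],
    )
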