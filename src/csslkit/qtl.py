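"""Additive QTL scanning for CSSL populations (stepwise-LRT approach).

The scan works on line means of a multi-environment trial.  Background
markers (cofactors) are chosen by forward-backward stepwise least-squares
regression on the marker codes; each marker is then tested by a likelihood
ratio between the model with the marker plus cofactors and the cofactor-only
model.  For Gaussian least squares ``LRT = n * ln(RSS0 / RSS1)`` and
``LOD = LRT / (2 * ln 10)``.

Genotypes are coded -1 (recurrent homozygote), 0 (heterozygote) and +1
(donor homozygote), so the fitted additive effect (ADD) is half the
carrier-vs-noncarrier mean difference and positive values mean the donor
allele raises the trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DONOR
from .segmap import PhysicalMap

log = logging.getLogger(__name__)

LOD_CAP = 1e6  # reported LOD for numerically perfect fits


# ---------------------------------------------------------------------------
# phenotype summarization
# ---------------------------------------------------------------------------

def env_means(pheno: pd.DataFrame, trait: str | None = None) -> pd.Series:
    """Per-line mean across environments (environment means averaged, not raw
    observations, so unbalanced replication does not weight environments)."""
    df = pheno if trait is None else pheno[pheno["trait"] == trait]
    if df.empty:
        raise ValueError("no phenotype records")
    per_env = df.groupby(["line", "env"])["value"].mean()
    means = per_env.groupby("line").mean()
    means.name = "value"
    return means


@dataclass
class VarianceComponents:
    """Expected-mean-squares variance components from the two-way ANOVA."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    n_env: int
    n_rep: float
    h2: float
    single_env: bool = False


def heritability(pheno: pd.DataFrame, trait: str | None = None) -> VarianceComponents:
    """Broad-sense heritability on the entry-mean basis.

    Two-way ANOVA (line, environment, line x environment, residual) with the
    expected-mean-squares estimators::

        sigma2_e  = MS_err
        sigma2_ge = (MS_GE - MS_err) / r
        sigma2_g  = (MS_G - MS_GE) / (e * r)
        h2 = sigma2_g / (sigma2_g + sigma2_ge / e + sigma2_e / (e * r))

    Negative component estimates are truncated to zero (logged).  With a
    single environment the GxE term is not separable; the entry-mean h2 with
    ``sigma2_ge`` omitted is returned and flagged.
    """
    df = pheno if trait is None else pheno[pheno["trait"] == trait]
    if df.empty:
        raise ValueError("no phenotype records")
    lines = df["line"].unique()
    envs = df["env"].unique()
    g, e = len(lines), len(envs)
    r = df.groupby(["line", "env"])["value"].size().mean()
    grand = df["value"].mean()

    cell = df.groupby(["line", "env"])["value"].mean()
    line_m = df.groupby("line")["value"].mean()
    env_m = df.groupby("env")["value"].mean()

    ss_g = e * r * float(((line_m - grand) ** 2).sum())
    ss_err = float(
        ((df["value"] - df.set_index(["line", "env"]).index.map(cell)) ** 2).sum()
    )
    if e >= 2:
        ss_e = g * r * float(((env_m - grand) ** 2).sum())
        ss_cells = r * float(((cell - grand) ** 2).sum())
        ss_ge = ss_cells - ss_g - ss_e
        ms_g = ss_g / (g - 1)
        ms_ge = ss_ge / ((g - 1) * (e - 1))
        df_err = len(df) - g * e
        ms_err = ss_err / df_err if df_err > 0 else 0.0
        sigma2_e = ms_err
        sigma2_ge = (ms_ge - ms_err) / r
        sigma2_g = (ms_g - ms_ge) / (e * r)
        single = False
    else:
        log.warning("single environment: GxE not separable; entry-mean h2 reported")
        ms_g = ss_g / (g - 1)
        df_err = len(df) - g
        ms_err = ss_err / df_err if df_err > 0 else 0.0
        sigma2_e = ms_err
        sigma2_ge = 0.0
        sigma2_g = (ms_g - ms_err) / r
        single = True

    for name, val in (("sigma2_g", sigma2_g), ("sigma2_ge", sigma2_ge),
                      ("sigma2_e", sigma2_e)):
        if val < 0:
            log.info("negative ANOVA estimate %s=%.4g truncated to 0", name, val)
    sigma2_g = max(sigma2_g, 0.0)
    sigma2_ge = max(sigma2_ge, 0.0)
    sigma2_e = max(sigma2_e, 0.0)
    denom = sigma2_g + sigma2_ge / e + sigma2_e / (e * r)
    h2 = sigma2_g / denom if denom > 0 else 0.0
    return VarianceComponents(sigma2_g=sigma2_g, sigma2_ge=sigma2_ge,
                              sigma2_e=sigma2_e, n_env=e, n_rep=float(r),
                              h2=h2, single_env=single)


# ---------------------------------------------------------------------------
# marker coding helpers
# ---------------------------------------------------------------------------

def marker_design(pmap: PhysicalMap, lines: list[str],
                  coding: str = "pm1") -> tuple[np.ndarray, list[str]]:
    """(n_lines x n_markers) genotype-code design matrix for the scan.

    ``pm1``: -1/0/+1 for recurrent/het/donor; ``01``: 0/0.5/1 dosage coding.
    """
    idx = [pmap.lines.index(l) for l in lines]
    codes = pmap.codes[idx].astype(float)
    x = np.where(codes < 0, np.nan, codes)
    # mean-impute the rare missing marker codes
    col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    nan_mask = np.isnan(x)
    x[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    if coding == "pm1":
        x = x - 1.0
    elif coding == "01":
        x = x / 2.0
    else:
        raise ValueError(f"unknown coding {coding!r}")
    return x, [m.id for m in pmap.markers]


def collinear_groups(X: np.ndarray) -> np.ndarray:
    """Map each column to the leftmost column identical to it."""
    m = X.shape[1]
    rep = np.arange(m)
    seen: dict[bytes, int] = {}
    for j in range(m):
        key = X[:, j].tobytes()
        if key in seen:
            rep[j] = seen[key]
        else:
            seen[key] = j
    return rep


def _rss(y: np.ndarray, D: np.ndarray) -> float:
    """Residual sum of squares of y on design D (with intercept prepended)."""
    A = np.column_stack([np.ones(len(y)), D]) if D.size else np.ones((len(y), 1))
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ coef
    return float(r @ r)


def _residualize(M: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Residuals of each column of M after regression on [1, D]."""
    A = np.column_stack([np.ones(M.shape[0]), D]) if D.size else np.ones((M.shape[0], 1))
    coef, _, _, _ = np.linalg.lstsq(A, M, rcond=None)
    return M - A @ coef


# ---------------------------------------------------------------------------
# stepwise cofactor selection
# ---------------------------------------------------------------------------

def rstep_cofactors(
    y: np.ndarray,
    X: np.ndarray,
    p_in: float = 0.05,
    p_out: float = 0.10,
    max_cof: int | None = None,
) -> list[int]:
    """Forward-backward stepwise selection of background markers.

    Perfectly collinear (identical) columns are collapsed to their leftmost
    representative before selection.  Forward steps add the candidate with
    the smallest partial-F p-value below ``p_in``; backward steps drop any
    selected marker whose partial-F p-value exceeds ``p_out``; iterate to a
    fixed point.  ``max_cof`` defaults to ``n_lines // 10``: with far more
    markers than lines an unbounded forward pass at ``p_in`` admits spurious
    cofactors until the residual degrees of freedom collapse, which distorts
    every downstream test.  The cap also always keeps at least two residual
    degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    rep = collinear_groups(X)
    candidates = [j for j in range(X.shape[1])
                  if rep[j] == j and np.ptp(X[:, j]) > 0]
    cap = n - 3
    if max_cof is None:
        max_cof = min(max(n // 10, 1), cap)
    else:
        max_cof = min(max_cof, cap)

    selected: list[int] = []
    changed = True
    while changed and len(selected) < max_cof:
        changed = False
        # forward
        D = X[:, selected]
        rss0 = _rss(y, D)
        k = len(selected) + 1  # intercept + selected
        ry = _residualize(y[:, None], D)[:, 0]
        pool = [j for j in candidates if j not in selected]
        if pool and rss0 > 0:
            RX = _residualize(X[:, pool], D)
            ss = np.einsum("ij,ij->j", RX, RX)
            with np.errstate(divide="ignore", invalid="ignore"):
                gain = np.where(ss > 1e-12, (RX.T @ ry) ** 2 / ss, 0.0)
            rss1 = rss0 - gain
            df2 = n - k - 1
            if df2 > 0:
                with np.errstate(divide="ignore", invalid="ignore"):
                    f = np.where(rss1 > 0, gain / (rss1 / df2), np.inf)
                pvals = stats.f.sf(f, 1, df2)
                best = int(np.argmin(pvals))
                if pvals[best] < p_in:
                    selected.append(pool[best])
                    changed = True
        # backward
        while len(selected) > 1:
            D = X[:, selected]
            rss_full = _rss(y, D)
            df2 = n - len(selected) - 1
            worst_j, worst_p = None, -1.0
            for j in selected:
                others = [s for s in selected if s != j]
                rss_red = _rss(y, X[:, others])
                if rss_full <= 0 or df2 <= 0:
                    p = 0.0
                else:
                    f = (rss_red - rss_full) / (rss_full / df2)
                    p = float(stats.f.sf(f, 1, df2))
                if p > worst_p:
                    worst_j, worst_p = j, p
            if worst_p > p_out:
                selected.remove(worst_j)
                changed = True
            else:
                break
    return sorted(selected)


# ---------------------------------------------------------------------------
# LRT scan
# ---------------------------------------------------------------------------

def lrt_scan(
    y: np.ndarray,
    X: np.ndarray,
    cofactors: list[int],
    pmap: PhysicalMap | None = None,
    lod_threshold: float = 2.5,
    pve_conditional: bool = False,
    cof_window: float = 10e6,
) -> pd.DataFrame:
    """Per-marker likelihood-ratio test of an additive effect.

    For marker ``m`` the background ``B`` is the cofactor set minus markers
    collinear with ``m`` (identical code vectors) and, when marker positions
    are available, minus cofactors within ``cof_window`` bp of ``m`` on the
    same chromosome — a linked cofactor would otherwise absorb the very
    effect being tested, as in composite-interval scanning where cofactors
    inside the test window are dropped.  ``LOD = n * ln(RSS0/RSS1) /
    (2 ln 10)``; ADD is the fitted coefficient of the marker code;
    ``PVE = 100 * (RSS0 - RSS1) / TSS`` with TSS the total sum of squares of
    y (``pve_conditional`` divides by RSS0 instead).  Markers at or above
    ``lod_threshold`` are declared QTL, and declared markers with identical
    code vectors are merged to the peak-LOD representative.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    m = X.shape[1]
    tss = float(((y - y.mean()) ** 2).sum())
    rep = collinear_groups(X)
    cof = [c for c in cofactors if c < m]

    if pmap is not None:
        chrom = np.array([mk.chrom for mk in pmap.markers])
        mid = np.array([(mk.start + mk.end) / 2 for mk in pmap.markers])
    else:
        chrom = mid = None

    def background(j: int) -> tuple[int, ...]:
        B = []
        for c in cof:
            if rep[c] == rep[j]:
                continue
            if chrom is not None and chrom[c] == chrom[j] and abs(mid[c] - mid[j]) <= cof_window:
                continue
            B.append(c)
        return tuple(B)

    lod = np.zeros(m)
    add = np.zeros(m)
    pve = np.zeros(m)
    if tss <= 0:
        declared = np.zeros(m, dtype=bool)
    else:
        # markers sharing an exclusion-adjusted background are tested together
        by_bg: dict[tuple[int, ...], list[int]] = {}
        for j in range(m):
            by_bg.setdefault(background(j), []).append(j)
        for B, members in by_bg.items():
            D = X[:, list(B)]
            rss0 = _rss(y, D)
            ry = _residualize(y[:, None], D)[:, 0]
            RX = _residualize(X[:, members], D)
            ss = np.einsum("ij,ij->j", RX, RX)
            with np.errstate(divide="ignore", invalid="ignore"):
                beta = np.where(ss > 1e-12, (RX.T @ ry) / ss, 0.0)
            gain = beta**2 * ss
            for k, j in enumerate(members):
                rss1 = max(rss0 - gain[k], 0.0)
                if rss1 <= max(1e-12 * tss, 1e-300):
                    lod[j] = LOD_CAP
                elif rss0 <= rss1:
                    lod[j] = 0.0
                else:
                    lod[j] = n * np.log(rss0 / rss1) / (2 * np.log(10))
                add[j] = beta[k]
                denom = rss0 if pve_conditional else tss
                pve[j] = 100.0 * max(rss0 - rss1, 0.0) / denom if denom > 0 else 0.0
        declared = lod >= lod_threshold
        # merge declared markers with identical code vectors: keep peak LOD
        for g in set(rep[declared]):
            members = np.flatnonzero((rep == g) & declared)
            if len(members) > 1:
                peak = members[np.argmax(lod[members])]
                declared[members] = False
                declared[peak] = True

    out = pd.DataFrame({
        "marker_index": np.arange(m),
        "lod": lod,
        "add": add,
        "pve": pve,
        "declared": declared,
    })
    if pmap is not None:
        mk = pmap.marker_frame()
        out.insert(0, "marker", mk["id"])
        out["chrom"] = mk["chrom"]
        out["start"] = mk["start"]
        out["end"] = mk["end"]
    return out


def _marker_coef(y: np.ndarray, X: np.ndarray, B: list[int], j: int) -> float:
    A = np.column_stack([np.ones(len(y)), X[:, B], X[:, j]])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[-1])


def scan(
    pmap: PhysicalMap,
    pheno: pd.DataFrame,
    trait: str = "dtf",
    lod_threshold: float = 2.5,
    p_in: float = 0.05,
    p_out: float = 0.10,
    max_cof: int | None = None,
    coding: str = "pm1",
    exclude_lines: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Convenience wrapper: line means -> stepwise cofactors -> LRT scan."""
    means = env_means(pheno, trait)
    lines = [l for l in pmap.lines if l in means.index and l not in exclude_lines]
    y = means.loc[lines].to_numpy()
    X, _ = marker_design(pmap, lines, coding=coding)
    cof = rstep_cofactors(y, X, p_in=p_in, p_out=p_out, max_cof=max_cof)
    return lrt_scan(y, X, cof, pmap=pmap, lod_threshold=lod_threshold)


# ---------------------------------------------------------------------------
# per-line significance vs the recurrent parent
# ---------------------------------------------------------------------------

def lines_vs_recurrent(
    pheno: pd.DataFrame,
    recurrent_id: str,
    trait: str | None = None,
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sided Student's t-test of each line's observations vs the recurrent
    parent's; returns per-line significance and direction (later/earlier)."""
    df = pheno if trait is None else pheno[pheno["trait"] == trait]
    ref = df.loc[df["line"] == recurrent_id, "value"].to_numpy()
    if len(ref) < 2:
        raise ValueError(f"recurrent parent {recurrent_id!r} needs >= 2 observations")
    rows = []
    for line, sub in df.groupby("line"):
        if line == recurrent_id:
            continue
        vals = sub["value"].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"line {line} has < 2 observations")
        t, p = stats.ttest_ind(vals, ref, equal_var=not welch)
        rows.append((line, float(vals.mean() - ref.mean()), float(t), float(p),
                     p < alpha, "later" if vals.mean() > ref.mean() else "earlier"))
    return pd.DataFrame(rows, columns=["line", "diff", "t", "p", "significant",
                                       "direction"])


def explain_significant_lines(
    qtl: pd.DataFrame,
    pmap: PhysicalMap,
    line_flags: pd.DataFrame,
) -> pd.DataFrame:
    """Attribute each significant line to declared QTL it carries.

    A line is explained iff it is a donor carrier at >= 1 declared QTL whose
    additive-effect sign matches the line's direction (positive ADD for later
    lines, negative for earlier).
    """
    declared = qtl[qtl["declared"]]
    marker_col = {}
    for _, row in declared.iterrows():
        j = int(row["marker_index"])
        marker_col[j] = (row.get("marker", str(j)), float(row["add"]))
    line_idx = {l: i for i, l in enumerate(pmap.lines)}
    rows = []
    for _, flag in line_flags.iterrows():
        if not flag["significant"]:
            continue
        line = flag["line"]
        want_positive = flag["direction"] == "later"
        carried = []
        if line in line_idx:
            for j, (mid, a) in marker_col.items():
                if pmap.codes[line_idx[line], j] == DONOR and (a > 0) == want_positive:
                    carried.append(mid)
        rows.append((line, flag["direction"], ";".join(carried), bool(carried)))
    return pd.DataFrame(rows, columns=["line", "direction", "explaining_qtl",
                                       "explained"])
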