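"""Synthetic CSSL populations, phenotypes, expression tables and planted variants.

The generator emulates the structure a CSSL (chromosome segment substitution
line) study assumes: a donor (wild) parent crossed to a recurrent (cultivated)
parent, followed by repeated backcrossing to the recurrent parent and selfing
to near-homozygosity.  Each line's genome is a mosaic of long recurrent
stretches with a handful of short donor segments.

Haplotypes are represented as breakpoint interval lists, not per-site arrays:
a chromosome haplotype is a pair ``(ends, origins)`` where ``ends`` are the
1-based inclusive end coordinates of successive single-origin intervals
(``ends[-1]`` equals the chromosome length) and ``origins`` are 0 (recurrent)
or 1 (donor).  Meiosis operates on intervals, which keeps a whole-population
simulation cheap regardless of SNP density.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DONOR, HET, MISSING, RECURRENT, GenotypeMatrix, Segment

Hap = tuple[np.ndarray, np.ndarray]  # (interval ends, interval origins)

TISSUES = ["Leaf", "Flower", "14seed", "21seed", "28seed", "35seed", "7pod", "21pod"]
NUCS = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# genome and scheme specifications
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Chromosome names/lengths and the biallelic SNP positions on each.

    Every SNP site is polymorphic between the two parents by construction.
    """

    chromosomes: list[tuple[str, int]]
    snp_positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("empty chromosome list")
        for name, length in self.chromosomes:
            pos = np.asarray(self.snp_positions[name], dtype=np.int64)
            if len(pos) and (np.any(np.diff(pos) <= 0) or pos[0] < 1 or pos[-1] > length):
                raise ValueError(f"positions on {name} must be strictly increasing within [1, {length}]")
            self.snp_positions[name] = pos

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p in self.snp_positions.values())

    @classmethod
    def regular(
        cls,
        n_chrom: int = 20,
        chrom_length: int = 45_000_000,
        sites_per_chrom: int = 150,
        prefix: str = "Gm",
    ) -> "GenomeSpec":
        """Evenly spaced SNPs on equal-length chromosomes named ``Gm01``..."""
        chroms = [(f"{prefix}{i + 1:02d}", chrom_length) for i in range(n_chrom)]
        step = chrom_length // (sites_per_chrom + 1)
        pos = np.arange(1, sites_per_chrom + 1, dtype=np.int64) * step
        return cls(chroms, {name: pos.copy() for name, _ in chroms})


@dataclass
class BreedingScheme:
    """Backcross/selfing programme used to derive each line.

    ``crossover_rate`` is the expected number of crossovers per chromosome per
    meiosis (the chromosome's genetic length in Morgans), with crossover
    positions uniform on the physical length.  ``recurrent_biased`` selection
    emulates marker-assisted selection by keeping, at each backcross, the
    gamete with fewer donor SNP sites among two candidate gametes.
    """

    n_backcross: int = 3
    n_self: int = 6
    selection_mode: str = "none"
    crossover_rate: float = 1.0
    #: how many of the backcross generations apply gamete selection
    #: (None = all); real programmes typically genotype only a few
    #: generations, so presets limit selection to the final two backcrosses
    n_selected_backcross: int | None = None

    def __post_init__(self) -> None:
        if self.n_backcross < 1:
            raise ValueError("n_backcross must be >= 1")
        if self.n_self < 1:
            raise ValueError("n_self must be >= 1")
        if self.crossover_rate <= 0:
            raise ValueError("crossover_rate must be > 0")
        if self.selection_mode not in ("none", "recurrent_biased"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        if self.n_selected_backcross is not None and self.n_selected_backcross < 0:
            raise ValueError("n_selected_backcross must be >= 0")


@dataclass
class TraitArchitecture:
    """Planted genetic architecture for one qualitative and one quantitative trait.

    ``scc_locus_i`` / ``scc_locus_g`` are the two epistatic seed-coat-colour
    loci (I masks G: donor homozygotes at I are black regardless of G).
    ``dtf_qtl`` lists ``(chrom, pos, additive_effect_days)`` for days to
    flowering; under the +/-1 genotype coding a donor homozygote deviates by
    ``+2a`` from a recurrent homozygote.
    """

    scc_locus_i: tuple[str, int]
    scc_locus_g: tuple[str, int]
    dtf_qtl: list[tuple[str, int, float]]
    mu: float = 53.7
    h2_target: float = 0.956
    n_env: int = 3
    n_rep: int = 3
    env_sd: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.h2_target < 1:
            raise ValueError("h2_target must lie in (0, 1)")
        if not all(np.isfinite(a) for _, _, a in self.dtf_qtl):
            raise ValueError("additive effects must be finite")

    def loci(self) -> list[tuple[str, int]]:
        return [self.scc_locus_i, self.scc_locus_g] + [(c, p) for c, p, _ in self.dtf_qtl]

    def validate_on(self, genome: GenomeSpec) -> None:
        lengths = genome.chrom_lengths
        for chrom, pos in self.loci():
            if chrom not in lengths or not 1 <= pos <= lengths[chrom]:
                raise ValueError(f"locus {chrom}:{pos} lies off the simulated genome")


@dataclass
class ParentalVariantSet:
    """Two fully homozygous parental haplotypes differing at every SNP site."""

    genome: GenomeSpec
    recurrent_allele: dict[str, np.ndarray]  # nucleotide per site
    donor_allele: dict[str, np.ndarray]


@dataclass
class TruthRecord:
    """Ground truth retained from the simulation for parameter-recovery tests."""

    genome: GenomeSpec
    lines: list[str]
    #: per line: chrom -> (hapA, hapB)
    haplotypes: list[dict[str, tuple[Hap, Hap]]]
    segments: list[Segment] = field(default_factory=list)
    genetic_values: pd.Series | None = None

    def genotype_at(self, line_idx: int, chrom: str, pos: int) -> int:
        """True genotype code of one line at an arbitrary coordinate."""
        hapA, hapB = self.haplotypes[line_idx][chrom]
        a = int(hapA[1][np.searchsorted(hapA[0], pos)])
        b = int(hapB[1][np.searchsorted(hapB[0], pos)])
        return {0: RECURRENT, 1: HET, 2: DONOR}[a + b]

    def genotypes_at_loci(self, loci: list[tuple[str, int]]) -> np.ndarray:
        """(n_lines, n_loci) genotype codes at the given coordinates."""
        out = np.empty((len(self.lines), len(loci)), dtype=np.int8)
        for j, (chrom, pos) in enumerate(loci):
            for i in range(len(self.lines)):
                out[i, j] = self.genotype_at(i, chrom, pos)
        return out

    def donor_fraction(self, line_idx: int) -> float:
        """Fraction of the genome donor-homozygous in one line (length-weighted)."""
        donor_bp = 0
        for chrom, (hapA, hapB) in self.haplotypes[line_idx].items():
            bounds = np.union1d(hapA[0], hapB[0])
            starts = np.concatenate(([0], bounds[:-1]))
            a = hapA[1][np.searchsorted(hapA[0], bounds)]
            b = hapB[1][np.searchsorted(hapB[0], bounds)]
            donor_bp += int(np.sum((bounds - starts) * ((a == 1) & (b == 1))))
        return donor_bp / self.genome.genome_length


# ---------------------------------------------------------------------------
# meiosis on interval haplotypes
# ---------------------------------------------------------------------------

def _slice_hap(hap: Hap, lo: int, hi: int) -> tuple[list[int], list[int]]:
    """Interval pieces of ``hap`` covering the 1-based inclusive range [lo, hi]."""
    ends, origins = hap
    i = int(np.searchsorted(ends, lo))
    out_e: list[int] = []
    out_o: list[int] = []
    while True:
        e = int(ends[i])
        out_e.append(min(e, hi))
        out_o.append(int(origins[i]))
        if e >= hi:
            break
        i += 1
    return out_e, out_o


def _merge(ends: list[int], origins: list[int]) -> Hap:
    """Fuse adjacent intervals of equal origin."""
    me: list[int] = []
    mo: list[int] = []
    for e, o in zip(ends, origins):
        if mo and mo[-1] == o:
            me[-1] = e
        else:
            me.append(e)
            mo.append(o)
    return np.asarray(me, dtype=np.int64), np.asarray(mo, dtype=np.int8)


def meiosis(hapA: Hap, hapB: Hap, length: int, rate: float, rng: np.random.Generator) -> Hap:
    """One recombinant gamete from a pair of chromosome haplotypes.

    The crossover count is Poisson(``rate``) with positions uniform on the
    physical length (no interference); the starting haplotype is chosen at
    random and the source alternates at each crossover.
    """
    k = int(rng.poisson(rate))
    cur = int(rng.integers(2))
    pair = (hapA, hapB)
    if k == 0:
        ends, origins = pair[cur]
        return ends.copy(), origins.copy()
    xs = np.unique(rng.integers(1, length, size=k))
    bounds = np.concatenate((xs, [length]))
    ends: list[int] = []
    origins: list[int] = []
    lo = 1
    for hi in bounds:
        e, o = _slice_hap(pair[cur], lo, int(hi))
        ends.extend(e)
        origins.extend(o)
        lo = int(hi) + 1
        cur = 1 - cur
    return _merge(ends, origins)


def _hap_codes_at(hap: Hap, positions: np.ndarray) -> np.ndarray:
    ends, origins = hap
    return origins[np.searchsorted(ends, positions)]


def _uniform_hap(length: int, origin: int) -> Hap:
    return np.array([length], dtype=np.int64), np.array([origin], dtype=np.int8)


def _donor_site_count(gamete: dict[str, Hap], genome: GenomeSpec) -> int:
    return sum(
        int(_hap_codes_at(gamete[name], genome.snp_positions[name]).sum())
        for name, _ in genome.chromosomes
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_parents(genome_spec: GenomeSpec, seed: int) -> ParentalVariantSet:
    """Draw nucleotides for the two parents, fixed-different at every SNP site."""
    rng = np.random.default_rng(seed)
    rec: dict[str, np.ndarray] = {}
    don: dict[str, np.ndarray] = {}
    for name, _ in genome_spec.chromosomes:
        n = len(genome_spec.snp_positions[name])
        r = rng.integers(0, 4, size=n)
        # donor allele: one of the three other nucleotides
        d = (r + rng.integers(1, 4, size=n)) % 4
        rec[name] = NUCS[r]
        don[name] = NUCS[d]
    return ParentalVariantSet(genome=genome_spec, recurrent_allele=rec, donor_allele=don)


def _simulate_line(
    genome: GenomeSpec, scheme: BreedingScheme, rng: np.random.Generator
) -> dict[str, tuple[Hap, Hap]]:
    """One CSSL: F1, then backcrosses to the recurrent parent, then selfing."""
    rec = {name: _uniform_hap(length, 0) for name, length in genome.chromosomes}
    donor = {name: _uniform_hap(length, 1) for name, length in genome.chromosomes}
    pair = {name: (donor[name], rec[name]) for name, _ in genome.chromosomes}

    def gamete_from(p: dict[str, tuple[Hap, Hap]]) -> dict[str, Hap]:
        return {
            name: meiosis(p[name][0], p[name][1], length, scheme.crossover_rate, rng)
            for name, length in genome.chromosomes
        }

    n_sel = (scheme.n_backcross if scheme.n_selected_backcross is None
             else min(scheme.n_selected_backcross, scheme.n_backcross))
    for bc in range(scheme.n_backcross):
        g = gamete_from(pair)
        # selection acts in the final n_sel backcross generations
        if (scheme.selection_mode == "recurrent_biased"
                and bc >= scheme.n_backcross - n_sel):
            g2 = gamete_from(pair)
            if _donor_site_count(g2, genome) < _donor_site_count(g, genome):
                g = g2
        pair = {name: (g[name], rec[name]) for name, _ in genome.chromosomes}
    for _ in range(scheme.n_self):
        g1 = gamete_from(pair)
        g2 = gamete_from(pair)
        pair = {name: (g1[name], g2[name]) for name, _ in genome.chromosomes}
    return pair


def _true_segments_for_line(
    line: str, genome: GenomeSpec, codes_by_chrom: dict[str, np.ndarray]
) -> list[Segment]:
    """Collapse per-site true codes into segments.

    The same coordinate convention as breakpoint inference is used: boundaries
    at the floor midpoint between the flanking sites, terminal segments
    extended to the chromosome ends.
    """
    segs: list[Segment] = []
    for chrom, length in genome.chromosomes:
        pos = genome.snp_positions[chrom]
        codes = codes_by_chrom[chrom]
        if len(pos) == 0:
            continue
        change = np.flatnonzero(np.diff(codes)) + 1
        starts_idx = np.concatenate(([0], change))
        ends_idx = np.concatenate((change - 1, [len(codes) - 1]))
        for k, (si, ei) in enumerate(zip(starts_idx, ends_idx)):
            start = 1 if k == 0 else (pos[si - 1] + pos[si]) // 2 + 1
            end = length if k == len(starts_idx) - 1 else (pos[ei] + pos[ei + 1]) // 2
            segs.append(
                Segment(
                    line=line,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    origin={0: "recurrent", 1: "het", 2: "donor"}[int(codes[si])],
                    n_sites=int(ei - si + 1),
                )
            )
    return segs


def simulate_cssl_population(
    parents: ParentalVariantSet,
    scheme: BreedingScheme | list[BreedingScheme],
    n_lines: int,
    seed: int,
    require_donor: bool = False,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate a CSSL population; returns the noise-free genotype matrix plus truth.

    ``scheme`` may be a list of length ``n_lines`` to mix backcross depths
    within one population (as real CSSL panels do).  ``require_donor``
    redraws a line that ends up carrying no donor-homozygous site, emulating
    the selection of substitution lines for the panel (a line with a purely
    recurrent genome is not a CSSL).
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    genome = parents.genome
    schemes = scheme if isinstance(scheme, list) else [scheme] * n_lines
    if len(schemes) != n_lines:
        raise ValueError("need one scheme per line")
    rng = np.random.default_rng(seed)
    lines = [f"CSSL{i + 1:03d}" for i in range(n_lines)]

    haplotypes: list[dict[str, tuple[Hap, Hap]]] = []
    segments: list[Segment] = []
    blocks: list[np.ndarray] = []
    for line, sch in zip(lines, schemes):
        for _attempt in range(100):
            pair = _simulate_line(genome, sch, rng)
            codes_by_chrom = {}
            row_parts = []
            for chrom, _ in genome.chromosomes:
                pos = genome.snp_positions[chrom]
                a = _hap_codes_at(pair[chrom][0], pos)
                b = _hap_codes_at(pair[chrom][1], pos)
                codes = (a + b).astype(np.int8)  # 0/1/2 by donor dose
                codes_by_chrom[chrom] = codes
                row_parts.append(codes)
            row = np.concatenate(row_parts)
            if not require_donor or (row == DONOR).any():
                break
        haplotypes.append(pair)
        segments.extend(_true_segments_for_line(line, genome, codes_by_chrom))
        blocks.append(row)

    sites = pd.DataFrame(
        {
            "chrom": np.repeat(
                [name for name, _ in genome.chromosomes],
                [len(genome.snp_positions[name]) for name, _ in genome.chromosomes],
            ),
            "pos": np.concatenate([genome.snp_positions[name] for name, _ in genome.chromosomes]),
        }
    )
    sites["qual"] = 60.0
    sites["mean_dp"] = 999.0  # noise-free matrix: depth not yet simulated
    matrix = GenotypeMatrix(
        sites=sites, lines=lines, calls=np.vstack(blocks),
        chrom_lengths=genome.chrom_lengths,
    )
    truth = TruthRecord(genome=genome, lines=lines, haplotypes=haplotypes, segments=segments)
    return matrix, truth


def observe_genotypes(
    matrix: GenotypeMatrix,
    depth: float,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    qual_range: tuple[float, float] = (40.0, 90.0),
    low_qual_fraction: float = 0.0,
) -> GenotypeMatrix:
    """Overlay a sequencing observation model on a true genotype matrix.

    Per line x site, read depth is Poisson(``depth``); zero depth yields a
    missing call, otherwise the call is mis-coded to one of the other two
    genotypes with probability ``error_rate``.  ``missing_rate`` drops further
    calls at random.  Per-site QUAL and mean-depth metadata are emitted for QC
    filtering; a ``low_qual_fraction`` of sites receives QUAL below 30.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    for r in (error_rate, missing_rate, low_qual_fraction):
        if not 0 <= r <= 1:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = matrix.calls.copy()
    dp = rng.poisson(depth, size=calls.shape)
    calls[dp == 0] = MISSING

    err = (rng.random(calls.shape) < error_rate) & (calls != MISSING)
    if err.any():
        # symmetric mis-call: shift to one of the two other codes
        shift = rng.integers(1, 3, size=int(err.sum()))
        calls[err] = (calls[err] + shift) % 3
    drop = rng.random(calls.shape) < missing_rate
    calls[drop] = MISSING

    sites = matrix.sites.copy()
    sites["mean_dp"] = dp.mean(axis=0)
    qual = rng.uniform(*qual_range, size=len(sites))
    if low_qual_fraction > 0:
        low = rng.random(len(sites)) < low_qual_fraction
        qual[low] = rng.uniform(5.0, 29.9, size=int(low.sum()))
    sites["qual"] = qual
    return GenotypeMatrix(sites=sites, lines=list(matrix.lines), calls=calls,
                          chrom_lengths=matrix.chrom_lengths)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def scc_category(code_i: int, code_g: int) -> str:
    """Seed-coat colour from the two-locus genotype; I is epistatic over G.

    Heterozygotes are treated as recurrent-like (the population is near-fully
    homozygous, so dominance at the residual heterozygotes is immaterial).
    """
    if code_i == DONOR:
        return "black"
    if code_g == DONOR:
        return "green"
    return "yellow"


def simulate_phenotypes(
    truth: TruthRecord,
    architecture: TraitArchitecture,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seed-coat colour and multi-environment days-to-flowering phenotypes.

    Returns ``(scc, dtf)``: one row per line with its colour category, and a
    long table (line, env, rep, trait, value).  The residual standard
    deviation is solved from the realized genetic variance so that the
    expected broad-sense heritability on the line-mean (entry-mean) basis
    equals ``h2_target``; no genotype-by-environment interaction is simulated.
    """
    architecture.validate_on(truth.genome)
    rng = np.random.default_rng(seed)
    lines = truth.lines
    codes = truth.genotypes_at_loci(architecture.loci())
    scc = pd.DataFrame(
        {
            "line": lines,
            "scc": [scc_category(codes[i, 0], codes[i, 1]) for i in range(len(lines))],
        }
    )

    effects = np.array([a for _, _, a in architecture.dtf_qtl])
    x = codes[:, 2:].astype(float) - 1.0  # 0/1/2 -> -1/0/+1
    g = architecture.mu + x @ effects
    var_g = float(np.var(g, ddof=1)) if len(lines) > 1 else 0.0
    e, r = architecture.n_env, architecture.n_rep
    if var_g > 0:
        sigma2_eps = e * r * var_g * (1.0 - architecture.h2_target) / architecture.h2_target
    else:
        sigma2_eps = 1.0
    env_effects = rng.normal(0.0, architecture.env_sd, size=e)

    records = []
    for ei in range(e):
        env = f"env{ei + 1}"
        for rep in range(1, r + 1):
            vals = g + env_effects[ei] + rng.normal(0.0, np.sqrt(sigma2_eps), size=len(lines))
            for line, v in zip(lines, vals):
                records.append((line, env, rep, "dtf", float(v)))
    dtf = pd.DataFrame(records, columns=["line", "env", "rep", "trait", "value"])
    truth.genetic_values = pd.Series(g, index=lines, name="genetic_value")
    return scc, dtf


# ---------------------------------------------------------------------------
# gene models, expression and planted variants
# ---------------------------------------------------------------------------

_STANDARD_STOPS = ("TAA", "TAG", "TGA")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(NUCS[rng.integers(0, 4, size=n)])


def random_gene_model(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    start: int,
    n_exons: int | None = None,
    strand: str | None = None,
    promoter_len: int = 2000,
):
    """A toy single-transcript gene model with its local reference sequence.

    Exons are 60-240 bp, introns 60-300 bp; the CDS spans all exons with
    UTR-free boundaries (CDS == exons), begins with ATG and ends with a stop
    codon, and contains no internal stop on the coding strand.  Returns a
    :class:`csslkit.genes.GeneModel`.
    """
    from .genes import GeneModel  # local import to avoid a cycle

    if n_exons is None:
        n_exons = int(rng.integers(1, 5))
    if strand is None:
        strand = "+" if rng.integers(2) == 0 else "-"
    exon_lens = (rng.integers(20, 80, size=n_exons) * 3).astype(int)  # keep frame simple
    intron_lens = rng.integers(60, 301, size=max(0, n_exons - 1)).astype(int)

    exons: list[tuple[int, int]] = []
    p = start
    for i, el in enumerate(exon_lens):
        exons.append((p, p + int(el) - 1))
        p += int(el)
        if i < n_exons - 1:
            p += int(intron_lens[i])
    span_start, span_end = exons[0][0], exons[-1][1]
    seq_start = span_start - promoter_len - 50
    seq_end = span_end + promoter_len + 50
    seq = list(_random_seq(rng, seq_end - seq_start + 1))

    # write a clean CDS (start codon, no internal stops, terminal stop) onto
    # the coding strand, then project it back onto the plus strand
    n_codons = int(exon_lens.sum()) // 3
    sense = ["ATG"]
    for _ in range(n_codons - 2):
        while True:
            c = _random_seq(rng, 3)
            if c not in _STANDARD_STOPS and c != "ATG":
                break
        sense.append(c)
    sense.append(_STANDARD_STOPS[rng.integers(0, 3)])
    cds_sense = "".join(sense)
    cds_plus = cds_sense if strand == "+" else _revcomp(cds_sense)
    i = 0
    for es, ee in exons:
        for pos in range(es, ee + 1):
            seq[pos - seq_start] = cds_plus[i]
            i += 1
    # canonical GT..AG introns on the plus strand representation
    for (es, ee), (ns, _ne) in zip(exons[:-1], exons[1:]):
        intron_start, intron_end = ee + 1, ns - 1
        if strand == "+":
            seq[intron_start - seq_start] = "G"
            seq[intron_start + 1 - seq_start] = "T"
            seq[intron_end - 1 - seq_start] = "A"
            seq[intron_end - seq_start] = "G"
        else:
            seq[intron_start - seq_start] = "C"
            seq[intron_start + 1 - seq_start] = "T"
            seq[intron_end - 1 - seq_start] = "A"
            seq[intron_end - seq_start] = "C"

    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=list(exons),
        promoter_len=promoter_len,
        seq="".join(seq),
        seq_start=seq_start,
    )


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


#: planted-class -> how to pick (position, donor base, recurrent base)
PLANTABLE_CLASSES = ("missense", "stop_gain", "stop_loss", "splice_acceptor", "promoter", "synonymous", "intron")


def plant_variant(gene, effect_class: str, rng: np.random.Generator) -> tuple[int, str, str]:
    """Choose a (pos, ref, alt) pair in ``gene`` producing the requested effect.

    Construction is by codon arithmetic on the coding strand, independent of
    the variant-effect classifier, so classifier round-trip tests are a real
    check.  ``ref`` is the recurrent (reference) base on the plus strand and
    ``alt`` the donor base.
    """
    cds_pos = gene.cds_plus_positions()  # plus-strand coords in transcription order

    def sense_base(base: str) -> str:
        return base if gene.strand == "+" else _revcomp(base)

    if effect_class == "stop_gain":
        # mutate a sense codon to TGA at its first base where possible (ref != T)
        for ci in range(1, len(cds_pos) // 3 - 1):
            codon = gene.cds_codon(ci)
            if codon[0] != "T" and codon[1:] == "GA":
                p = cds_pos[3 * ci]
                return p, gene.base_at(p), sense_base("T") if gene.strand == "-" else "T"
        # fall back: rewrite via third base of TAC->TAA style not possible
        # without editing the sequence; pick TGG -> TGA (third base)
        for ci in range(1, len(cds_pos) // 3 - 1):
            if gene.cds_codon(ci) == "TGG":
                p = cds_pos[3 * ci + 2]
                return p, gene.base_at(p), "A" if gene.strand == "+" else "T"
        raise ValueError("no stop-gain site available in this gene")
    if effect_class == "stop_loss":
        # first base of the terminal stop codon -> C gives CAA/CAG/CGA (non-stop)
        p = cds_pos[-3]
        return p, gene.base_at(p), "C" if gene.strand == "+" else "G"
    if effect_class == "missense":
        for ci in range(1, len(cds_pos) // 3 - 1):
            codon = gene.cds_codon(ci)
            # second-base transversion always changes the amino acid and, for
            # non-T first bases, can never create a stop codon
            if codon[0] not in "T":
                new = "A" if codon[1] != "A" else "C"
                p = cds_pos[3 * ci + 1]
                return p, gene.base_at(p), new if gene.strand == "+" else _revcomp(new)
        raise ValueError("no missense site available in this gene")
    if effect_class == "synonymous":
        for ci in range(1, len(cds_pos) // 3 - 1):
            codon = gene.cds_codon(ci)
            # fourfold-degenerate families: third base free
            if codon[:2] in ("CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"):
                new = "A" if codon[2] != "A" else "G"
                p = cds_pos[3 * ci + 2]
                return p, gene.base_at(p), new if gene.strand == "+" else _revcomp(new)
        raise ValueError("no synonymous site available in this gene")
    if effect_class == "splice_acceptor":
        introns = gene.introns()
        if not introns:
            raise ValueError("gene has no introns")
        s, e = introns[0]
        # acceptor = the 2 intron bases adjacent to the downstream exon
        p = e if gene.strand == "+" else s
        ref = gene.base_at(p)
        alt = "C" if ref != "C" else "T"
        return p, ref, alt
    if effect_class == "intron":
        introns = gene.introns()
        if not introns:
            raise ValueError("gene has no introns")
        s, e = introns[0]
        p = (s + e) // 2
        ref = gene.base_at(p)
        return p, ref, "A" if ref != "A" else "G"
    if effect_class == "promoter":
        tss = gene.tss()
        p = tss - 500 if gene.strand == "+" else tss + 500
        ref = gene.base_at(p)
        return p, ref, "A" if ref != "A" else "G"
    raise ValueError(f"cannot plant variant class {effect_class!r}")


def simulate_expression_and_variants(
    causal_genes: list,
    decoy_genes: list,
    seed: int,
    causal_classes: dict[str, str] | None = None,
    fold: float = 4.0,
    n_de_tissues: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parental 8-tissue FPKM table plus planted parental variants.

    Causal genes receive >= ``fold``-fold parent differences in
    ``n_de_tissues`` tissues (>= 3) with FPKM >= 2 somewhere, and one planted
    SNP of their assigned effect class.  Decoys get either sub-two-fold
    differences or sub-2 FPKM everywhere, plus synonymous/intronic decoy
    variants.  Expression rows: (gene, tissue, parent, fpkm) with parents
    labelled ``donor``/``recurrent``.
    """
    if n_de_tissues < 3:
        raise ValueError("causal genes must differ in at least 3 tissues")
    rng = np.random.default_rng(seed)
    classes = causal_classes or {}
    expr_rows = []
    var_rows = []

    for gene in causal_genes:
        base = rng.uniform(5.0, 40.0, size=len(TISSUES))
        de_idx = rng.choice(len(TISSUES), size=n_de_tissues, replace=False)
        donor_v = base.copy()
        rec_v = base.copy()
        up_in_donor = rng.integers(2) == 0
        for t in de_idx:
            if up_in_donor:
                donor_v[t] = base[t] * fold
            else:
                rec_v[t] = base[t] * fold
        for t, tissue in enumerate(TISSUES):
            expr_rows.append((gene.gene_id, tissue, "donor", float(donor_v[t])))
            expr_rows.append((gene.gene_id, tissue, "recurrent", float(rec_v[t])))
        cls = classes.get(gene.gene_id, "missense")
        pos, ref, alt = plant_variant(gene, cls, rng)
        var_rows.append((gene.chrom, pos, ref, alt, gene.gene_id, cls))

    for gene in decoy_genes:
        if rng.integers(2) == 0:
            vals = rng.uniform(0.0, 1.9, size=len(TISSUES))  # low everywhere
            donor_v, rec_v = vals, vals * rng.uniform(0.8, 1.2, size=len(TISSUES))
            rec_v = np.minimum(rec_v, 1.9)
        else:
            vals = rng.uniform(5.0, 40.0, size=len(TISSUES))
            donor_v = vals
            rec_v = vals * rng.uniform(0.6, 1.6, size=len(TISSUES))  # < 2-fold
        for t, tissue in enumerate(TISSUES):
            expr_rows.append((gene.gene_id, tissue, "donor", float(donor_v[t])))
            expr_rows.append((gene.gene_id, tissue, "recurrent", float(rec_v[t])))
        try:
            cls = "synonymous" if rng.integers(2) == 0 else "intron"
            pos, ref, alt = plant_variant(gene, cls, rng)
            var_rows.append((gene.chrom, pos, ref, alt, gene.gene_id, cls))
        except ValueError:
            pass  # single-exon decoy without a plantable decoy site

    expr = pd.DataFrame(expr_rows, columns=["gene", "tissue", "parent", "fpkm"])
    variants = pd.DataFrame(
        var_rows, columns=["chrom", "pos", "ref", "alt", "gene", "planted_class"]
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return expr, variants


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def paper_preset_schemes(n_lines: int = 177, seed: int = 0) -> list[BreedingScheme]:
    """Backcross-depth mixture emulating the study population's pedigree classes.

    Roughly 100/49/28 of 177 lines at BC3/BC4/BC5, each with >= 6 selfing
    generations.  Marker-assisted (recurrent-biased) gamete selection acts in
    two generations only, matching the programme's two rounds of
    marker-assisted selection; selecting at every backcross would thin donor
    segments well below the panel's reported density.
    """
    rng = np.random.default_rng(seed)
    depths = rng.choice([3, 4, 5], size=n_lines, p=[100 / 177, 49 / 177, 28 / 177])
    return [
        # 1.25 Morgans/chromosome ~ a 2500 cM genome over 20 chromosomes
        BreedingScheme(n_backcross=int(d), n_self=6,
                       selection_mode="recurrent_biased",
                       n_selected_backcross=2, crossover_rate=1.25)
        for d in depths
    ]


def paper_preset_architecture(genome: GenomeSpec) -> TraitArchitecture:
    """Trait architecture mirroring the study: 2 epistatic colour loci and 6 DTF QTL.

    Additive effects use the reported profile (-0.58, +3.68, +2.63, -1.00,
    -0.72, +2.07 days) on six distinct chromosomes; population mean 53.7 d and
    target heritability 0.956 over 3 environments x 3 replicates.
    """
    L = genome.chrom_lengths

    def mid(chrom: str, frac: float) -> int:
        return int(L[chrom] * frac)

    return TraitArchitecture(
        scc_locus_i=("Gm08", mid("Gm08", 0.2)),
        scc_locus_g=("Gm01", mid("Gm01", 0.95)),
        dtf_qtl=[
            ("Gm04", mid("Gm04", 0.9), -0.58),
            ("Gm10", mid("Gm10", 0.85), 3.68),
            ("Gm12", mid("Gm12", 0.1), 2.63),
            ("Gm15", mid("Gm15", 0.6), -1.00),
            ("Gm16", mid("Gm16", 0.01), -0.72),
            ("Gm17", mid("Gm17", 0.95), 2.07),
        ],
        mu=53.7,
        h2_target=0.956,
        n_env=3,
        n_rep=3,
    )


def simulate_paper_study(
    seed: int,
    n_lines: int = 177,
    sites_per_chrom: int = 150,
) -> tuple[GenotypeMatrix, TruthRecord, TraitArchitecture, pd.DataFrame, pd.DataFrame]:
    """One full paper-emulating study: population, colour and flowering phenotypes.

    Returns ``(matrix_true, truth, architecture, scc, dtf)``; derived seeds
    stay below 2**31.
    """
    genome = paper_genome(sites_per_chrom)
    parents = simulate_parents(genome, seed % 2**31)
    schemes = paper_preset_schemes(n_lines, seed=(seed + 1) % 2**31)
    matrix, truth = simulate_cssl_population(
        parents, schemes, n_lines, (seed + 2) % 2**31, require_donor=True
    )
    arch = paper_preset_architecture(genome)
    scc, dtf = simulate_phenotypes(truth, arch, (seed + 3) % 2**31)
    return matrix, truth, arch, scc, dtf


def toy_genome() -> GenomeSpec:
    return GenomeSpec.regular(n_chrom=2, chrom_length=10_000_000, sites_per_chrom=50)


def paper_genome(sites_per_chrom: int = 150) -> GenomeSpec:
    return GenomeSpec.regular(n_chrom=20, chrom_length=45_000_000, sites_per_chrom=sites_per_chrom)
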