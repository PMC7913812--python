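# Methods

`csslkit` implements the analysis chain for a chromosome segment substitution
line (CSSL) panel: a population of near-isogenic lines, each carrying one or a
few donor (wild) genome segments in a recurrent (cultivated) parent
background, genotyped by low-coverage resequencing and phenotyped for one
qualitative trait (seed-coat colour, SCC) and one quantitative trait (days to
flowering, DTF) in a multi-environment trial.  This note documents the models,
the defaults and why they were chosen, and what the synthetic data do and do
not demonstrate.

## 1. Synthetic populations (`simulate`)

**Breeding model.**  Each line descends from an F1 of two fully homozygous
parents, followed by `n_backcross` backcrosses to the recurrent parent and
`n_self` selfing generations.  Meiosis draws a Poisson number of crossovers
per chromosome (mean = `crossover_rate`, in Morgans) with positions uniform on
the physical length — no interference and no genetic map, which is sufficient
to produce the segment-mosaic structure the downstream analysis consumes.
Haplotypes are stored as breakpoint interval lists, so simulation cost does
not grow with SNP density.

Marker-assisted selection is approximated by biased gamete choice: in a
selected backcross generation, two candidate gametes are drawn and the one
with fewer donor SNP sites is kept.  The generic default applies selection in
every backcross; the study-emulating preset applies it in the final two
backcross generations only, mirroring a programme with two rounds of
marker-assisted selection, and uses `crossover_rate = 1.25` M/chromosome
(a ~2500 cM genome over 20 chromosomes).  Under no selection the expected
donor fraction after BC\_n plus selfing is (1/2)^(n+1); the BC3 value of
6.25% is a test oracle.  The preset mixes backcross depths 3/4/5 at
100/49/28 of 177 lines and requires every line to retain at least one donor
segment (a fully recurrent line is not a substitution line); it yields ~96.5%
mean recurrent-genome recovery and ~5 donor segments per line on a 20 x 45 Mb
genome with 150 SNPs per chromosome.

**Observation model.**  Per line x site, read depth ~ Poisson(`depth`); zero
depth gives a missing call; otherwise the call is mis-coded to one of the
other two genotype codes with probability `error_rate` (symmetric mis-call —
real low-depth callers are biased toward the reference allele, but the QC
depth filter makes the distinction immaterial at pipeline level).  Per-site
QUAL and mean depth are emitted for the QC filter.

**Phenotypes.**  SCC follows a two-locus epistatic rule: donor homozygous at
the I locus → black, regardless of the G locus; else donor homozygous at G →
green; else yellow.  Residual heterozygotes are treated as recurrent-like —
the panel is near-fully homozygous, so dominance there is irrelevant.  DTF
for line *l*, environment *e*, replicate *r* is

    y_ler = mu + sum_j a_j x_lj + E_e + eps_ler,   x in {-1, 0, +1}

with fixed environment effects (SD `env_sd` = 1.5 d) and
eps ~ N(0, sigma2_eps).  The residual variance is solved in closed form,
`sigma2_eps = e * r * Var(g) * (1 - h2) / h2`, where Var(g) is the realized
genetic variance; since no genotype-by-environment interaction is simulated,
the expectation of the ANOVA heritability estimator then equals `h2_target`
exactly (verified by parameter recovery).  Default architecture: six QTL with
additive effects (-0.58, +3.68, +2.63, -1.00, -0.72, +2.07) days on six
chromosomes, mu = 53.7 d, h2 = 0.956, 3 environments x 3 replicates.

**Expression and variants.**  Toy single-transcript gene models (1-4 exons,
frame-clean CDS, canonical splice dinucleotides) carry parental 8-tissue FPKM
profiles: causal genes get >= 4-fold differences in >= 3 tissues and FPKM >= 2
somewhere; decoys get sub-2-fold differences or sub-2 FPKM everywhere.
Causal variants are planted by codon arithmetic (e.g. writing a Trp codon and
mutating its third base for a stop gain) — deliberately independent of the
variant classifier, so classifier round-trips are a genuine check.

**What the generator does not emulate.**  Linkage-disequilibrium structure of
an external germplasm panel; reference-biased genotyping errors; segregation
distortion; multi-isoform genes; trait GxE.  Tests passing on these data show
the estimators are correct under the stated model, not that the model captures
every property of a real resequenced panel.

## 2. Segment maps (`segmap`)

**QC.**  Sites are kept when QUAL >= 30, missing fraction <= 0.2 and mean
depth >= 1.5 (all configurable).

**Breakpoint inference.**  Per line and chromosome, non-missing calls are
smoothed by a centred majority vote over `window` = 15 non-missing sites
(ties keep the site's own call — this avoids oscillation), collapsed into
runs, and runs supported by fewer than `min_sites` = 5 sites are absorbed
into the flanking run with more support (shortest run first; ties to the
left).  Breakpoints are placed at the floor midpoint between the last site of
one run and the first of the next; terminal segments extend to the chromosome
ends.  The defaults are chosen for ~3x depth with sub-percent mis-call rates,
where isolated flips are common; at that noise level > 99% of genotyped
genome is assigned its true origin, while noiseless input is reproduced
exactly when smoothing is disabled (`window=1, min_sites=1`).  An all-missing
chromosome is reported as a single no-call segment, not an error.

**SNPLDB markers.**  The union of all lines' breakpoints partitions each
chromosome into blocks within which no line recombines; adjacent blocks whose
per-line code vectors are identical across the whole panel are merged.  Each
block becomes one marker, named `<chrom>_LDB_<k>` in positional order.  This
breakpoint-union definition is equivalent, within the panel, to deriving
linkage-disequilibrium blocks externally and merging them by co-segregation;
an external block boundary set (BED-style intervals) can be supplied to
reproduce a published partition.  Coordinates are 1-based inclusive
internally; BED output is 0-based half-open.  Reported segment length is
`end - start` bp, matching the convention behind printed interval lengths.

**Statistics.**  Per-line recovery % uses recurrent-code marker length over
genome length; donor/heterozygous/no-call percentages are tracked separately
(tiling uses `end - start + 1` so the four shares sum to exactly 100).
Donor-segment statistics count donor-homozygous runs only; heterozygous runs
are genuine segment states but excluded from donor summaries.  Map
comparison counts fine-map donor segments with no coarse overlap ("new"),
coarse segments overlapping k >= 2 fine segments ("broken", k-1 each), and
the coarse donor territory not confirmed by the fine map ("misjudged").

## 3. Co-segregation mapping (`bsa`)

Lines are grouped by phenotype category; each non-reference category is
contrasted pairwise against the reference (recurrent-like) category, with
other categories excluded.  The pairwise design matters under epistasis: a
black line carrying the green allele would otherwise break the green locus's
co-segregation.  For each marker, `n_g` counts donor carriers within the
contrast, `n_pg` carriers of the expected category, and
`C_P&G = n_pg / n_g x 100` (reported to whole percent).  A marker
co-segregates when C = 100% *and* every line of the category carries it.
Heterozygous carriers count as non-carriers (panel heterozygosity is ~0.02%).

## 4. QTL scan (`qtl`)

**Line means and heritability.**  QTL mapping uses per-line means across
environments (environment means first, then their average, so unbalanced
replication does not re-weight environments).  Broad-sense heritability uses
the two-way ANOVA expected-mean-squares estimators

    sigma2_e = MS_err;  sigma2_ge = (MS_GE - MS_err)/r;  sigma2_g = (MS_G - MS_GE)/(e r)
    h2 = sigma2_g / (sigma2_g + sigma2_ge/e + sigma2_e/(e r))

with negative estimates truncated to zero (logged).  A single-environment
table yields the entry-mean h2 without the GxE term, flagged.

**Stepwise cofactors.**  Markers are coded -1/0/+1 (donor = +1), so the
fitted additive effect is half the carrier-vs-noncarrier mean difference.
Identical marker columns are collapsed to their leftmost representative.
Forward steps add the candidate with the smallest partial-F p-value below
`p_in` = 0.05; backward steps drop any selected marker with p above
`p_out` = 0.10.  `max_cof` defaults to `n_lines // 10`: with an order of
magnitude more markers than lines, an uncapped forward pass at p = 0.05
admits spurious cofactors until the residual degrees of freedom collapse,
inflating every downstream LOD (observed ~3x); the cap keeps the background
honest while comfortably exceeding the expected number of true QTL.

**Per-marker LRT.**  For marker m with background B (the cofactors minus
markers collinear with m and minus cofactors within `cof_window` = 10 Mb of m
on the same chromosome):

    LRT = n ln(RSS0 / RSS1),  LOD = LRT / (2 ln 10),
    PVE = 100 (RSS0 - RSS1) / TSS

where RSS0/RSS1 are the residual sums of squares without/with the marker and
TSS is the cofactor-free total sum of squares (a conditional PVE against RSS0
is available by flag).  The window exclusion is the same reasoning as in
composite-interval mapping: a cofactor sitting in a linked adjacent block
shares most of its carriers with the tested marker and would absorb the very
effect under test; 10 Mb covers the panel's typical donor-segment length with
margin.  Perfect fits are reported at a LOD cap of 1e6.  Markers at LOD >=
2.5 are declared; declared markers with identical code vectors merge to the
peak-LOD representative.  No multiple-testing correction is applied beyond
the LOD threshold.  Rare missing marker codes are mean-imputed for the
design matrix.

**Per-line significance.**  Each line's environment x replicate observations
are compared with the recurrent parent's by a two-sided pooled-variance
Student's t-test at alpha = 0.05 (Welch by flag).  A significant line is
"explained" when it carries the donor code at a declared QTL whose effect
sign matches the line's direction.

## 5. Candidate genes (`genes`)

Genes overlap an interval under 1-based inclusive any-overlap (edge contact
counts).  The expression filter removes a gene only when FPKM < 2.0 in every
tissue for both parents (a gene expressed in even one tissue stays); a tissue
is differential when `max(p1,p2) / max(min(p1,p2), 0.01)` exceeds 2.0 — the
0.01 floor handles zero FPKM, and the ratio is direction-agnostic.  Raising
either threshold can only remove genes (monotone).

Variant classification precedence: splice (2 bp at each intron end, strand
aware) > CDS codon change > UTR > intron > promoter > intergenic.  CDS
variants are classified by translating both alleles of the spliced coding
sequence on the coding strand: an earlier stop in the alternate is a stop
gain; a lost stop is a stop loss; otherwise amino-acid difference vs identity
separates missense from synonymous.  The promoter window is 2000 bp upstream
of the transcription start (no standard definition exists; configurable).  A
reference-allele mismatch against the local sequence is a hard error, since
it signals inconsistent inputs.  Only single-transcript models are handled.

Ranking is lexicographic and descending: (expressed, impactful, differential
tissue count, max FPKM), ties broken by gene id.  "Impactful" means any
protein-changing or splice variant, or >= 5 promoter SNPs — a promoter
haplotype can drive an expression difference without touching the CDS.

## 6. Haplotype demonstration (`haplotypes`)

A unit (line or accession) is labelled at a candidate gene from its
diagnostic SNPs: wild only if all match the donor parent, cultivated only if
all match the recurrent parent, missing if any call is absent, otherwise
"other".  Units labelled other/missing at any trait locus are excluded from
contrasts — multiple alleles segregate at these loci in broader germplasm and
would contaminate the background.  The focal contrast compares units wild at
the focal gene and cultivated at every other trait gene against units
cultivated throughout; the background group is therefore identical across
focal genes.  Two-sided pooled-variance Student's t; stars at 0.05/0.01/
0.001; a size-1 group reports means without a p-value; no correction across
genes.  Colour-gene concordance reuses the C_P&G formula on predicted vs
observed categories.

## 7. Numerical and testing choices

- All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give byte-identical outputs, and every derived seed stays below 2^31.
- Least squares uses `numpy.linalg.lstsq`; scan estimates are verified to
  1e-9 against an independent normal-equations oracle on random small
  instances (markers exactly collinear with their background are skipped —
  their coefficient is undefined).
- Acceptance-scale simulations use a 20 x 45 Mb genome with 150 SNPs per
  chromosome and 177 lines; the statistical structure (segment counts,
  carrier frequencies, h2) matches the emulated study while one full
  simulate-map-scan replicate runs in ~1.3 s.
- Parameter recovery is assessed in two parts: planted additive effects by
  joint least squares of line means on the true causal genotype codes (each
  within 3 SE), and localization by requiring a declared marker within one
  block of the truth coordinate or collinear with the block representing the
  causal genotype — the causal position lies between SNP sites, so its
  carrier set may be represented by a collinear twin block.  Draws in which
  a causal locus is monomorphic or nearly so (0-3 carriers) can fail
  detection; this is a power limit of any 177-line panel, not an estimator
  defect.

## 8. Known limitations

- Breakpoint inference is rule-based (majority smoothing + short-run
  absorption), not a hidden-Markov genotype model; at depths well below ~2x
  or error rates of several percent a probabilistic model would do better.
- The LRT scan tests markers only (no between-marker interval positions) and
  fits additive effects only — no dominance or epistasis terms.
- PVE values are marginal (against total variance) and can sum above 100%
  when declared markers are correlated.
- The variant classifier handles biallelic SNPs on single-transcript models;
  indels, MNVs and isoform choice are out of scope.
- Stepwise selection entry/exit thresholds and the cofactor cap are
  heuristics; very closely linked true QTL inside one exclusion window will
  shadow each other.
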