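# Methods

This note documents the models and estimators implemented in `evopot`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical and design decisions that
were genuinely open.

## Genotype substrate and site filters

The analysis substrate is a sites × samples matrix of diploid
alternate-allele dosages (0/1/2, −1 missing) with per-site metadata and
optional per-call depth. Variant positions are 1-based (VCF dialect);
gene intervals are 0-based half-open (BED dialect); the conversion lives
in exactly two functions (`genes.bed_to_pos` / `pos_to_bed`).

Hard filters reproduce the conventional resequencing recipe: genotypes
with depth < 3 are set to missing *before* the missingness test (sites
are never dropped on depth directly — depth is a property of a call, not
a site); sites with more than 25% missing calls are dropped; sites with
minor-allele frequency strictly below 5% are dropped (a site at exactly
5% passes, because the rule is "below"); only biallelic SNVs are kept.
MAF uses non-missing calls as its denominator — the only defensible
choice. The filter is idempotent and is property-tested against a
per-site brute-force oracle.

GATK-style annotation filters (QD, FS, SOR, …) require caller-specific
INFO fields and are out of scope.

## Statistics

**Heterozygosity.** `He = n_het / callable_sites` per individual. The
callable-sites denominator is an explicit parameter: on real data it
should be the genome-wide count of confidently genotyped positions; on a
SNP panel the panel size is the only available choice. The package does
not guess between the two.

**Runs of homozygosity.** A documented simplification of the referenced
PLINK `--homozyg` method: scanning windows of 20 consecutive SNPs qualify
with ≤1 heterozygote and ≤5 missing calls; a SNP in any qualifying window
is "in a run"; consecutive in-run SNPs merge into segments, split where
adjacent SNPs are >1 Mb apart; segments below 100 kb or 20 SNPs are
discarded. The two explicitly configured values are the window size and
length floor; the remaining knobs sit at PLINK defaults. PLINK's
proportion-of-overlapping-windows threshold is not reproduced — on the
planted-tract fixtures the simpler any-qualifying-window rule recovers
every injected ≥100-kb tract exactly. `F_ROH` divides summed segment
lengths by the SNP-covered autosomal length supplied by the caller.

**LD decay.** `r²` is the squared Pearson correlation of genotype dosages
over samples non-missing at both sites (composite LD) — the right
statistic for unphased genotypes; haplotype-EM `r²` is not attempted.
Pairs monomorphic in their shared samples are skipped rather than
propagated as NaN. Under independence the expected `r²` is ≈ 1/n for n
samples (sampling noise floor), which the tests assert.

**Fst.** Weir–Cockerham (1984) per-site variance components `a, b, c`
with the weighted "ratio of sums" estimator `Σa / Σ(a+b+c)` per fixed
50-kb window and genome-wide — the dialect of the standard VCF tooling.
The per-window *unweighted mean of ratios* is a known alternative and is
deliberately not used. Sites with fewer than two called genotypes in
either population, or monomorphic overall, get zero weight.

**D and f4-ratio.** Frequency-based ABBA–BABA on derived-allele
frequencies polarized by a homozygous outgroup (outgroup-polymorphic
sites dropped): per-site `ABBA = (1−p₁)p₂p₃`, `BABA = p₁(1−p₂)p₃`,
`D = Σ(ABBA−BABA)/Σ(ABBA+BABA)`. Z comes from a delete-one
block-jackknife over contiguous blocks of a fixed *site count* (no
genetic map is assumed; physical-distance blocks would be an easy
extension). The f4-ratio uses the standard five-population arrangement:
`f4(A,O;X,C)/f4(A,O;B,C)` estimates the admixed fraction α when
`X = αB′ + (1−α)C′`; the tests build exactly that construction and
recover α = 0, 0.3, 1.0.

## Genetic load

**Polarization.** An allele is ancestral when (i) strictly more than 50%
of ingroup individuals are homozygous for it and (ii) the outgroup is
homozygous for the same allele. "Individuals" means ingroup samples only
— the outgroup is the second, independent criterion, so it cannot also
vote in the majority. Both criteria must agree (the rule conjoins them);
conflicts are unresolved and excluded downstream. When the outgroup call
is missing the majority rule alone decides, flagged as such; a lenient
mode (`require_both=False`) also lets a homozygous outgroup resolve
majority-less sites. Exactly 50% homozygous fails the majority test (the
rule says "more than").

**Effect classes.** The derived allele is substituted into the annotated
codon (strand-aware; the ancestral call orients the substitution, so an
alt-ancestral site is classified as the alt→ref change) and translated:
stop gains are LOF, amino-acid changes missense, silent changes
synonymous. SNVs in the two intronic bases flanking each CDS junction are
splice-disrupting LOF; the two-base rule matches the canonical GT/AG
donor/acceptor positions (intron sequence itself is not available from a
CDS FASTA, so the dinucleotide identity is assumed canonical).
Stop-*loss* changes fall outside the LOF definition (premature stops and
splice SNVs only) and are binned as `noncoding/other`; no Grantham score
exists for a stop. Transcript isoforms, indels and regulatory classes are
out of scope.

**Grantham scores.** The 20×20 distance matrix is embedded as integer
data generated from Grantham's composition/polarity/volume formula,
`D = ρ·[α(Δc)² + β(Δp)² + γ(Δv)²]^½` with α = 1.833, β = 0.1018,
γ = 0.000399 and ρ chosen so the mean over the 190 unordered pairs is
exactly 100, rounded to integers. The tests recompute the formula
independently and require equality on all 190 pairs; spot checks against
commonly tabulated values (C–W 215, I–L 5, R–K 26, D–E 45, A–S 99) agree.
Missense changes with score ≥150 are flagged deleterious.

**Load ratio.** Per sample and class: `2H/(2H+X)` where `H` = derived
homozygous sites (two derived alleles each) and `X` = derived
heterozygous sites (one each). `H = X = 0` is reported as undefined, not
0. Per-lineage summaries are arithmetic means with pairwise Wilcoxon
rank-sum tests (skipped for groups of fewer than two defined ratios).

## Demography

Trajectories are per-generation `Ne` series with generation 0 = present.
The bundled fixtures rebuild the four published lineage reconstructions
from their printed endpoints: 160,753→8,677 from 73 generations ago
(Congo Basin), 41,939→5,069 from 58 (Cameroon & Gabon), 10,473→923
ending 14 generations ago (West Africa), 6,420→5,183 gradual (Nigeria).
Only endpoints and onset timings are published, so interpolation is
linear on the natural scale with `Ne` held constant outside the decline
window. Decline percent is `100(1 − end/start)` rounded to one decimal;
carrying-capacity scenarios take `K = round(fraction × current Ne)`
(round half up, floor 2), with "current `Ne`" the trajectory value at
generation 0.

## The forward simulator

An individual-based, non-Wright–Fisher model with overlapping
generations, one tick = one year = one generation:

1. **Reproduction.** Individuals aged ≥1 shuffle into random pairs
   (selfing excluded); each pair produces a Poisson litter
   (mean 2 — one offspring per parent per year on average, appropriate
   for a species bearing single young annually, and sufficient for the
   density regulation below to hold census at ≈ `w̄K`).
2. **Meiosis.** Crossovers occur at gene boundaries with probability
   10⁻³ per boundary (each boundary standing in for ~100 kb of
   intergenic DNA at an effective 10⁻⁸/bp); chromosomes assort freely,
   implemented as a ½-probability phase flip at each chromosome
   junction; a per-site within-gene rate (default 10⁻⁸) is folded into
   the boundary probability at gene resolution. Genes occupy contiguous
   equal blocks per chromosome — with free inter-chromosome assortment
   and a uniform per-boundary rate this is genetically identical to any
   other even assignment, and contiguous coordinates keep meiosis a pair
   of `searchsorted` calls. New mutations arrive Poisson with the genomic
   rate; each is deleterious with probability 2.31/3.31, drawing
   `s = −Gamma(shape 0.186, mean 0.0131)` (a standard parameterization of the
   human-derived DFE; both knobs are configurable) truncated at −1, with
   `h = 0` if `s < −0.01` else `h = 0.25`; neutral mutations have
   `s = 0, h = ½`.
3. **Viability.** Survival probability `min(1, (w/w_fixed)·K/N)` —
   multiplicative fitness times density regulation, the canonical non-WF
   recipe. Regulation acts on fitness *relative to the fixed-substitution
   baseline* so that accumulated drift load shifts reported fitness
   without collapsing the census (a population does not dwindle to
   nothing merely because every member shares the same fixed mutations).
4. **Catastrophes.** In future projections only, one `Beta(0.5, 8)`
   mortality fraction is drawn per generation and applied as an
   independent death probability per individual (an alternative
   per-individual-draw mode was considered and rejected as
   indistinguishable in expectation but noisier).
5. **Ageing.** Survivors age by one year; there is no explicit maximum
   age — mortality arises from viability and catastrophes only.

Fitness is multiplicative: `(1+s)` per homozygous, `(1+hs)` per
heterozygous deleterious genotype, floored at 10⁻⁶; a homozygous lethal
(`s = −1`) floors immediately. Mutations fixed in every haplotype are
periodically folded into a substitution-load baseline and removed from
genomes (bookkeeping only). Reported fitness comes in two flavours:
absolute (including the fixed baseline) and **segregating**
(baseline divided out). Purging acts on segregating recessive load, so
recovery detection uses the segregating series; both are recorded.

**Wright–Fisher mode.** For theory checks the simulator can force
non-overlapping generations: exactly K offspring per tick, parents drawn
uniformly (or fitness-proportionally when selection is on — the
classical fecundity-selection WF limit), no viability step. In this mode
neutral heterozygosity at standing marker loci decays as
`(1 − 1/(2N))^t`, and semidominant deleterious mutations at fixed `s`
equilibrate at `u/(hs)` per site — both asserted by tests. These closed
forms do *not* hold verbatim in the overlapping-generation cycle, where
an individual is exposed to viability selection every year of its life
(≈ twice per generation of turnover at the default litter size), roughly
doubling the effective selection pressure; the WF mode exists precisely
so the theory comparisons are clean.

**Rescaling.** A factor λ maps `N → N/λ`, `u → uλ`, `r → min(½, rλ)`,
`s → sλ` (dominance assigned from the unscaled `s`), preserving `Nu`,
`Nr`, `Ns`. Scaled runs compress time: dynamics per desk generation
correspond to roughly λ full-scale generations, so desk trajectories are
read qualitatively (orderings, contrasts), not as calendar-year
predictions. Full paper-scale runs (`Ne ≈ 10⁴–10⁵`, 30 Mb of coding
sequence) are cluster work; nothing in the package caps the sizes.

**Inbreeding index.** The population-level index is `F_t = 1 − H_t/H_0`
with `H_0` the mean per-individual heterozygosity (heterozygous mutation
sites / genome length) at projection start, so `F_0 = 0` by construction.
The source analysis does not define its inbreeding metric; this is the
natural drift-anchored choice, and percent changes are computed on it.

**Fitness recovery.** A trajectory "dips" at the first report tick where
segregating fitness falls >1% below its projection-start value; it has
"recovered" at the first tick at or after the dip from which the *mean
over the remaining horizon* is back at or above the start. The tail-mean
criterion means a single noisy tick cannot declare recovery; trajectories
that never dip or never recover are right-censored one report interval
past the horizon, so "no recovery observed" sorts after every observed
recovery. Applied to replicate-mean curves in reports and to individual
replicates in paired-scenario contrasts.

## Study conditions for desk-scale analyses

The heavy checks run at a documented desk scale chosen once:

- Genome: 8 chromosomes × 240 genes × 1,500 bp (360 kb coding) — the
  full architecture divided by ~83, keeping multi-gene linkage blocks.
- Neutral-drift check: K = 200, WF mode, 200 standing markers at
  frequency ½, 25 replicates, horizon 1,000 generations, compared with
  `(1 − 1/(2N))^t` at t = 100/500/1,000.
- Purging contrast: a lineage declining 8,000 → 2,000 over the last 100
  generations (a 75% contraction, within the published lineages' 19–95%
  range), λ = 20 (desk 400 → 100), K scenarios 100% (desk 100) and 25%
  (desk 25), 800 burn-in generations, 1,000-generation horizon, reports
  every 25, catastrophes on, 25 replicate pairs. The burn-in is run once
  and shared: every replicate branches from the same ancestral
  population through its own historical decline and future scenarios.
  Replicates therefore share ancestral standing variation — acceptable
  because the contrast of interest is *within* replicate (paired across
  K scenarios), and the randomness that matters for the pairing
  (contraction, mating, mutation, catastrophes) is replicate-specific.

## What the synthetic data does and does not emulate

The Balding–Nichols generator gives exact analytic control of `F_ST`
(subpopulation frequencies are Beta around the ancestral frequency with
variance `F·p(1−p)`) and free sites — no LD, no site-frequency-spectrum
realism, no sequencing error, no genotype-likelihood uncertainty, none of
the low-coverage structure of real resequencing panels. Passing tests
show the estimators are correct on their own definitions and recover
planted truth; they do not show robustness to alignment artefacts or
coverage-driven biases. Planted ROH tracts are clean homozygous runs;
real ROH boundaries are fuzzier. Trajectory fixtures interpolate printed
endpoints; the full published reconstructions are not public, which is
why simulation checks target qualitative contrasts (orderings between K
scenarios) rather than the printed future-decline percentages.

## Known limitations

- The ROH caller simplifies PLINK's window-hit-proportion logic (see
  above); calls on real low-density panels may differ near segment edges.
- D/f4 blocks are site-count blocks; with strong LD heterogeneity a
  map-based blocking would be preferable.
- The non-WF cycle's effective selection differs from WF by the mean
  lifetime factor; quantitative comparisons with WF-derived theory must
  use the WF mode.
- Cross-λ trajectory comparisons are regime-level only (time compresses
  with λ); per-generation curves at different λ are not superimposable.
- Beneficial mutations, spatial structure and tree-sequence recording are
  not modeled.
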