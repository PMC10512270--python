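# Methods

This note documents the models behind `ploidypaint`, the defaults and
why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for
reproducibility.

## Read-count model

Every analysis consumes per-site biallelic read counts
(reference depth, alternative depth). The simulator draws, per site,

* a total depth from a negative binomial with mean `mean_depth`
  (default 150, a typical whole-thallus Illumina coverage after
  mapping) and dispersion `overdispersion` (default 20; variance
  m + m²/k, giving a realistic spread across the 50–300x coverage
  filter window; `None` degenerates to Poisson);
* an alternative depth, binomial in the total depth with success
  probability f·(1−ε) + (1−f)·ε, where f is the site's true
  alternative-allele fraction and ε the per-base substitution error
  rate (default 0.005, matching the low-frequency floor typical of
  permissive variant calling). Errors are symmetric between the two
  alleles of the pair; error bases to third alleles are ignored, since
  only biallelic records are retained anyway.

At a heterozygous site f = (copies carrying the alternative allele) /
(total copies). Ploidy configurations are expressed as distributions
over alternative-copy counts: diploid {1}, triploid {1, 2} with equal
weight (so the unfolded spectrum has similar 1/3 and 2/3 modes),
tetraploid {1, 2, 3} uniform. Heterokaryons (n + n + n) and 2n + n
chimeras are parameterized by mixing proportions of their component
genotypes (default balanced); with balanced proportions they are
read-count-indistinguishable from euploids of the same copy number,
which is exactly the ambiguity the MAF approach has in principle.

## Site filters

Defaults: biallelic SNPs only, contigs ≥ 100 kbp, no missing data
across the sample set, no repeat overlap, total depth within [50, 300].
The depth rule "above 300x or below 50x" is applied literally — 50 and
300 themselves survive. Coverage bounds are enforced per sample across
the run set (the conservative reading when a published pipeline does
not say). Filters are order-independent in the surviving set; the
removal ledger attributes counts in the fixed order biallelic →
contig length → completeness → repeats → coverage.

## Folded MAF spectra and ploidy calls

Spectra use MAF = min(alt, ref)/(alt + ref), exclude MAF = 0, and are
normalized to unit area. Bin width defaults to 0.02 — fine enough to
separate 1/4 from 1/3 at depth ≥ 50, coarse enough that a 50,000-site
spectrum is smooth.

Classification is template matching, not mixture fitting. A spectrum
with less than `min_peak_mass` (default 0.2) of its probability above
`error_cutoff` (default 0.15) is haploid: the error decay at ε = 0.005
and depth ≥ 50 is confined well below 0.15, while any real
heterozygous mode (lowest template 1/4) lies above it. Otherwise the
maximum-density bin above the cutoff is matched to {1/3} → triploid,
{1/2} → diploid, {1/4, 1/2} → tetraploid within ±0.05; the tetraploid
secondary mode must reach 0.3× the primary density; ties between
templates go to the lower mode, and an unmatched primary mode is
"ambiguous". The deliberate caveat is encoded as behaviour: a
zero-heterozygosity diploid classifies as haploid, because read counts
cannot distinguish them.

## Ancestry painting

The alternative-allele frequency thresholds (> 0.2 "other", < 0.1
"lupina"/error, closed [0.1, 0.2] missing) partition [0, 1]
exhaustively and exclusively. The artificial "other" haplotype takes
the alternative allele at "other" sites, the reference allele at
"lupina" sites, missing elsewhere. Haploid consensus haplotypes take
the majority allele and are masked where the minor-allele fraction
reaches 0.05. Matrix columns must be genotyped in every sample
consensus; the "other" haplotype's own missing cells are kept, which is
why pairwise-complete deletion is used for window distances.

Median tracks tile each contig from coordinate 0 in fixed windows
(7.5 kb genome-wide, 2.5 kb for MAT-region zooms); medians are taken
over classified (non-missing) sites; windows with no usable site or
overlapping a repeat interval are missing; trailing partial windows are
kept and flagged. LOH tracts are maximal runs of ≥ 3 consecutive
non-missing windows with median < 0.1 (toward the reference allele) or
> 0.9 (toward "other"); missing windows break runs. Three windows at
7.5 kb ≈ 22 kb, comfortably below the length of figure-scale LOH tracts
while suppressing single-window noise.

## Window genealogies

Distances are uncorrected p-distances over pairwise-complete columns; a
pair sharing no column is an error that discards the window. NJ
follows the Saitou–Nei Q-criterion with two determinism rules: taxa are
processed in alphabetical order, and Q-ties are broken by the
lexicographically smallest pair of minimum leaf labels; negative branch
lengths are clamped to zero. Consecutive 50-SNP windows per contig;
trailing windows with fewer SNPs are dropped; windows whose
first-to-last SNP span exceeds 10 kb are flagged discarded (the span is
measured SNP-to-SNP, not by genomic footprint). Rooting is on the
branch to the designated outgroup lineage (*L. columbiana* by default);
the sister of a focal haplotype is the leaf set of the other child of
its parent in the rooted orientation, so classification is invariant to
branch-length scaling.

The panel simulator evolves binary alleles on the species topology
(((lupina, rugosa), donor), outgroup) with branch-specific substitution
probabilities scaled by a divergence parameter (default 0.12, giving
clearly resolvable 50-SNP windows). Inside "other" ancestry blocks the
hybrid's non-reference subgenome carries the donor's allele with
private mutations at rate 0.005 — the subgenome is modelled as a
recent, essentially direct copy of the donor lineage, with residual
divergence on the scale of the error floor. Only sites where the
"other" subgenome differs from the reference become variants, the same
conditioning the real SNP set has; note this conditioning enriches
whatever donor-private divergence exists, which is why the rate is kept
small.

## Idiomorph scan

Identity windows slide over alignment columns (100 columns, step 10);
columns gapped in either sequence leave the denominator, and windows
with under half their columns comparable are missing — this reproduces
the visible gap over a long single-sequence indel. The coarse 5'
boundary (first window center below 60% identity after a run above
90%) is refined to the exact column by a two-segment least-squares fit
on the per-column match indicator in the surrounding ±1 window; the
refinement removes the ~quarter-window geometric bias of the
window-center estimate. The 3' boundary is the 3' end of the
single-sequence gap run (≥ 20 columns) nearest the end of the
low-identity region; without an indel the 3' changepoint is refined
symmetrically. Length is reported on the ungapped coordinates of the
first (MAT1-1-like) sequence.

On simulated pairs (flanks at 98.5% identity, a 3,800 bp core at 48%,
a 129 bp indel) the 3' boundary and indel length are recovered exactly
and the 5' boundary typically within a few bp. The realized changepoint
of a stochastic pair can sit a few bases past the drawn boundary when
the core happens to open with matching columns; this is an
identifiability limit of the realized sequence, not estimator error,
so ensemble tests check the median deviation.

## Mating-type statistics

The 1:1 test is the two-sided exact binomial test in the
minimum-likelihood convention, which for the symmetric null p₀ = 0.5
equals the doubled smaller tail capped at 1; hence the most balanced
split of an odd n gives exactly p = 1. Thalli amplifying both
idiomorphs are reported but excluded from n. Display rounding follows
the field's reporting style: one decimal at p ≥ 0.1, two significant
figures in scientific notation below.

The copy-ratio estimator is the mean repeat-masked total depth of sites
in the target interval divided by the genome-wide repeat-masked mean.
At 150x and a few hundred sites in the interval its sampling noise is
well inside the [0.60, 0.73] band expected for a 2/3-dosage region.

## What the simulations do and do not emulate

The generator reproduces the statistical structure the analyses rely
on: binomial allele sampling at realistic overdispersed coverage, the
low-frequency error tail, block-structured ancestry with LOH in either
direction, copy-number dosage as a coverage multiplier, conserved-flank
/ divergent-core idiomorph alignments, and binomial mating-type
samples. It does not emulate mapping bias, paralogy/repeat
misalignment, indel variants, multi-allelic sites, linkage between
error reads, GC-dependent coverage, or contamination by other symbiont
genomes. Passing recovery tests therefore demonstrates correctness of
the inference chain under its own assumptions, not robustness to every
artifact of real metagenome mapping — the conservative missing band and
repeat masking exist precisely because real data violate these
assumptions locally.

## Problem sizes

Tests and the acceptance script use desk-scale inputs chosen to hold
the relevant asymptotics: 10,000–50,000 sites for spectra (mode
standard errors ≪ bin width), ~1 Mbp mosaics at ~5–12 het sites/kb
(hundreds of 7.5 kb windows, dozens to hundreds of 50-SNP trees), and
20-seed ensembles for boundary recovery.
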