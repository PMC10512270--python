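# ploidypaint

Read-count genomics for whole-thallus (metagenomic) sequencing of
lichenized fungi: infer ploidy from folded minor-allele-frequency
spectra, paint the ancestry of a hybrid's subgenomes along the genome,
scan mating-type (MAT) idiomorph alignments for their boundaries, and
test regional mating-type ratios against the 1:1 expectation of regular
sexual reproduction.

The motivating system is the *Letharia* species complex, where a
metagenome mapped to a pure-culture *L. lupina* reference shows a
triploid-like allele-balance signal, mosaic ancestry blocks, tracts of
loss of heterozygosity (LOH), and both MAT idiomorphs at unequal copy
dosage. All analyses run equally on real variant tables (VCF with
allele depths, including the VarScan RD/AD dialect) and on the
package's own truth-annotated simulations.

## What it computes

**Ploidy from allele balance.** For biallelic SNPs with reference depth
$r$ and alternative depth $a$, the folded minor-allele frequency is
$\mathrm{MAF} = \min(a, r)/(a + r) \in [0, 0.5]$. At heterozygous sites
the expected allele balance is (copies carrying the allele)/(total
copies), so the spectrum modes discriminate ploidy classes: 1/2
(diploid), 1/3 (triploid), {1/4, 1/2} (tetraploid), while a haploid
shows only the sequencing-error decay near 0. "Ploidy" is used broadly:
an n + n + n heterokaryon with balanced nuclei is indistinguishable from
a true triploid by read counts, and a fully homozygous higher-ploidy
individual is indistinguishable from a haploid.

**Ancestry painting.** Relative to the reference genotype, a site's
alternative ("other") allele frequency $f = a/(a+r)$ is classified as a
true non-reference subgenome allele ($f > 0.2$), a sequencing error
($f < 0.1$, reference-matching "lupina"), or missing (the conservative
closed band $[0.1, 0.2]$). From the calls the package builds the
artificial "other" haplotype, unfolded allele-frequency spectra
(bimodal at 1/3 and 2/3 for a balanced triploid hybrid), windowed
median-frequency tracks (7.5 kb, or 2.5 kb for MAT-region zooms), and
LOH tract calls.

**Window genealogies.** The haplotype matrix (artificial "other",
reference, and haploid-sample consensus rows) is cut into
non-overlapping 50-SNP windows; each window gets a neighbor-joining
tree of uncorrected p-distances, rooted on an outgroup lineage, and the
sister taxon of the focal haplotypes is recorded. Windows spanning more
than 10 kb are discarded.

**Idiomorph scan.** Sliding identity (100 bp windows, 10 bp steps) along
an aligned MAT1-1/MAT1-2 pair, with boundary calls at the identity
drop-off (refined by a per-column changepoint fit) and at the 3' end of
the diagnostic single-sequence indel.

**Mating-type ratios.** Two-sided exact binomial tests of MAT1-1 :
MAT1-2 counts per region and species, and coverage-based copy-ratio
estimates for intervals such as a MAT idiomorph carried on two of three
chromosome sets.

## Worked example

```python
import ploidypaint as pp

# a triploid-like metagenome: 50,000 heterozygous sites at 150x
table = pp.simulate_read_counts(
    pp.PloidyModel.triploid(), n_sites=50_000, het_fraction=1.0,
    coverage=pp.CoverageModel(mean_depth=150), error=pp.ErrorModel(rate=0.005),
    seed=11,
)
hist = pp.folded_maf(table, bin_width=0.02)
call = pp.classify_ploidy(hist)
print("label:", call.label)
print("modes:", call.modes)

# a heavily skewed regional mating-type sample
(res,) = pp.ratio_report([pp.MatingTypeCounts("Alps", "L. vulpina", 53, 6)])
print(res.n, res.p_display)
```

prints

```
label: triploid
modes: [0.33]
59 1.8e-10
```

i.e. the folded spectrum's dominant non-error mode sits in the bin at
1/3 — the triploid signature — and a 53:6 mating-type split in 59
thalli rejects the 1:1 ratio at p = 1.8e-10, evidence against regular
local sexual reproduction.

A command-line interface mirrors the pipeline stages
(`ploidypaint filter | maf | paint | track | loh | idscan | matratio |
copyratio`); see `ploidypaint --help`.

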