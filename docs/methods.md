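# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `sweepscan`, module by module.

## Synthetic cohorts (`simdata`)

The generator produces the minimal data structure a sweep scan needs:
several diverged populations of unphased diploid genotypes, localized
sweep signatures, and an optional genotype-driven binary phenotype.

**Divergence model.** Each site's ancestral frequency p comes from a
neutral-SFS-like law: the derived-allele count i over a nominal pool of
2N haplotypes is drawn with probability ∝ 1/i, so rare variants dominate
as in real resequencing data. Population frequencies then follow the
Balding–Nichols construction, q ~ Beta(p(1−F)/F, (1−p)(1−F)/F), whose
mean is p and whose between-population variance F·p(1−p) makes the
expected Hudson Fst equal F. This is the simplest generator with an
analytically known differentiation level, which is exactly what the
calibration tests need. Genotypes are Binomial(2, q) per sample —
Hardy–Weinberg within populations, no inbreeding, no LD between sites
(each site's frequencies are drawn independently).

**Sweeps.** A sweep is implanted by displacing the target population's
frequency toward the nearer of {0, 1} so that expected heterozygosity
2q(1−q) is multiplied by (1 − r), r the configured diversity reduction.
This frequency-displacement shortcut produces the two signatures the scan
targets — locally depressed π in the target population and elevated
pairwise Fst — without forward simulation. It does *not* produce linked
haplotype structure, so passing recovery tests demonstrate sensitivity to
the π/Fst signature only, not to LD-based signals (which the scan does not
use).

**Phenotypes.** Causal sites are the sweep's most breed-differentiated
variants: sweep sites ranked by (target-population frequency − highest
other-population frequency), top ones taken. This emulates a locus where
the derived allele rose in one population and drives a near-Mendelian
trait; carrier status then separates cases from controls the way a
horned/polled-type contrast does. A carrier of ≥1 derived causal allele
is a case with probability equal to the penetrance (range [0.5, 1.0]),
otherwise with one minus it; penetrance 1.0 makes labels deterministic
and 0.5 is an exact null.

**Defaults as study conditions.** 20 diploids per population, F = 0.05,
5,000 sites on a 5-Mb chromosome, 200-kb sweeps with reduction 0.8, and
2% of sites/genotypes drawn to fail each hard filter. These are the
conditions at which the test suite and the acceptance script operate —
small enough for a desk run, large enough that a 20-kb window holds ~20
SNPs, matching the per-window information of a dense resequencing scan.

**Determinism.** All randomness flows through one `numpy` Generator
seeded from the config; writing fixtures re-derives auxiliary streams
from the same seed with fixed offsets. Identical configs are
byte-identical on disk.

## Variant handling (`vario`)

Hard filters implement the usual GATK-style expression: a site fails when
QD < 2.0 OR FS > 60.0 OR MQ < 40.0; a genotype with GQ < 20 is set
missing. All inequalities are strict, so boundary values pass. A site
missing any INFO metric fails closed. The SNP-cluster ("window") clause
some callers add to this expression has no defined semantics here and is
deliberately not applied; the filter report records it as unimplemented.

Multi-allelic and non-SNP records are excluded rather than split —
downstream statistics assume biallelic sites — and counted. MAF is
computed over non-missing alleles pooled across all samples; the filter
removes sites strictly below the threshold (a site at exactly 0.05 stays).
Missing genotypes are excluded from every allele-frequency denominator.

Site classification assigns exactly one label with precedence
exonic > UTR > intronic > upstream > downstream > intergenic, with a
1,000-bp flank for the upstream/downstream classes (the conventional
annotator default). UTR here means transcribed gene sequence 5′ of the
first or 3′ of the last CDS base — without explicit exon features, true
UTR introns are not distinguished. Consequence calls rebuild the codon
containing the site from the reference FASTA (reverse-complemented on the
minus strand), substitute the ALT allele, and compare translations under
the standard genetic code; a REF/FASTA mismatch is a hard error naming
the site. Internal coordinates are 0-based half-open; VCF (1-based) and
GFF3 (1-based closed) are converted at the I/O boundary.

## Diversity and differentiation (`diversity`)

Per-site π uses allele-count pair counting, 2n₁(n−n₁)/(n(n−1)), which is
identical to enumerating all unordered haplotype pairs and is unbiased
for 2q(1−q); at least two called alleles are required. π_between at a
site is (n₁ᴬn₀ᴮ + n₀ᴬn₁ᴮ)/(nᴬnᴮ). No additional sample-size correction is
applied on top of pair counting. One consequence worth knowing: for two
*identical* finite samples of n alleles each, Fst is exactly −1/(n−1)
rather than 0 (the estimator is unbiased around zero; the offset vanishes
as n grows). The worked 4+4-haplotype example (Fst = 0.2) and the
Balding–Nichols calibration both pin this convention down.

Windows are [k·step, k·step + size) with trailing partials dropped; a SNP
contributes to every window containing it. Window Fst is
1 − Σπ_within/Σπ_between over the window's sites (ratio of sums — robust
when windows are sparse); the genome-wide value is the same ratio over
all sites, which makes it invariant to how sites are partitioned into
chromosomes. Windows with zero π_between, or zero denominator π for the
ratio, are flagged undefined (NaN), excluded from empirical
distributions, and never selected.

## Sweep selection (`sweep`)

Tail thresholds are nearest-rank quantiles: the right 5% tail of N values
is the top ⌈0.05·N⌉, and the threshold is the smallest selected value —
an attained data value, so reported thresholds look like "Fst > 0.26".
Thresholds are always recomputed from the dataset at hand; thresholds
printed for any particular dataset are properties of that dataset, not
constants of the method. Pooled-genome distributions are used (not
per-chromosome). Selection requires the Fst condition jointly with the
ratio-tail condition (left/right/both), so the selected fraction never
exceeds the tail fraction.

Merging coalesces windows that overlap *or* touch (sliding windows
sharing sequence); genes attach to regions by ≥1-bp overlap in half-open
coordinates. "Shared" regions across comparisons are the maximal
intervals covered by at least one merged region of every comparison —
interval intersection, not exact-coordinate identity, which would be
fragile to window phasing. The full Venn partition (every non-empty
subset of comparisons, with exclusive region-cover and gene counts) is
emitted alongside.

## Population structure (`structure`)

The NJ tree uses the Saitou–Nei Q-matrix agglomeration, hand-implemented
for two reasons: taxa are sorted lexicographically and joins break ties
on the smallest row/column pair, making the output invariant to input
order; and negative branch lengths are clamped to zero. The test suite
cross-checks path distances against an independent NJ implementation.
Distances are allele-sharing distances (1 − mean shared-allele score over
co-typed sites, score ∈ {0, ½, 1}), the standard choice for SNP trees and
robust to missingness; a sample pair with no co-typed site is an error.
Site-bootstrap replicate trees are available (default 100 replicates).

PCA standardizes each site by centring at 2p and dividing by √(2p(1−p))
(the GRM convention of GCTA-style tools), mean-imputes missing dosages,
and eigendecomposes the sample covariance; each component's sign is fixed
so its largest-magnitude coordinate is positive. The MAF filter is
applied first.

## Association and haplotypes (`assoc`)

The per-SNP test is the allelic 2×2 chi-square (1 df, no continuity
correction), switching to Fisher's exact test whenever any expected cell
is below 5; monomorphic sites are skipped; BH adjustment runs across
tested SNPs. Genotype-count tables per status accompany every SNP.
Because the simulated phenotype is driven by *carrier* status (dominant
coding) while the test is allelic, power is maximal when the causal
allele is strongly population-differentiated — which the generator's
causal-site ranking guarantees.

EM haplotype estimation enumerates the 2^k haplotype space (k ≤ 8
enforced). The E-step distributes each multi-heterozygous genotype over
its 2^(h−1) phase resolutions proportionally to current frequency
products; the M-step re-normalizes expected gamete counts. Convergence is
a log-likelihood gain below 10⁻⁸ (cap 2,000 iterations), with 5 restarts
(uniform plus Dirichlet-perturbed) keeping the best likelihood; the
log-likelihood is asserted non-decreasing at every step. Frequencies
below 10⁻³ are reported absent — this defines "identified haplotypes"
when counting haplotypes in a block. Recovery accuracy is assessed
against the *realized* gamete frequencies of each simulated sample rather
than the generating probabilities: at n = 200 the binomial sampling noise
(SE ≈ 0.02 per frequency) would otherwise dominate the EM's own phasing
error, and it is the latter the check is meant to bound.

Pairwise D′ and r² come from two-locus EM frequencies (D = p_AB − p_A·p_B,
D′ = |D|/D_max with the tight frequency bound, r² = D²/(p_A(1−p_A)p_B(1−p_B))).
An LD block is the longest run of consecutive SNPs whose *all* pairwise
r² clear the threshold (default 0.5, ties leftmost) — a deliberately
simple, reproducible rule; confidence-interval block definitions are out
of scope.

## Enrichment (`enrich`)

One-sided hypergeometric over-representation: p = P(X ≥ k) for overlap k
between n candidates and a K-gene pathway in an N-gene universe, BH
adjustment across pathways, significance at q ≤ 0.05 inclusive. The
default universe is all genes of the gene model (overridable); candidates
outside the universe are dropped with a warning. Depletion is not tested.

## Pipeline (`pipeline`, `cli`)

One YAML config drives simulate/load → hard+MAF filters → per-comparison
window statistics → joint-tail selection → regions/genes → shared-region
Venn → NJ/PCA → association (plus LD-block follow-up around the top SNP)
→ enrichment. Defaults: window 20,000 bp, step 5,000 bp, tail 0.05, MAF
0.05, FDR 0.05, flank 1,000 bp — all overridable. Comparison orientation
is explicit: the control population is the ratio numerator, so a sweep in
the case population produces a right-tail ratio signal; both tails can be
requested. Stages log parameters and record counts; `summary.json` holds
every derived threshold and count, and re-running a config reproduces it
exactly.

## Limitations

- The simulator draws sites independently: no recombination maps, no
  background LD, no site-frequency correlation along the chromosome.
  Sweep recovery results therefore speak to the π/Fst signature, not to
  haplotype-based statistics.
- Windowed statistics assume dense, reasonably uniform SNP coverage;
  extremely sparse windows rely on the ratio-of-sums construction but
  still carry few sites.
- The annotator distinguishes UTR from intron only outside the CDS span
  and handles one transcript per gene.
- InDels, SVs and CNVs are out of scope; the VCF reader keeps biallelic
  SNPs only.
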