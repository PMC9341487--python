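# Methods

This note documents the models, conventions and defaults behind `popchar`,
the choices made where several defensible options existed, and what the
synthetic-data tests do and do not demonstrate about real data.

## Genotype representation and QC

Genotypes are dosages of `allele_b` of the MAP/BIM record (0/1/2, −1 =
missing), individuals × SNPs.  All statistics are invariant to this global
orientation choice.  Coordinates are 1-based inclusive (PLINK convention);
only autosomes 1–29 are retained, and non-autosomal or unplaced SNPs are
dropped on read.

QC applies, in fixed order: duplicate position (first occurrence in file
order kept) → call rate (default ≥ 0.90) → MAF (≥ 0.05) → exact
Hardy–Weinberg test (p ≥ 1e−6).  The order changes per-rule removal counts
but not the final SNP set, except for the MAF/HWE interplay; the report
itemizes removals in application order.  For ROH/HER detection the MAF and
HWE filters are switched off (`apply_maf_hwe=False`): pruning rare or
HWE-deviant SNPs would bias homozygosity runs.  The HWE test is the
conditional exact test on heterozygote counts given allele counts,
two-sided by summing outcomes no more probable than the observed one, with
no mid-p correction.

PED text files carry no allele-order metadata, so alleles are assigned
lexicographically on read; dosage round-trip through PED is exact whenever
both alleles are observed at a SNP.  BED/BIM round-trip is exact always
(magic bytes `6c 1b 01`, SNP-major, 2-bit codes 00/01/10/11 = hom-A1 /
missing / het / hom-A2).

## Genomic relationship matrix and PCA

VanRaden's first GRM: `G = ZZ′ / 2Σpᵢ(1−pᵢ)` with `Z = M − 2P`.  Missing
dosages are imputed to `2pᵢ` (centered value 0).  Reference frequencies
default to the sample frequencies of the analysis panel after QC; an
external frequency vector can be supplied.  PCA is the eigendecomposition
of G; variance-explained fractions use eigenvalues clipped at zero, and
scores are eigenvectors scaled by √λ.

## Inbreeding estimators

Four frequency-based estimators share `hᵢ = 2pᵢ(1−pᵢ)`:

* **F_HOM1** `= 1 − O_het/E_het` (method-of-moments excess homozygosity;
  equals PLINK `--het`'s `(O_hom−E_hom)/(m−E_hom)`).  The
  homozygote-vs-heterozygote phrasing is the one that yields negative
  values for outbred individuals, which is the behavior reported for
  freshly admixed populations.
* **F_GRM** per-SNP `(x−2p)²/h − 1` (diagonal of VanRaden's G).
* **F_HOM2** per-SNP `1 − x(2−x)/h`.
* **F_UNI** per-SNP `[x² − (1+2p)x + 2p²]/h` (correlation of uniting
  gametes).

Per-SNP ratios are aggregated as the **mean over the individual's
non-missing SNPs** (GCTA convention) by default; a ratio-of-sums variant is
exposed (`aggregate="sum"`), under which F_GRM equals `diag(G) − 1`
exactly.  Missing genotypes are excluded per individual for these
estimators (not imputed).  F_HOM and F_ROH weigh all SNPs equally while
F_GRM/F_UNI up-weight rare alleles, so the former pair correlates more
tightly with each other than with the latter — a property the test suite
checks qualitatively on synthetic inbred panels.

Pedigree inbreeding is Wright's F = kinship(sire, dam), computed by
memoized recursive kinship (algebraically identical to the tabular additive
relationship matrix, verified against it to 1e−12 in tests).  Cohorts for
ΔF default to birth year (real pedigrees have overlapping generations); a
discrete-generation mode serves simulations.  Animals with unknown parents
contribute F = 0 to cohort means; no phantom-parent grouping is applied.

F_ROH divides an individual's summed ROH length by the SNP-covered
autosomal genome, Σ over chromosomes of (last SNP bp − first SNP bp).
Segment length is `end_bp − start_bp` (not +1) everywhere — fixed by the
convention that published island tables satisfy BP2 − BP1 = Length.  ROH
length classes are left-closed, right-open: <2, 2–4, 4–8, 8–16, >16 Mb,
plus <8/>8 Mb aggregates; class F values sum to the total exactly.

## LD, Ne and gametic-phase consistency

Two-locus haplotype frequencies are estimated from unphased genotypes by EM
over the double-heterozygote ambiguity (tolerance 1e−10, ≤ 200 iterations);
phase is never assumed known.  `D = p(ab) − p(a)p(b)`,
`r² = D²/(p_a q_a p_b q_b)`, `signed_r = sign(D)·√r²`.  The EM fixed point
conserves the observed allele counts, so the likelihood has one free
parameter; tests verify the EM solution against a grid-search maximizer of
the full two-locus multinomial likelihood to 1e−6.

LD decay uses intra-chromosome pairs binned by distance: 10-kb bins to
100 kb, then 100-kb bins to 1 Mb; bins with fewer than 50 pairs are
suppressed from reports.  A per-chromosome pair cap (default 200,000,
seeded subsample) bounds the cost on dense panels.

Ne inversion uses the Sved relation `E[r²] = 1/(α + 4Ne·c)` with f(c) = c:
`Ne(T) = (4c)⁻¹(1/r²_adj − α)`, `T = 1/(2c)`, `c` in Morgans from physical
distance at a constant 1 cM/Mb (configurable; the bovine average).  α = 1
(no mutation) by default, α = 2 available.  The small-sample correction
`r²_adj = r² − 1/(2n)` is optional; bins whose adjusted r² is non-positive
are dropped with a warning.  Alternative mapping functions (Ohta–Kimura)
are deliberately not offered.

Consistency of gametic phase correlates `signed_r` between two panels over
the same SNP pairs per distance bin, after intersecting the panels on
(chrom, pos) and complementing dosages where allele labels are swapped;
pairs undefined in either panel are dropped.  CGP of a panel with itself is
exactly 1 in every reported bin.

## ROH and HER detection

ROH follows the PLINK `--homozyg` scheme: 50-SNP windows slide one SNP at a
time; a window passes with ≤ 1 heterozygous and ≤ 1 missing call
(per-window allowances, PLINK semantics); a SNP is in-run when ≥ 5% of the
windows overlapping it pass.  Maximal in-run stretches are split at
inter-SNP gaps > 1 Mb and filtered on ≥ 30 SNPs, ≥ 500 kb and ≤ 50 kb per
SNP density.  The implementation is vectorized but contract-equivalent to a
brute-force enumerate-every-window oracle (tested on ≤ 200-SNP panels).
Note a detectability condition inherent to window voting: a homozygous
tract shorter than one window flanked by dense heterozygosity produces no
passing window and cannot be called, even if it meets the segment-level
thresholds; on real array data flanks are rarely that heterozygous.

HER uses the consecutive-SNP scan: a run starts at a heterozygous SNP and
grows while it contains ≤ 2 homozygous and ≤ 1 missing calls with gaps
≤ 1 Mb ("two homozygous and one missing allowed" read as maximum
allowances — a minimum would be vacuous); on violation the run closes,
trimmed back to its last heterozygous SNP, and the scan restarts after the
violating SNP (greedy left-to-right, as in the consecutive method of
detectRUNS).  Emitted runs need ≥ 20 SNPs and ≥ 500 kb.  HER classes:
0.5–1, 1–1.5, 1.5–2, >2 Mb.

Islands are maximal stretches of SNPs whose segment incidence (fraction of
individuals covered) reaches a threshold — 0.36 for ROH and 0.10 for HER by
default, both exposed as parameters since such thresholds are partly
conventional.  Island bounds snap to the first/last qualifying SNP; no
gap-merging across sub-threshold SNPs.

## Population structure

Reynolds' distance is the Reynolds–Weir–Cockerham least-squares co-ancestry
θ: per SNP, numerator `(p_A−p_B)²` minus each population's sampling-variance
correction `pq/(2n−1)`, denominator adding the within-population
heterozygosity term; numerators and denominators are summed over SNPs
before the ratio (less noisy than averaging per-SNP ratios) and the result
is clamped at 0.  Neighbor joining is Saitou–Nei with Q-criterion ties
broken by the smallest (row, column) index pair and negative branch lengths
clamped to 0 (noted in the tree object); additive metrics are recovered
exactly, and the topology agrees with an independent NJ implementation on
random matrices.  Region-restricted trees take a (chrom, start, end) filter
before frequency computation.

Ancestry estimation is **supervised**: founder allele frequencies are fixed
(clamped to [1e−6, 1−1e−6]) and each individual's fraction vector q is
fitted by EM on the simplex under the binomial likelihood
`Σⱼ [gⱼ ln pⱼ + (2−gⱼ) ln(1−pⱼ)]`, `pⱼ = Σₖ qₖ f_kj`, until the
improvement falls below 1e−6 (≤ 1,000 iterations).  The likelihood is
monotone non-decreasing per iteration.  Unsupervised K-selection with
cross-validation is out of scope; with duplicate founder columns only the
sum of their fractions is identifiable.

## Synthetic-data generator

Founder breeds follow the Balding–Nichols model: ancestral frequency
p ~ Uniform(0.05, 0.95) per SNP, breed frequency
~ Beta(p(1−F)/F, (1−p)(1−F)/F) with per-breed F_ST against a common
ancestor.  Within-chromosome LD comes from a first-order copying chain: the
latent uniform that thresholds each allele is reused from the previous SNP
with probability `exp(−d/L)` (L = `ld_decay_bp`, default 100 kb in the
pipeline scenario), giving exact Bernoulli(p) marginals and r² decaying
with distance.  This is deliberately not a coalescent simulation: it
reproduces a monotone decay curve and sensible CGP behavior but not a
realistic site-frequency spectrum, recombination hotspots or mutation-drift
equilibrium, so LD-based Ne estimates on synthetic panels are checked for
closed-form consistency, not for matching the generator's census size.

The crossing simulator forms gametes with Haldane-model crossovers
(Poisson crossover count at 1 cM/Mb, uniform positions) and tracks founder
origin per transmitted SNP (segment painting at SNP resolution), expanding
composite founder labels (Canchim → 5/8 Charolais + 3/8 Nellore) at
reporting time.  Expected composite fractions are therefore 13/32
Charolais, 8/32 Caracu, 8/32 Angus, 3/32 Nellore, and realized per-offspring
fractions scatter around them.  The drift-pedigree generator mates
`n_sires` males and `n_dams` females per discrete generation so that
E[ΔF] ≈ 1/(8·n_sires) + 1/(8·n_dams); the founders → generation-1
transition has ΔF = 0 by construction (unrelated base population) and is
excluded as burn-in when estimating realized Ne.

Default scenario sizes (3,000 SNPs on three chromosomes, 50 individuals per
founder breed, 100 composite offspring) were chosen as the smallest scale
at which every stage produces stable, interpretable output; all stages
accept larger panels unchanged.

Planted homozygous segments copy one haplotype over the other in a region
(without stored haplotypes, heterozygous dosages collapse to homozygous
`allele_a`); planted heterozygous segments set dosage 1 and are idempotent.

## What the tests show — and do not

Passing tests demonstrate: exact agreement with brute-force oracles
(pedigree kinship, HWE enumeration, two-locus likelihood, window
enumeration, additive-metric NJ), closed-form inversions recovered to
machine precision, unbiasedness of the inbreeding estimators under a
simulated Hardy–Weinberg null, recovery of planted segments and simulated
parameters within stated tolerances, and end-to-end byte-level determinism
under a fixed seed.  They do not validate array-specific artifacts
(genotyping error, ascertainment bias beyond an ancestral-MAF floor),
overlapping-generation pedigree dynamics, or the behavior of LD statistics
under realistic demography — real-data results should be interpreted with
those limits in mind.
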