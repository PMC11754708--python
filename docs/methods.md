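# Methods

This note documents the models behind each `transpoly` module, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions a user should know
before trusting a result.

## Data model and conventions

Genotypes are diploid alt-allele dosages (0/1/2, `-1` missing) over
biallelic SNPs with 1-based VCF coordinates. Multiallelic or non-SNP
records are skipped on read (counted in `meta['n_skipped']`). All
frequencies are computed over non-missing calls only. Optional per-call
allele depths `(ref_reads, alt_reads)` support the read-depth analyses; a
called genotype with zero total depth is rejected as inconsistent.

Clonal samples are collapsed to multi-locus genotypes (MLGs) by single
linkage on the pairwise genotype-mismatch fraction over jointly called
sites. The default threshold is 0 (exact identity); for panels with
genotyping error a threshold of roughly twice the per-sample error rate
merges clone pairs while keeping distinct genets apart. Each MLG is
represented by its highest-coverage sample, ties broken by input order —
coverage is the natural proxy for call quality.

## Coalescent engine

`simulate` implements a backward-in-time structured coalescent (Hudson
style): per deme, k lineages coalesce at rate k(k−1)/2 in units of 2N
generations; migration moves single lineages at per-lineage rate M/2
(M = 4Nm); scheduled events merge demes (species splits, viewed backward)
or apply admixture pulses. Lineages are integer bitmasks over sampled
haploids, so descendant sets — and therefore site genotypes and truth
tables — are exact. Mutations are infinite-sites: Poisson with rate θ/2
per branch-length unit per locus (θ = 4NμL), assigned unique positions
within the locus. Expectations E[π] = θ and E[S] = θ·a_n at T = 0 are
verified in the test suite, and the two-population spectrum is
cross-checked against an independent coalescent implementation (msprime)
on a small configuration.

Loci carry no intra-locus recombination (each locus is a single
genealogy); `recomb > 0` is rejected rather than approximated. This is
the regime all downstream consumers assume; independent loci play the
role of recombining chromosome segments. The truth table records each
mutation's age (uniform on its branch) and the deme its branch was born
in; with migration active, a branch that moved demes mid-life keeps its
birth deme, so origin labels are exact only for M = 0.

Default per-locus θ = 1 over 1 kb (per-site diversity 0.001) keeps
simulations light; the genotype-level analyses are scale-free in θ. The
recorded defaults μ = 5.69e-9 and recombination 8e-8 per site per
generation are the literature values for the motivating *Daphnia* system
and serve only to translate coalescent units into real time; no analysis
here consumes them directly.

## Site classification

Within each species the alt frequency and call rate are computed over
non-missing calls; sites with call rate < 0.5 in either species are
UNCLASSIFIED. A site is SHARED_POLY when its minor-allele frequency is
≥ `maf_min` (default 0.01) in **both** species — a site polymorphic at
MAF 0.009 in one species is PRIVATE to the other, not shared, because
sub-threshold residual polymorphism is indistinguishable from genotyping
error at panel scale. FIXED_DIFF requires frequency exactly 0 in one
species and 1 in the other over non-missing calls; missingness tolerance
beyond the call-rate floor is deliberately not granted, because a
relaxed fixed-difference definition contaminates the hybrid index.

The hybrid index of a test individual is its heterozygous fraction at
FIXED_DIFF sites of a reference species pair: F1 hybrids ≈ 1, parentals
≈ 0, first-generation backcrosses ≈ 0.5.

## Joint SFS, model comparison, ILS bound

The joint SFS counts sites by alt-allele counts (i, j). Projection to
smaller sample sizes is the hypergeometric expectation applied per axis
(mass-conserving; identical to averaging over all subsamples, which a
Monte-Carlo test verifies). Folding merges (i, j) with its complement
(n_A−i, n_B−j), keeping the lexicographically smaller index. Shared
polymorphisms in a projected spectrum are cells whose **minor** count is
≥ 2 on both axes — for a 20×20 projection this is "frequency above 1/20
in both species", and requiring it on the minor side excludes cells that
are fixed in one species and hence not polymorphisms there.

Model spectra are inputs (from a diffusion solver, a coalescent fit, or
this package's own simulator); the comparison machinery is agnostic.
Residuals default to Pearson (O−E)/√E — the right standardization for
Poisson-distributed SFS counts — with (O−E)/E available as
`mode="relative"`. The composite log-likelihood is Poisson per cell,
Σ O·ln E − E − ln O!, and BIC = −2·loglik + k·ln(n_obs). The absorbing
corner cells (0,0) and (n_A, n_B) carry no polymorphism information and
are excluded from means and likelihoods.

π and D_xy are mean pairwise differences per site over haploid allele
counts; both need the number of *monitored* sites (including invariant
ones) for per-site scaling, and SNP-only input produces explicitly
warned per-SNP averages. For identical panels D_xy equals π up to the
(n−1)/n pairing factor (cross-species pairs include self-comparisons of
the allele pool; within-species pairs do not).

The ILS bound asks how many ancestral polymorphisms could persist in
both species without migration. Writing θ_anc = max(p_A, p_B) for the
ancestral diversity (the conservative choice: the larger extant
diversity), the split age of lineage i in units of its own 2N_i is
τ_i = (d_between − θ_anc)/p_i, since divergence accrues at rate p_i per
2N_i generations per lineage. A neutral polymorphism survives τ
coalescent units with probability exp(−τ) independently per species, so
E[shared] ≤ max(S_A, S_B)·exp(−(τ_A + τ_B)). The persistence exponent is
exposed (`exponent_scale`) for sensitivity analysis. The bound's
validity — coverage of the observed shared count across a grid of split
times, and monotone decrease with divergence — is established against
the package's own neutral simulator in the acceptance suite rather than
assumed.

## Balancing-selection statistics

**α_b** contrasts the NS/Syn ratio of shared polymorphisms with that of
within-species (private) polymorphisms:
α_b = 1 − (Poly_NS·SP_Syn)/(Poly_Syn·SP_NS). Under neutrality the two
ratios match and α_b = 0; balancing selection preserves functional
(non-synonymous) shared variants and pushes α_b above 0. Confidence
intervals and the one-sided p-value come from a percentile bootstrap
over genomic blocks (default 1,000 replicates; blocks resample linked
SNPs together). Degenerate replicates (zero denominator) are redrawn and
counted; p is floored at 1/n_boot. Null calibration (CI covering 0 at
the nominal rate when the two ratios are equal) is tested, not assumed.

**β(1)** scores a core SNP by frequency similarity of its neighbours:
θ̂_β = Σ_i w_i / C with w_i = (1 − |φ_i − φ_core|/0.5)^p (folded
frequencies φ, default exponent p = 2), where C = Σ_k w(φ_k)/k
normalizes by the neutral folded spectrum so that E[θ̂_β] = θ; the score
is θ̂_β − θ̂_W (Watterson). The expectation argument treats sites as
independent — the free-recombination limit. In fully linked windows
(this package's non-recombining loci) shared genealogy alone induces
frequency similarity, so neutral β(1) is positive there; the calibration
test therefore draws frequencies i.i.d. from the 1/k spectrum, and the
balanced-locus test asserts only an *elevation* over background. Exact
parity with any particular reference implementation's constants is not
claimed.

**LD r²** is the squared Pearson correlation of dosage vectors over
jointly non-missing samples; monomorphic members yield NaN (flagged).

## Gene trees and the CPD test

Windows (default 500 bp, inclusive, centred on the focal SNP) are cut
around shared non-synonymous SNPs with MAF > 0.25 in both species, from
phased haplotypes of the 30 highest-coverage individuals per species
(both haplotypes of every chosen individual). Distances are p or JC69
(−¾ ln(1 − 4p/3), undefined at p ≥ 0.75, N sites excluded pairwise);
trees are neighbor-joining with deterministic tie-breaking (first
minimal Q-pair in input order) and negative branch estimates clamped to
0 with the deficit moved to the sister branch, preserving path lengths —
NJ is exact on additive matrices, which the suite verifies via the
cophenetic∘NJ identity. The final two clusters join through a midpoint
root; tip-to-tip path lengths are unaffected. ML tree inference is
intentionally out of scope: only the within/between cophenetic contrast
is consumed, and externally built Newick trees can be supplied for
parity runs.

The CPD statistic is Δ = median(within-species tip-pair path lengths) −
median(between-species pairs); Δ < 0 is the species-tree signature,
Δ > 0 the allele-clustered (trans-specific) signature, Δ = 0 reported as
TIE. Same-individual haplotype pairs count as within-species by default
(flag available). Δ's sign is invariant to uniform branch scaling and to
relabeling within species.

A subtlety worth knowing: with two balanced allelic classes at frequency
~0.5, same-class pairs are a minority of within-species pairs
((m−1)/(2m−1) < ½ for m haplotypes per class) but exactly half of
between-species pairs — this finite-sample asymmetry is what pushes the
within median onto the deep cross-class distances while the between
median stays on the boundary, making Δ reliably positive for genuinely
trans-specific haplotypes but only marginally so when class frequencies
drift far from 0.5; the test is correspondingly conservative.

## Balanced-locus generator

`sim_balanced_trans_locus` builds the fixture the CPD and β tests need:
two haplotype classes joined at `allele_age` (≥ T_split) with species
joining within each class at T_split, within-cell coalescence at
T_split/4, Jukes-Cantor mutations at the split model's per-site θ/2, and
`n_linked_sites` class-diagnostic variants (focal SNP at the window
centre). Class frequencies come from a forward Wright-Fisher trajectory
with symmetric overdominance (fitnesses 1 : 1+s : 1), run (allele_age −
T)·2N generations ancestrally and T·2N in each species, conditioned on
retention. Defaults — s_het = 1.0, N = 5,000 forward individuals,
allele_age = 6 with a fixture split time of 2 coalescent units and
per-site θ = 0.01 — encode the study conditions: a deeply diverged
species pair (d_xy ≫ π) with strong heterozygote advantage at the focal
locus, which holds class frequencies tightly enough near 0.5 that the
finite-sample median asymmetry above resolves the topology reliably.
What the generator does **not** emulate: recombination within the
haplotype (real balanced loci decay into the flanks), selection on
linked sites, gene conversion between classes, and frequency differences
between species beyond independent drift — so passing tests demonstrate
the classifier's behavior under a clean trans-specific architecture, not
its power on eroded or recombining real loci.

## Introgression statistics

Site-frequency ABBA/BABA: D = Σ(ABBA − BABA)/Σ(ABBA + BABA) with
ABBA = (1−p1)p2p3(1−pO), frequencies rather than pseudo-haploid draws
(lower variance, same expectation). Sites with a polymorphic or missing
outgroup are dropped; outgroup-fixed-alt sites are polarized by flipping.
Significance is a delete-one block jackknife (default 1,000-SNP blocks,
≥ 10 blocks required); a constant statistic across blocks reports Z = ∞
rather than failing. The f4-ratio estimates the admixture proportion by
splitting P3 into halves: α̂ = f4(P1,P2;P3a,O)/f4(P1,P3b;P3a,O), the
classic P3-splitting arrangement in which the denominator replaces P2 by
"more P3" as the full-admixture yardstick; splits are seeded and
averaged over 10 redraws. The estimator assumes the admixture pulse is
recent relative to the P3 stem — an older pulse deflates α̂ by roughly
(t_stem − t_adm)/t_stem, visible in the simulations.

## Depth-aware inheritance

A true genotype observed at depth d with per-read error ε yields alt
reads ~ Binomial(d, ε | ½ | 1−ε); a heterozygote is called iff both
alleles appear ≥ `het_call_rule` (default 1) times, otherwise the
majority homozygote; depth 0 and sub-rule ties are missing. The
called-genotype distribution of a cross is the analytic mixture over the
depth distribution of per-depth calling matrices (exact by enumeration),
with a Monte-Carlo path for cross-checking; at fixed depth d without
error a true heterozygote is miscalled with probability 2^(1−d) — 0.25
at depth 3, which is why naive Mendelian expectations are wrong for
low-coverage panels. Heterozygote excess is tested by Pearson chi-square
over the three classes plus an exact binomial test on the heterozygote
count. F_IS = 1 − H_obs/H_exp per SNP (H_exp = 2p(1−p) from sample
frequencies; monomorphic SNPs excluded), averaged per gene without
weights. The null distribution pushes HWE genotypes through the same
depth model: shallow depth shifts the null *positive* (apparent
heterozygote deficit), so a negative empirical F_IS against this null is
a stronger heterozygote-excess signal than against textbook HWE.

## Activity models

Beam-break series are binarized per 5-s interval (≥ 1 break; the
threshold is a flag) after dropping a 60-minute acclimation window —
12 h at 5-s sampling leaves 7,920 intervals — and fitted as weighted
binomial GLMs, Models 1–3 adding Genotype and Light:Genotype to
Light + Clone + Block. Clone and Block are fixed categorical effects for
determinism; because every clone carries one genotype, raw clone dummies
would span the genotype space, so clone enters as within-genotype
sum-to-zero deviation contrasts — the models stay strictly nested,
Genotype stays identifiable, and clone-level variation is absorbed
exactly as a fixed-effect analogue of a random intercept. LRTs use
2Δloglik against chi-square with Δparams df; type-I error at the
interaction test is verified against the binomial band around 0.05 over
500 null simulations. The simulated design (12 clones, 216 individuals,
3 lights × 3 genotypes, ~7,800 intervals) mirrors the assay it emulates;
overdispersion beyond the fitted fixed effects (e.g., autocorrelated
activity bouts within an individual) is not simulated, so real assays
should expect some LRT anticonservatism that these calibrations do not
capture.

## Pipeline and determinism

`run_all` seeds every stage deterministically from the master seed and
writes TSVs with fixed float formatting, so identical configs produce
byte-identical outputs (tested). The report generator renders whatever
stages a bundle contains and marks absent ones explicitly. Default
problem sizes (400 loci × 1 kb, 8 CPD window pairs, 1,000 bootstrap
replicates) complete in well under a minute on one CPU; the acceptance
suite's larger calibrations (200 simulations per grid) are sized to run
in a few minutes.

## Known limitations

- No intra-locus recombination anywhere; loci are exchangeable
  single-genealogy units.
- The ILS bound uses point estimates of π/D_xy; no uncertainty is
  propagated into the bound itself.
- β(1) constants are calibrated by construction + simulation, not
  matched to an external tool's output.
- The CPD pipeline substitutes NJ/JC69 for ML trees; adequate for the
  median within/between contrast, not for branch-support questions.
- Truth-table origin labels are approximate under migration (branch
  birth deme).
- The f4-ratio assumes recent admixture; D's jackknife assumes
  exchangeable blocks.
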