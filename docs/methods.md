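# Methods

`forenpop` implements the statistical core of a forensic MPS
characterization study: converting per-allele read counts into genotype
calls, summarizing marker efficiency with the standard forensic
parameter suite, and placing a study population among references with
distance, informativeness and ordination analyses. This note records
the models, the parameters that matter, and the design choices made
where the field's conventions genuinely diverge.

## Genotype calling from read counts

Calling at one sample-locus operates on the map {candidate allele →
read count} with total depth `D`:

1. **Minimum depth** — no call is attempted below 10× (STRs) or 5×
   (SNPs).
2. **Analytical threshold (AT)** — candidates with count < AT·D are
   dropped as noise. Default 1.5% with the conventional per-locus
   overrides DYS635 3.3%, DYS389II 5%, DYS448 3.3%.
3. **Stutter filter (SF)** — for STRs, a candidate whose repeat number
   is exactly one full unit below a surviving allele and whose count is
   < SF × that parent's count is removed as an n−1 stutter artifact.
   Default SF 0.19 with per-locus overrides supported. Only n−1 stutter
   is modelled: it is the dominant artifact species and the rule set
   carries a single scalar per locus. The parent comparison is per
   allele (a sequence isoallele is its own stutter parent), and "one
   repeat unit" means a repeat-number difference of exactly 1.0, so
   microvariants (9.3 vs 10) are never treated as stutter of an
   integer neighbour.
4. **Interpretation threshold (IT)** — survivors with count < IT·D
   (default 4.5%; overrides DYS635 10%, DYS389II 15%, DYS448 10%) are
   retained in the genotype but flagged for review. Retaining rather
   than dropping preserves the information a reviewer needs; the region
   between AT and IT is by definition the uncertainty band.
5. **Genotype assembly** — diploid loci call 1 survivor as a homozygote
   and 2 as a heterozygote, flagging **intra-locus imbalance** when the
   minor/major count ratio is below IB (0.60 STRs, 0.50 SNPs); more
   than 2 survivors is an ambiguous no-call. Haploid single-copy loci
   call the top survivor (ties broken by higher count, then
   lexicographic allele name), flagging ambiguity if more survive.
   Multi-copy loci (DYS385a-b, DYF387S1) call up to two alleles; a
   single survivor is reported as a duplicated homozygous-like call,
   the standard DYS385 convention.

An imbalance flag does not demote a call to no-call; the rule set
defines IB as a quality flag, and demotion policy is left to the
analyst. Note one subtlety: the final genotype is *not* monotone in AT
— raising AT can drop a third survivor and thereby turn an ambiguous
no-call into a clean two-allele call. The monotone object is the set of
alleles dropped at the AT step, and that is what the property tests
assert.

QC reporting follows the usual accounting: per-locus success rate
(calls / samples × 100), per-locus depth mean and SD, per-sample mean
depth, and grand mean depths per sample, per locus, and per locus per
sample.

## Allele model

STR alleles are plain strings: the repeat number ("14", "9.3"),
optionally followed by an opaque isoallele tag ("14[t2]") marking a
sequence variant of the same length. All sequence-level statistics
depend only on distinctness, so tags are never parsed further;
bracketed ISFG sequence nomenclature is deliberately out of scope.
Collapsing to length strips tags; the diversity gain of sequence over
length typing at a locus is 100·(n_seq − n_len)/n_len. Allele
frequencies divide observed copy counts by observed copies (2n for
diploid and multi-copy loci, n for haploid), excluding missing cells
from the denominator. Outputs round frequencies to 4 decimals; full
precision is kept internally.

## Forensic parameters

For a diploid locus with observed heterozygosity `h` (heterozygotes /
typed individuals), allele frequencies `p_i` and typed count `n`:

- expected heterozygosity (Nei's unbiased): `H_exp = 2n/(2n−1) · (1 − Σp_i²)`
- polymorphism information content: `PIC = 1 − Σp_i² − Σ_{i<j} 2 p_i² p_j²`
- match probability: `PM = Σ (observed genotype frequency)²`, so the
  power of discrimination `PD = 1 − PM` holds exactly by construction
- power of exclusion (single-parent form): `PE = h²(1 − 2hH²)`, `H = 1 − h`
- typical paternity index: `TPI = 1/(2(1 − h))`, undefined at `h = 1`

PM uses observed genotype frequencies rather than HWE expectations;
that is what standard forensic summary software computes and is the
only convention under which the published PD = 1 − PM complements hold.
The PE form above reproduces all three published anchor values (0.2909
at h = 0.6, 0.8410 at h = 83/90, 0.9096 at h = 86/90) to 4 decimals,
which we treat as confirmation of the formula choice. H_exp's unbiased
correction is our choice — summary tools rarely print their estimator —
and is the one assumption here that published tables cannot confirm or
refute without the underlying genotype counts.

Combined values multiply across loci in log space (CPM = ΠPM,
CPD = 1 − CPM, CPE = 1 − Π(1 − PE)) and print the complement form
("1-3.4332e-11") used in forensic reporting; a `fractions.Fraction`
exact product in the tests confirms 12-digit agreement at 94-locus
panel scale.

**Hardy–Weinberg testing.** Biallelic loci use the full Levene
enumeration: conditional on the allele counts, every heterozygote count
of the right parity is assigned its exact probability and the p-value
sums those no more probable than the observed configuration.
Multiallelic loci use the Monte-Carlo exact test: the observed allele
pool is randomly re-paired `n_perm` times (default 100,000, seeded) and
p = (1 + #{log-probability ≤ observed}) / (1 + n_perm). Monomorphic
loci return p = 1. Bonferroni correction flags p < α/L within a
marker-class batch (e.g. the 27 autosomal STRs together), matching
per-class correction practice.

## Haploid statistics

Per-locus gene diversity `GD = n/(n−1) · (1 − Σp_i²)` with `n` the
observed allele copies — identical to the individual count at
single-copy loci in an all-male cohort, which is the only case the
published values exercise. Whole-haplotype statistics over complete
profiles: `PM = Σf_i²`, `HD = n/(n−1) · (1 − PM)`,
`DC = distinct/n`. Multi-copy loci enter the haplotype as a sorted
tuple so DYS385a/b order never affects identity; individuals missing
any locus are excluded from haplotype statistics (haplotype identity is
undefined under missingness) but still count toward per-locus GD.

## Population differentiation

**Nei's D_A** between two populations is one minus the locus-averaged
Bhattacharyya coefficient, `1 − (1/L) Σ_l Σ_i √(x_li y_li)`, over
shared loci with the allele union zero-filled.

**Pairwise R_st** is the stepwise-mutation analogue of F_st, computed
per population pair by AMOVA on squared repeat-number distances
`d²(u,v) = Σ_l (u_l − v_l)²` (multi-copy loci contribute both sorted
copies as separate coordinates). With N pooled haplotypes:
`SSD_total = (1/N) Σ_{i<j} d²`, `SSD_within = Σ_g (1/n_g) Σ_{i<j∈g} d²`,
`σ²_w = SSD_within/(N−2)`, `n_c = N − (n₁²+n₂²)/N`,
`σ²_a = (SSD_among − σ²_w)/n_c`, `R_st = σ²_a/(σ²_a+σ²_w)`. The
self-consistency identity SSD_total = SSD_within + SSD_among is
asserted on every computation, and a brute-force recomputation from the
explicit pairwise-distance matrix agrees to 1e-10 in the tests. Small
negative R_st values (sampling noise around zero differentiation) are
reported as computed and floored at zero only inside MDS, which
requires dissimilarities. Loci with microvariant (non-integer-step)
alleles are excluded per locus with a warning, since the stepwise
distance is undefined for them; an optional permutation p-value
shuffles group labels. Whether reference AMOVA tools include multi-copy
loci at all is not standardized; including both sorted copies is this
package's documented choice.

**Neighbor-joining** follows Saitou–Nei with the Studier–Keppler
Q-criterion. Ties in Q are broken by the lexicographically first label
pair (internal nodes inherit their smallest leaf label), making output
deterministic. Negative limb lengths are clamped to zero with the
deficit moved to the sister branch. The tree is midpoint-rooted for the
rooted presentation — the natural choice when no outgroup is named —
and serialized to Newick with 6-significant-digit branch lengths;
labels containing spaces or underscores are quoted (unquoted
underscores are read as spaces by standard Newick parsers).

## Assignment informativeness and ordination

Rosenberg's `I_n` at a locus over K groups, in nats (natural log,
Rosenberg's convention):
`I_n = Σ_j (−p̄_j ln p̄_j + Σ_i (p_ij/K) ln p_ij)` with `p̄_j` the
unweighted mean frequency and 0·ln 0 = 0; it is 0 for identical groups
and at most ln K. The one-vs-rest contrast pools the complement groups
weighted by chromosome counts — pooled frequencies are then exactly the
frequencies of the merged sample — and applies the K = 2 formula. Both
the all-groups and one-vs-rest contrasts are reported, since published
"intercontinental" values can be read either way.

Population-level PCA is the SVD of the column-centered populations ×
stacked-allele-frequency matrix; individual-level PCA centers (and by
default unit-scales) the minor-allele dosage matrix of biallelic loci,
dropping zero-variance columns with a warning and mean-imputing missing
dosages. Components are oriented so each loading vector's
largest-magnitude entry is positive, making output sign-deterministic.
Classical (Torgerson) MDS floors negative dissimilarities at zero,
double-centers the squared distances, and embeds with the top-k
positive eigenvalues, reducing k with a warning when fewer exist.

## Synthetic cohort generator

The generator produces every input the pipeline consumes, emulating the
study design the analyses assume: one study population of 90 males plus
four references, 27 autosomal STRs, 24 Y-STRs (DYS385a-b and DYF387S1
multi-copy), 7 X-STRs, and 150 biallelic SNPs (94 identity- plus 56
ancestry-informative). It is first-class, tested code — the simplest
models that exercise the statistics under test, with no coalescent
machinery, migration, growth or linkage (all loci independent).

- **SNP structure**: Balding–Nichols — population frequency
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral p drawn uniform
  (0.1, 0.9), with per-population F defaulting to (0.01, 0.02, 0.05,
  0.10, 0.15). Draws are clamped to [1e-6, 1−1e-6] so tables stay
  valid for √- and log-based statistics. Genotypes are sampled under
  HWE (independent allele draws).
- **STR structure**: symmetric single-step SMM. A shared ancestral
  founder haplotype drifts per population for `drift_generations × k`
  generations (k the population's divergence rank, default step 100) —
  this *shared* drift is what creates among-group variance, since
  independent lineages alone cannot — and each individual lineage then
  accumulates Poisson(μg) ±1 steps around its population founder
  (μ = 0.002/locus/generation, g = 200). With the defaults the study
  population's pairwise R_st against the references spans roughly
  0.15–0.4, ordered by divergence rank.
- **Isoalleles**: each length allele at a locus is split into m = 3
  sequence variants with Dirichlet(1) proportions; allele copies sample
  their tag from those proportions.
- **Read counts**: locus depth ~ negative binomial (mean 300,
  dispersion 5, so depth CV ≈ 0.45 — spanning the order-of-magnitude
  spread real panels show without per-locus depth targets);
  heterozygote reads split by a Beta(30,30) balance draw; each STR
  allele diverts Binomial(reads, rate) reads to its n−1 stutter
  product, rate ~ Beta with mean 0.10 and concentration 200 (sd ≈ 2
  percentage points, the tight spread characteristic of a calibrated
  panel, and safely below the 19% filter); stutter of a sequence
  isoallele keeps the parent's tag, since the artifact inherits the
  parent motif minus one repeat. Diverting rather than adding stutter
  reads conserves depth and makes the truth exactly recoverable when
  stutter and noise are switched off — the round-trip oracle the
  calling tests rely on. Spurious noise alleles appear at rate 0.05
  per sample-locus with ~1% of depth, i.e. below the analytical
  threshold except at low depth.
- **Determinism**: one seed per run; every draw comes from a sub-stream
  keyed by (operation, population, locus), so adding loci or
  populations never perturbs earlier draws, and identical configs give
  byte-identical outputs.

What the generator does *not* emulate: linkage disequilibrium, null
alleles, primer-binding-site dropout, n+1 and half-repeat stutter,
sequencing error within reads, and realistic per-locus depth profiles.
Passing tests therefore demonstrate the correctness of the statistical
machinery under its stated assumptions, not the behaviour of any
laboratory assay on real samples.

## Numerical choices

- Combined products and HWE configuration probabilities accumulate in
  log space (`scipy.special.gammaln`); underflow to exactly 0 happens
  only past ~e⁻⁷⁴⁵.
- Distance matrices are validated symmetric to 1e-12 and re-symmetrized
  after file round-trips (writers keep 10 significant digits).
- The R_st denominator σ²_a + σ²_w = 0 (two identical constant groups)
  returns R_st = 0.
- The heterozygote-count enumeration compares log-probabilities with a
  1e-12 slack so ties count as "at most as probable", the conservative
  convention.
- MAF ties at 0.5 report the lexicographically smaller allele;
  monomorphic loci report MAF 0 with a flag and no allele name.

## Problem sizes in the test suite

The default synthetic cohort (5 × 90 males, 208 markers) is used
whole for pipeline and calling tests; statistical oracles run at the
sizes their precision requires (10⁴ SNPs for Balding–Nichols moments,
1,000 replicates of n = 90 for HWE test calibration, 100 random
instances for the R_st brute-force comparison, 2 × 10⁴ permutations
for Monte-Carlo/enumeration agreement). Monte-Carlo HWE defaults to
100,000 permutations in the API; summaries inside tests pass smaller
`n_perm` since only reproducibility and calibration are at stake there.
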