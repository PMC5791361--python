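# Methods

## Model and estimation

All analyses fit the single-trait animal model
`y = Xβ + g + e` with one genetic random effect `g ~ N(0, K σ²g)` and
i.i.d. residuals.  Fixed effects are an intercept plus reference-coded
categorical factors (by default the stock-origin of each fish, wild vs
F1 broodstock descent).  There is one record per genotyped individual,
so the record-to-individual incidence matrix is the identity throughout.

**REML.** With a single random effect the restricted likelihood can be
profiled exactly.  `K = UDU′` rotates the model so the covariance is
diagonal, `diag(dᵢλ + 1)·σ²e` with `λ = σ²g/σ²e`; β̂ and σ̂²e then have
closed forms given λ and the restricted log-likelihood is a smooth
scalar function of `log λ`.  We maximise it on a 49-point grid over
`log λ ∈ [−12, 12]` followed by bounded Brent refinement
(`xatol = 1e-10`, which is far inside the stated `|Δ log L| < 1e-8`
convergence band).  This is exact for the model class, needs one
eigendecomposition per fit, and has no EM/AI iteration to diverge.
Consequences of the parameterisation:

- λ at the lower grid bound is reported as a boundary solution
  (`σ²g = 0`, `converged=True, boundary=True`), not an error;
- a kinship matrix numerically proportional to the identity makes λ
  unidentifiable; this raises `FlatLikelihoodError` rather than
  returning an arbitrary point on a flat profile;
- variance components inherit a floor of `1e-10·var(y)` through the
  λ bounds.

Standard errors come from the inverse average-information matrix of
`(σ²g, σ²e)` evaluated once at the optimum; `se(h²)` follows by the
delta method.

**BLUP and marker effects.** Given variance components, fixed effects
are GLS and breeding values are `ĝ = σ²g K V⁻¹(y − Xβ̂)` with
`V = Kσ²g + Iσ²e` (algebraically Henderson's mixed-model equations;
verified against an explicit dense MME solve to 1e-8 in the tests).
Allele substitution effects are back-solved as `α̂ = φ·W′G⁻¹ĝ`, which
satisfies the reconstruction identity `Wα̂ = ĝ` up to the ridge term.
Phenotypes of unseen genotypes are `ŷ = Xβ̂ + Wα̂` with `W` centered at
the *training* allele frequencies.

**Relationship matrices.** A uses the tabular-method recursion in a
topological order of the pedigree.  G is VanRaden method 1 with
observed (sample) allele frequencies — no base-population frequencies
exist for a single-generation sample — and monomorphic markers are
excluded from both `W` and the normalisation sum `Σ2pq`.  The constant
`φ = 1/Σ2pq` is stored with the matrix, making `Var(g) = Gσ²g`
equivalent to per-locus effects of equal variance `σ²z = φσ²g`.  A
ridge of `1e-6` is added to the diagonal of G at construction so every
downstream solve sees a positive-definite matrix; we deliberately do
not blend G with A, keeping the genomic matrix marker-only.

**Predictive ability.** Reported as the correlation `r(y, ŷ)` divided
by √h².  The denominator defaults to the genomic model's own
pseudo-heritability (per cross-validation run, the mean over training
folds); a parameter substitutes a pedigree h² instead, since either
convention is defensible and they differ.  The metric can exceed 1 for
weakly heritable traits — that is a property of the definition and is
not clamped.  The regression of actual on predicted phenotype supplies
the complementary `R²`, slope and intercept.

## Marker QC choices

- Missingness/MAF filter bounds are strict (`missing < max_missing`,
  `maf > min_maf`), so markers exactly at 10 % missing or MAF 0.05 are
  removed; the missing fraction is computed as a direct count ratio to
  keep the boundary exact in floating point.
- PIC is reported in the codominant (Botstein) form
  `1 − (p² + q²) − 2p²q²` alongside expected heterozygosity `2pq`.  An
  additive-coding index `2pq(1 − 2pq)` is available behind an explicit
  flag; genotyping providers' proprietary "additive PIC" definitions
  vary and no equivalence is claimed.
- LD pruning is greedy left-to-right within sliding windows (defaults
  r² > 0.95, window 50, step 25) with missing dosages mean-imputed for
  the correlation computation only; earlier markers always win, so the
  result is deterministic given marker order.  There is no genetic map
  in this design, so windows are index-based.
- Imputation defaults to the mean-dosage fill (2p̂), which leaves
  per-marker means unchanged and is the natural companion of a
  centered-G construction; a full-sib family-mean fill (falling back to
  2p̂ for wholly missing families) exploits the family structure.
  Post-imputation dosages are real-valued and G construction accepts
  them.

## Cross-validation design

Folds are stratified by sire: within each sire's offspring (shuffled),
members are dealt to the folds in increasing order of current fold
load, ties broken at random.  This guarantees overall fold sizes differ
by at most one (752 → 151/151/150/150/150 at k = 5) *and* that every
paternal half-sib group with ≥ k members appears in every fold.

Per fold, REML and gBLUP are fitted on training individuals only.
Centering frequencies, φ and the allele substitution effects all derive
from training rows; remaining missing calls are completed with training
means.  Validation phenotypes therefore cannot influence their own
predictions (verified by a permutation leakage test).  Variance
components are re-estimated inside each training fold by default; a
flag reuses full-data components, since published workflows are often
ambiguous on this point.  The fold with the largest R² is recorded —
some workflows select that fold's effects for downstream prediction —
but the headline outputs are the pooled out-of-fold metrics, because
best-fold selection is optimistically biased.

## The synthetic-data generator

The generator reproduces the design of the target population, not its
biology:

- **Pedigree.** 16 sires and 31 dams staff 3♂ × 3♀ spawning tanks; 35
  families are distinct sire×dam pairs within tanks, every parent
  producing at least one family.  Family sizes follow a log-normal
  (σ = 0.8) truncated to [3, 108] and rescaled to exactly 752
  offspring.  (A nominal mean of 17 offspring per family is
  inconsistent with 752/35 ≈ 21.5; the generator pins the total, which
  is what every downstream analysis consumes.)
- **Genotypes.** Unlinked biallelic SNPs, founder frequencies uniform
  on [0.05, 0.5] (sample mean MAF ≈ 0.27), Hardy-Weinberg founders,
  Mendelian gene dropping, i.i.d. missingness at 14.8 %.
- **Traits.** Defaults: weight 3.0 ± 0.35 kg (h² = 0.42), fork length
  58.2 ± 2.10 cm (h² = 0.42), condition index 15.0 ± 1.02 (h² = 0.11).
  In marker mode, per-locus effects are `αⱼ ~ N(0, σ²g·φ)` — the gBLUP
  generative model — so realized genetic variance matches `σ²g = h²·sd²`
  in expectation; pedigree mode uses the infinitesimal model (founder
  values `N(0, σ²g)`, mid-parent plus Mendelian sampling).  A
  stock-origin shift of ~0.3 phenotypic SD is applied to F1-descended
  fish, a visible but minor fixed effect.  The condition index is
  simulated as its own trait by default so that its h² is controlled; a
  flag derives it as `10⁶·W/L³` from the simulated weight and length
  instead (the two options trade controlled heritability against
  arithmetic consistency).  Binary traits (skin fluke 4.3 %, deformity
  17.6 % incidence) come from a liability threshold with a modest
  liability h² of 0.10; they are generated for completeness and carry
  no prediction targets.

**What passing tests do and do not show.**  Because loci are unlinked
and effects i.i.d., predictive ability on simulated data reflects how
well G captures realized family relationships.  Real GBS data add
marker–QTL linkage disequilibrium, genotyping error, family-correlated
missingness and selection history, none of which are modelled.
Synthetic cross-validation accuracies are therefore internally valid
benchmarks of the machinery, not forecasts of real-data accuracy, and
published real-data values are never used as numerical targets.

## Problem sizes and determinism

The test suite and the acceptance script run the parameter-recovery
studies at the full design scale (752 offspring, 35 families, 50
replicates) with marker panels of 3,000 SNPs for genomic analyses —
enough for G to resolve the family structure, chosen to keep a full run
in the tens of seconds — and reduced populations (~180 offspring, a few
hundred markers) for distributional properties where the design itself
is not under test.  Every stochastic step takes an explicit seed;
`simulate_dataset` derives per-stage seeds from one master seed, and
identical configuration plus seed reproduces every output bit-for-bit.

## Known limitations

- Single random effect only: no common-environment/maternal full-sib
  effect (available designs rear families communally from birth, where
  such an effect is typically non-significant), no multi-trait REML, no
  genotype-by-environment structures, no Bayesian marker models.
- G is never blended with A (no single-step H matrix).
- The accuracy denominator convention (pseudo vs pedigree h²) changes
  the reported accuracy scale; both are exposed, the default is the
  model's own pseudo-h².
- The A-matrix recursion is quadratic in pedigree size and the REML
  eigendecomposition cubic in the number of phenotyped individuals;
  both are comfortable up to a few thousand animals, which covers the
  intended single-population use.
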