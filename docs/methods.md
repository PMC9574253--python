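# Methods

`ovitherm` implements the complete analysis chain of a heat-tolerance
association study in hot-arid sheep: heat-load and heat-response
phenotyping, SNP-chip quality control, multilocus diversity and
differentiation statistics, population-structure inference, mixed-model
association and SNP-to-gene annotation, together with a synthetic-data
generator that provides ground truth for every stage.

## Heat-stress phenotypes

**THI.** The temperature-humidity index is computed as

    THI = F − 0.55 · (RH/100) · (F − 58),    F = 1.8·DBT + 32

with DBT the dry-bulb temperature in °C and RH the relative humidity in
percent. The grouping of terms matters: this parenthesisation is the one
that reproduces published field-site values for this index family
(Thom/Hahn-type livestock THI). At F = 58 (DBT ≈ 14.4 °C) humidity has
no effect; values above ~72 indicate heat stress in sheep, above ~100
severe stress. THI is reported to one decimal; internal computation is
full precision.

**Derived respirometry traits.** Tidal volume is TV = GV/RR (L/breath,
from minute ventilation GV and respiration rate RR). Metabolic rate uses
the abbreviated Weir equation on open-circuit respirometry measurements,

    MR = 1440 · (3.941·VO2 + 1.106·VCO2) / BW^0.75   [kcal·kg^−0.75·day^−1],

i.e. kcal/min scaled to a day and normalised by metabolic body size.
The Weir coefficient pair is exposed as a configuration point
(`phenotype.WEIR_O2`, `phenotype.WEIR_CO2`) because calorimetric
conventions differ slightly between sources.

**AHTI.** For each of the five parameters RT, ET, RR, TV, MR an animal
scores one point when its rest→stress change is at least twice the rest
standard deviation of that parameter; the sum is the 0–5 animal
heat-tolerance index (0 = most tolerant). Two interpretation choices are
config-exposed and defaulted as follows:

* the rest SD is computed **across animals** (a per-animal SD is not
  computable from a single rest measurement); a supplied per-parameter
  SD can be passed instead, e.g. per-breed baselines;
* the **absolute** change is compared to the threshold, so parameters
  that fall under stress (TV typically does, because RR rises faster
  than GV) can still flag; `signed=True` restores increase-only scoring.

A parameter with zero rest SD flags on any nonzero change, with a logged
warning.

## SNP quality control

Markers are dropped when MAF < 0.01, call rate < 0.90, or the exact
Hardy-Weinberg test gives p < 10⁻⁶ (all three thresholds are arguments).
The HWE test is the conditional exact test on the heterozygote count
given the allele counts, with probabilities built by the standard stable
recurrence from the modal heterozygote count; the two-sided p-value sums
all outcomes no more probable than the observed one (a ≤ comparison with
1e-12 relative slack so ties are included deterministically). An exact
test is used instead of a χ² because the 10⁻⁶ tail is exactly where the
χ² approximation fails at cohort sizes of a few hundred. Each criterion
is evaluated on the full input matrix, so the retained set is
order-independent; removal is *attributed* to the first failing rule in
the order MAF → call rate → HWE purely for reporting. This makes the
filter idempotent and monotone in each threshold, both of which are
tested.

## Diversity and differentiation

**Hexp** is Nei's unbiased gene diversity: per marker
h = N/(N−1)·(1 − p² − q²) with N observed allele copies, averaged over
markers with N ≥ 2.

**Ia / rbarD.** Per locus j and individual pair (a,b) the distance is
d_j = |dosage_a − dosage_b|/2 ∈ {0, ½, 1}; the multilocus distance is
D = Σ_j d_j. With V_O the variance of D over pairs and V_E = Σ_j var(d_j),

    Ia = V_O/V_E − 1,    rbarD = (V_O − V_E) / (2 Σ_{j<k} √(var_j var_k)).

Both have expectation 0 under random mating; rbarD ≤ 1 with equality for
perfectly associated loci. All variances over pairs use the population
(divide-by-N) convention consistently, which makes the duplicated-locus
identity (Ia = rbarD = 1) exact — this identity is the main algebraic
test of the implementation. Missing data are handled pairwise-complete:
a pair missing a genotype at locus j is dropped from that locus's
variance terms, and contributes the locus-mean d to its multilocus D so
pairs with different missingness stay on a comparable scale (identical to
the plain definition on complete data). V_O is computed from pair row
sums, never from an m×m covariance matrix, so memory stays
O(n² + m) with locus chunking.

**Fst.** Pairwise Weir–Cockerham θ between groups, from the per-locus
variance components a (among populations), b (among individuals within
populations) and c (within individuals) for biallelic loci with two
samples of unequal size, including the heterozygosity terms;
θ = Σa / Σ(a+b+c) over loci. Small negative estimates are retained
(property of the estimator; note that duplicating one table into two
"groups" gives θ ≈ −1/(2n̄) rather than exactly 0, since the
among-population variance is then exactly zero rather than its null
expectation). Groups with fewer than two genotyped individuals are
excluded with a warning. The test suite checks the estimator against an
independently coded scalar transcription of the component formulas to
1e-10 and against the generator's drift parameter (±0.02 at n=200,
m=5000).

**NJ tree.** Neighbour joining (Saitou–Nei, Studier–Keppler Q criterion)
over the Fst matrix via scikit-bio, with negative input distances
clamped to zero first and negative branch lengths clamped to zero in the
result; output is an unrooted Newick string.

## Population structure

**PCA** uses Patterson scaling (centre each marker by 2p̂, scale by
√(2p̂(1−p̂)), mean-impute missing) and an SVD of the centred matrix;
percent variance per axis is reported.

**DAPC.** k-means (10 seeded restarts) on retained principal components
for K = 1..K_max, scored by BIC(K) = n·ln(WSS_K/n) + K·ln(n), followed by
linear discriminant axes (at most K−1) on the retained PCs. Retained PCs
default to the number explaining 90% of variance, capped at
n − #groups. Singular within-scatter is handled by a small shrinkage
ridge. **K selection:** this BIC keeps decreasing past the true K
whenever splitting a tight cluster still cuts WSS by more than a
ln(n)/n relative factor, which is the typical desk-scale situation; the
default rule therefore takes the argmin when the BIC curve has an
interior minimum and otherwise the point of maximum curvature (the
elbow practitioners read off such curves). Both pure rules
(`selection="argmin"`, `"elbow"`) remain available.

**Least-squares admixture.** The dosage/2 matrix M is factorised as
M ≈ Q·F with Q rows on the probability simplex and F in [0,1]^{K×m}, by
minimising the squared error over *observed* entries. The solver
alternates projected-gradient sweeps with exact Lipschitz step sizes
(1/L with L = 2λ_max of the relevant Gram matrix); the data term of each
sweep's gradient is hoisted out of the inner loop, so inner iterations
cost O(nK²)/O(K²m). Missing entries are excluded via an EM-style fill
with the current prediction, which majorises the observed-entry
objective; the objective is therefore non-increasing across sweeps (a
tested invariant). Initialisation is a k-means warm start on the leading
singular vectors (cluster indicators softened to 0.9, per-cluster
frequencies for F), deterministic given the seed. Defaults: max_iter
500 sweeps, relative-objective tolerance 1e-7. The tolerance is tighter
than a generic 1e-6 because ancestry rows continue to polarise after
the objective has nearly flattened; stopping at 1e-6 leaves visibly
soft Q rows on unadmixed data.

**Choice of K** uses a masked cross-entropy criterion: a seeded random
5% of observed genotypes is hidden from the fit and scored by the mean
binomial cross-entropy of the hidden dosages against the fitted Q·F
frequencies (clipped to [ε, 1−ε], ε = 1e-6, so the criterion is always
finite); the best K minimises the criterion.

## Mixed-model GWAS

The model is y = Gα + Xβ + Zu + e with Var(u) = σ_g²K, Var(e) = σ_e²I
and K the vanRaden genomic relationship matrix
W·Wᵀ / (2Σ_j p̂_j(1−p̂_j)) on dosages centred by 2p̂ (missing dosages
mean-imputed). Variance components are estimated once on the
marker-free null model by EMMA-style spectral REML: eigendecompose the
kinship projected off the fixed effects (with a +I shift for numerical
stability), profile the restricted likelihood over δ = σ_e²/σ_g² on a
100-point log grid spanning 10⁻⁵..10⁵, then refine the best grid point
by bounded scalar optimisation. Per-marker tests reuse these components
(P3D/EMMAX); each marker's effect is the GLS coefficient after rotating
by V^{-1/2}, tested two-sided against t with n − rank(X) − 1 df.
Covariates default to intercept-only; breed/location factors can be
passed. Exact per-marker REML is available behind a flag. With K = I
the scan reproduces ordinary least squares exactly (tested to 1e-8
against an independent closed form). Monomorphic markers are emitted
with effect 0, p = 1 and a flag.

Significance status follows the raw-p rule of the reference analysis
family: `Sig` when p ≤ 10⁻³ (BH q-values are reported alongside);
`SigLD` when a non-significant marker has p ≤ 2×10⁻³ and composite
dosage r² ≥ 0.8 with a significant marker on the same chromosome within
1 Mb (all three knobs are arguments); otherwise `NS`. Markers without a
physical position are tested but never enter LD pairs or gene
annotation. Manhattan/QQ tables and the genomic inflation factor λ
(median χ² ratio) are produced for plotting; note that testing markers
that themselves built the kinship is slightly conservative
(no leave-one-chromosome-out correction is applied).

Heritability is only weakly identified when the kinship has little
eigenvalue spread (an unstructured cohort of a few hundred): the REML
point estimate of h² is then diffuse even under a pure-noise phenotype.
Calibration tests therefore use structured cohorts, and single-cohort
h² estimates should be read with that caveat.

## Annotation and over-representation

A SNP inside a gene body is assigned that gene; otherwise the nearest
gene with boundary distance strictly less than 10 kbp is assigned with a
`*` suffix, and when several genes fall within the flank the two nearest
are joined by `-` (ties broken by distance then lexicographic id);
otherwise `-`. Over-representation of a gene list against user-supplied
gene sets (GMT) is the one-sided hypergeometric tail P(X ≥ k) with BH
correction across sets — a generic replacement for curated-database
enrichment tools, deliberately free of any bundled annotation database.

## Synthetic data generator

Genotypes follow the Balding–Nichols model: per marker an ancestral
frequency p0 ~ U(0.05, 0.95), per ancestral population k a frequency
from Beta(p0(1−F)/F, (1−p0)(1−F)/F) with F the drift/Fst parameter, so
the generator's differentiation is directly checkable by the package's
own Weir–Cockerham estimator. Ancestry rows are Dirichlet(α); dosages
are Binomial(2, Σ_k q_ik f_kj); entries are masked missing independently.
Markers are assigned uniformly to 26 autosomes with sorted random
positions. Defaults emulate the study conditions: K = 3 populations,
F = 0.05 (within the plausible 0.02–0.1 range for closely related local
breeds; recovery tests use 0.1 where a sharper signal is the point of
the test), α = 0.2 (mostly distinct breeds with some admixture), 2%
missingness, ~200 individuals × 2×10⁴ markers. Breed and location
labels are the argmax ancestry component.

Physiology: rest values are Normal per animal with sheep baselines
(RT 38.8 ± 0.3 °C, ET 35.5 ± 0.6 °C, RR 35 ± 6 /min, GV 7 ± 1.2 L/min,
VO2 0.055 ± 0.008 and VCO2 0.045 ± 0.007 L/min, BW 45 ± 5 kg), and the
stress value is rest + Δ·(1 + s_i) + ε with mean stress changes
Δ = (RT +1.0, ET +2.5, RR +55, GV +5, VO2 +0.020, VCO2 +0.018, BW 0)
chosen to represent exercise under severe heat load, and ε measurement
noise with SD 0.25·|Δ|. The stress-response score s_i is standardized:
a genetic part (causal-SNP effects on centred dosages plus a polygenic
draw with covariance proportional to the realized vanRaden kinship)
rescaled to variance h², plus independent noise of variance 1 − h².
Because the polygenic term is drawn from the realized kinship, the
mixed model's assumptions hold exactly under simulation, which makes
type-I-error checks clean. `simulate_gwas_phenotype` provides the same
construction for a continuous phenotype in AHTI units, used by power
and calibration studies where integer scoring would only coarsen the
signal.

What the generator does **not** emulate: linkage disequilibrium
(markers are independent given ancestry, so LD-status behaviour is only
exercised through constructed duplicate-column fixtures), genotyping
batch effects, pedigree/family structure beyond the polygenic term, and
any environment-by-genotype interaction. Passing tests therefore
demonstrate correctness of the estimators under their own model
assumptions and calibrated behaviour on structured-but-LD-free data,
not performance on a real chip dataset.

## Numerical choices and problem sizes

* All randomness flows from integer seeds through named
  `numpy.random.Generator` instances; no global state.
* Test and acceptance runs use desk-scale cohorts chosen as the
  package's own study sizes: n = 100–300 individuals and m = 500–6000
  markers depending on what the check needs (e.g. Fst recovery at
  n=200/m=5000, structure selection at n=150/m=5000, mixed-model
  calibration at n=200/m≈2300 post-QC, a full-chain run at n=206/m=6000).
* HWE p-values are cached by (het count, rare-allele count, n); REML's
  marker scan caches one spectral decomposition.
* Degenerate inputs are flagged, not silently dropped: all-missing
  markers (call rate 0), monomorphic markers in the scan, zero rest SDs
  in AHTI, groups of one sample in Fst.

## Known limitations

* The PED/MAP round trip is exact only for matrices whose Alt allele is
  the minor allele — PED text does not carry Ref/Alt designations, and
  the reader's documented convention is Alt = minor (ties alphabetical).
* No LOCO correction in the marker scan; λ runs slightly below 1 when
  tested markers built the kinship.
* The admixture factorisation, like all least-squares variants, yields
  slightly softer ancestry rows than binomial-likelihood solvers; Q
  recovery accuracy is ~0.04 MAE at desk scale rather than ~0.01.
* The enrichment test ships no gene-set database; results depend
  entirely on the user-supplied GMT and universe.
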