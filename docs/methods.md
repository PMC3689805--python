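# Methods

This note records the models implemented in `rnaimap`, their
assumptions, the defaults and why, and what the synthetic data do and do
not establish.

## Phenotype statistics

**Induced lethality.** Each assay observation is a plate: `DE` dead
fertilized embryos and `HL` hatched larvae, giving embryonic lethality
`L = DE/(DE+HL)` (undefined on an empty plate, which is an error).
Treatment-specific lethality is isolated against the strain's
empty-vector control plate as `(L_t − L_c)/(1 − L_c)`. The statistic is
1 exactly when the treated brood is fully dead, can be negative on
noisy plates (treated below control), and is undefined when the control
plate is itself fully lethal. Negative values are reported raw but
clamped to 0 before classification, which keeps class labels well
defined without discarding data. When a strain has replicate plate
pairs, induced lethality is computed per pair and the per-pair values
averaged — replicate plates are separate assays, not a pooled count.

**Classification.** F2 classes use raw lethality: full = exactly 1,
high = [0.75, 1), intermediate = [0.25, 0.75), low = [0, 0.25). The
half-open convention is a design choice: the published verbal ranges
overlap at their endpoints, and assigning each boundary to the higher
class partitions [0, 1] so every observation gets exactly one label.
RIAIL classes use induced lethality: full = 1, zero = ≤ 0,
intermediate = strictly between.

**Dominance.** `d = (hybrid − midparent)/|parentA − midparent|`; 0 is
additive, ±1 full dominance. Because the denominator is the distance
from either parent to the midparent, `d` is invariant under swapping
the parent labels. Equal parent means make `d` undefined (error).

## The linked incompatibility segregation model

The F2 expectation model has two loci on one chromosome: a recessive
insensitivity locus (*ppw-1*) and the *zeel-1/peel-1* incompatibility
element 7.47 cM away, deleted in CB4856. Assumptions:

* **Linear cM→r conversion**, r = cM/100 capped at 0.5. At 7.47 cM this
  is the convention that reproduces the published class expectations
  exactly; the Haldane transform (r = 0.0694) does not. The forward
  *simulators* use Haldane per interval — the linear rule is specific
  to this expectation model and is recorded as its inferred convention.
* **Universal toxin deposition**: every gamete of a *peel-1*-carrying
  (heterozygous) parent delivers the toxin, so in an F1 selfing the
  zygote's own *zeel-1* genotype alone determines susceptibility.
* **Penetrance covers death only** (default p = 0.26, an input
  parameter, not estimated here); sublethal toxin effects are ignored.

The computation is exact enumeration: 4 gamete haplotypes at
frequencies (1−r)/2, (1−r)/2, r/2, r/2; 16 ordered gamete pairs;
removal of zeel-CB/CB zygotes with probability p; renormalization over
survivors. Survivors classify as total lethality (any N2 allele at the
insensitivity locus), no lethality (insensitive, zeel homozygous — no
toxin or full rescue in their own broods) or low lethality
(insensitive, zeel heterozygous — own-brood background loss p/4). The
p/4 level is itself run through the F2 thresholds rather than
hard-labelled "low", so a parameterization with p ≥ 1 would relabel the
class intermediate.

The additive extension composes this base with one unlinked recessive
intermediate-loss locus segregating 1/4 homozygous: the base sensitive
class splits 3/4 high : 1/4 intermediate, and all insensitive
survivors form the low-sensitivity class. Single-locus Mendelian
references (dominant → 25% fully sensitive F2, recessive → 75%) are
provided for the rejection comparisons.

**Goodness of fit** is Pearson chi-square with df = merged classes − 1,
no continuity correction, no parameters estimated from the tested
counts. The merge of observed onto model classes
({full→high, high+intermediate→intermediate, low→low}) is an inference
— the published analysis does not state its grouping — and is recorded
as such; it reproduces the published P = 0.94 from the printed counts.

## Synthetic data

No raw plate counts or genotype files are publicly deposited for the
original panels, so the simulators define the package's study
conditions.

**Meiosis** is Haldane/no-interference: a crossover falls independently
in each inter-marker interval with r = (1 − e^(−2d/100))/2. No
crossover interference, no X-hemizygosity, no mutation.

**F2 panels** draw two independent gametes per zygote from the
two-locus haplotype distribution and kill susceptible zygotes with
probability p — the exact sampling counterpart of the analytic model,
which it is tested against (3-SE agreement at n = 10⁶ over a 5×5
parameter grid).

**RIAIL genomes.** Each line runs an independent sib-pair intercross
chain from the F1 base for `g_intercross` generations (default 10,
echoing the advanced-intercross design) and is then fixed by doubling
one final gamete. This is a deliberate simplification of the real
funnel design: it preserves the properties the mapping code relies on —
homozygous mosaic genomes, accumulated recombination, independent lines
with marginal allele frequency exactly 1/2 — while omitting shared
pedigree drift, selection during construction and, in particular, the
segregation distortion that the incompatibility locus imposed on the
real panel. Simulated panels are therefore unselected: a single
recessive major locus splits them ~50/50, not 80/20 as observed in the
real (distorted) panel.

**Assay counts** are binomial with a fixed embryo number per plate
(default 200; a constant rather than a Poisson draw — sufficient for
the variance contracts), background lethality b (default 0.05) and
treated-plate death probability b + (1−b)v, so the induced-lethality
statistic recovers the architecture's rule value v in expectation (the
round trip is verified to 3 SE over 10⁴ lines; the estimator's
nonlinearity in L_c contributes O(1/n_embryos) bias, negligible at 200
embryos). Architecture presets (`ppw1_only`,
`ppw1_additive_modifier`, `epistatic_suppressor`,
`dominant_insensitivity`) encode genotype→lethality rule tables that
mirror the qualitative phenomena of interest: bimodality, an
intermediate class, suppression of a CB-ppw background to near-full
sensitivity, and low lethality on an N2-ppw background. Preset locus
positions (e.g. the major locus at 20 cM on chromosome I of the
synthetic map) are arbitrary fixed choices.

What passing tests show: the estimators and scans behave correctly
under this generative model. What they do not show: robustness to
plate-to-plate technical variation, crossover interference, segregation
distortion in panel construction, or epistasis patterns beyond the
presets.

## Interval mapping

**Genotype posteriors.** Two-genotype RIL model (N2 vs CB homozygote);
heterozygous input calls are treated as missing, matching inbred panel
construction. At each grid position (the union of the 1-cM lattice and
the typed markers, per chromosome) the posterior comes from the nearest
informative flanking markers under a Haldane two-point model, with
P(state change) = r between a flank and the target; missing markers are
skipped to the next informative flank, a single flank is used at
chromosome ends, and individuals with no information sit at 1/2. Marker
positions are taken as given — no RIL map expansion is applied.

**Nonparametric scan.** The Kruskal–Wallis statistic extended with
posterior weights: with midranks Rᵢ, weights wᵢ = P(N2) and group
masses n₁ = Σwᵢ, n₀ = n − n₁,

    H = 12/(n(n+1)) · [ (Σ wᵢRᵢ)²/n₁ + (Σ (1−wᵢ)Rᵢ)²/n₀ ] − 3(n+1)

divided by the standard tie-correction factor; lod = H/(2 ln 10), so
2 ln(10)·lod is asymptotically χ²(1). At fully informative positions
this is exactly the classical tie-corrected Kruskal–Wallis test (tested
against an independent implementation and scipy). Rank-based, hence
invariant under monotone phenotype transformations. A constant
phenotype yields lod 0 by convention (the tie correction degenerates).

**Normal-model scan.** Haley–Knott regression of phenotype on expected
genotype dosage, lod = (n/2) log₁₀(RSS₀/RSS₁), with any covariate
retained in the null design so the lod isolates the dosage term. A
regression-on-dosage formulation was chosen over an EM mixture: for
inbred panels with dense markers the difference is negligible.
Numerical choices: the added regressor is residualized against the null
basis (QR), positions whose residualized dosage norm is ~0 are flagged
collinear and set to lod 0 with a warning, and RSS₁ is floored at
10⁻¹² · RSS₀ so noiseless fits produce large finite lods rather than
infinities.

**Permutations.** Phenotype assignments are permuted jointly against
the intact genome grid; the genome-wide maximum lod per permutation is
recorded and the threshold is the empirical (1−α) quantile (default
α = 0.05, 1000 permutations). Deterministic given the seed. Calibration
is verified at reduced scale: over 200 independent null phenotypes on a
fixed 200-line panel, a 200-permutation threshold is exceeded at a rate
within the binomial 3-SE band of 5%.

**Support intervals.** The 1.5-lod (configurable) interval is the
contiguous grid run around the peak with lod ≥ peak − drop, extended by
one grid point each side and clamped at chromosome ends; a flat peak
chromosome returns the whole chromosome with a warning. Coverage of the
causal position is ≥ 90% over seeded major-effect replicates.

## Problem sizes and defaults

The package's standard demonstration scales, used throughout the tests:
synthetic map of six 50-cM chromosomes with 1-cM markers (306);
500-line panels for scan localization; 1000 permutations for reported
thresholds (200 for the calibration study); 10⁶ simulated F2 for
oracle-equivalence checks; 10⁴ lines for the forward-model round trip.
These are the package's chosen desk-scale study conditions and are
plenty for the 3-SE contracts they support.

## Known limitations

* The incompatibility penetrance is an input, not estimated from cross
  data; likelihood estimation of (r, p) from F2 counts is out of scope.
* The published dominance value for the parental cross (d = 0.982)
  depends on raw per-individual assay values that were never deposited;
  the dominance operation is implemented and tested on arithmetic
  examples only.
* Physical (bp) coordinates, gene-content annotation of intervals and
  multi-QTL models beyond a single covariate scan are out of scope.
* The χ² class merge and the mapping defaults (Haldane posteriors,
  midrank ties, Haley–Knott dosage regression) are this package's
  documented conventions, not claims about how the original analyses
  were configured internally.
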