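# Methods

## Data model

The unit of analysis is a balanced multi-environment trial: `g` genotypes ×
`e` environments × `r` replicate blocks (RCBD), one plot value per
combination and trait. Replicate-level data live in `METDataset` (long
format); every stability model consumes `TraitMeans`, the `g × e` matrix of
cell means with genotype order fixed by first appearance. Marginals
(genotype means, environment means, grand mean) are *always* recomputed from
cells. Printed marginals in published tables are treated as claims:
`validate_means_table` flags any claim differing from the recomputed value
by more than `tol` (default 0.05, matching one-decimal printing) and screens
cells lying more than `k` IQR (default 3) outside their environment column —
the packaged rice tables contain several such typos (a plant-height cell of
18.3 cm where ≈108.3 is implied by the printed row mean; transposed
days-to-maturity column means; a thousand-grain-weight cell inconsistent
with its printed row mean), and the package flags rather than corrects them.

## Descriptive statistics

Quartiles default to linear interpolation at `p(n−1)` (the spreadsheet
"type 7" convention, chosen because trial reports of this kind are produced
in spreadsheets); Tukey hinges are available via `quantile_method`.
Whiskers extend to the most extreme points inside `Q1 − 1.5·IQR` /
`Q3 + 1.5·IQR`; points beyond are labeled outliers. Skewness is the
adjusted Fisher–Pearson estimator `n/((n−1)(n−2))·Σz³`, excess kurtosis the
analogously corrected fourth-moment estimator (spreadsheet SKEW/KURT); raw
moment versions are behind `bias_corrected=False`. Shape labels use a dead
band of ±0.2: within it a distribution is called symmetric/mesokurtic —
values like skew 0.09 / kurtosis 0.18 are shape-indeterminate at n = 26.
Shapiro–Wilk is delegated to `scipy.stats.shapiro` (Royston approximation);
the package contributes the contract (3 ≤ n ≤ 5000, zero-variance guard),
not the internals.

## Combined ANOVA

For balanced data the sums of squares are the textbook marginal-mean forms;
degrees of freedom: Location `e−1`, Variety `g−1`, Location×Rep `e(r−1)`,
Location×Variety `(e−1)(g−1)`, Error `e(g−1)(r−1)`, totalling `ger−1`.
All effects are treated as fixed and every F is tested against the pooled
error MS. This matches the classical MET reporting convention the package
reproduces; a mixed-model analysis would test Location against
Location×Rep and is deliberately out of scope. `LSD = t(1−α/2, df)·√(2·MSE/r)`
with the pooled error df by default (`lsd_df="local"` switches to
`(g−1)(r−1)`); both round to the same published LSDs to within 0.01 and the
source convention is not recoverable. A natural-log transform is exposed
(`log_transform`) for traits failing normality; nothing downstream assumes
it.

## Eberhart–Russell joint regression

`Iⱼ = ȳ·ⱼ − ȳ··` (ΣIⱼ = 0), `Pᵢ = mᵢ − ȳ··` (ΣPᵢ = 0),
`bᵢ = Σⱼ(Yᵢⱼ−mᵢ)Iⱼ/ΣIⱼ²`, residuals `δᵢⱼ`, `ms_dev = Σδ²/(e−2)`.
Algebraic identities tested to machine precision: mean(bᵢ) = 1 and
`Σ(Yᵢⱼ−mᵢ)² = bᵢ²ΣIⱼ² + Σδ²ᵢⱼ` per genotype.

**S²di convention.** Two definitions circulate: the textbook
`ms_dev − s²ₑ/r` (subtracting the error contribution of a mean of `r`
plots) and plain `ms_dev`. The packaged reference tables unambiguously
print plain `ms_dev` (verified numerically on all 26 grain-yield rows), so
`s2di_paper = ms_dev` is the reproduction default and `s2di_textbook` is
computed whenever `error_ms` is supplied. This is the single most
consequential convention choice in the package.

**Tests and calls.** `bᵢ` is tested against 1 (average responsiveness) with
`e−2` df; the deviation F test `ms_dev/(s²ₑ/r)` needs `error_ms`. With
`e = 3` every test has a single deviation df and essentially no power —
results are reported anyway, and classification treats a missing deviation
test as non-significant. The verbal call has deterministic precedence:
`bᵢ < 0` → usable only in poor environments; significant deviation →
unpredictable; significant `bᵢ > 1` → responsive to favorable environments;
significant `bᵢ < 1` → specific (sub-average) response; otherwise stable.
Desirability is the sign of `Pᵢ`. The published tables' significance stars
follow no recoverable convention and are not reproduced.

## AMMI

Interaction residual `Yᵢⱼ − ȳᵢ· − ȳ·ⱼ + ȳ··`, SVD truncated to
`K = min(g−1, e−1)` axes. Scores are reported both as unit loadings and as
`√λ`-scaled scores whose product reconstructs the interaction. Axis signs
are fixed by requiring the environment with the largest |loading| on each
axis to load positively, making output deterministic across LAPACK
backends. No axis-significance tests (Gollob/FR) are computed. The AMMI1
"stable" label uses a configurable |IPCA1| threshold (default 25% of the
score range) — any such threshold is a reading aid, not an inference.

## GGE biplot

The environment-centered matrix (optionally column-standardized; default
off, matching "centering only" practice) is decomposed by SVD; markers are
`U·Λ^f` and `V·Λ^(1−f)`. `f` only moves scale between marker sets — the
rank-2 reconstruction is partition-invariant (tested). Defaults follow
standard GGE practice: symmetric `f = 0.5` for the polygon view, `f = 1`
(genotype-focused) for mean-vs-stability and ideal ranking, `f = 0`
(environment-focused) for environment diagnostics.

*Which-won-where.* Convex hull of genotype markers by the monotone-chain
algorithm (CCW, collinear boundary points dropped); each hull edge
contributes the ray through the origin along its outward normal; the sector
between the normals of a vertex's two edges is exactly that vertex's normal
cone, i.e. the set of directions in which it maximizes the marker inner
product. Sector assignment therefore provably coincides with
argmaxᵢ gᵢ·eⱼ for every environment, the property the tests verify on 200
random biplots; it holds whether or not the origin lies inside the hull.
Environments sharing a sector form a mega-environment.

*AEA views.* The average-environment axis is the unit vector along the mean
environment marker. Projection on it estimates mean performance (Spearman
ρ > 0.9 vs genotype means on rank-2 synthetic data), perpendicular distance
estimates instability; the ideal point sits on the AEA at the maximal
observed projection, and genotypes are ranked by Euclidean distance to it.
Representativeness is the cosine of an environment's angle to the AEA,
discriminating power its vector length. Only rotation-invariant statements
(sector co-membership, argmax identities, lengths, ranks) are asserted in
tests, since biplot orientation is conventional.

## Grain classification

Kernel length 5.0–6.0 mm (closed interval) is medium, above 6.0 long;
L/B ratio strictly above 3.0 is slender, otherwise bold — the published
class table writes the bold column redundantly ("2.0–3.0 or <3.0"), which
collapses to ratio ≤ 3.0. Lengths below 5.0 mm have no published class and
map to `out_of_range` rather than to a guessed label.

## Synthetic generator

`Y_ijk = μ + gᵢ + eⱼ + GEᵢⱼ + εᵢⱼₖ`, ε i.i.d. Gaussian. Low-rank mode draws
interaction factors orthonormal and orthogonal to the constant vector, so
GE rows/columns sum to zero exactly and the AMMI spectrum equals the
configured singular values. Regression mode sets `GEᵢⱼ = (bᵢ−1)eⱼ`, making
the joint-regression model exact with `Iⱼ = eⱼ`; if mean(b) ≠ 1 the
estimable slopes are `bᵢ/mean(b)` (the index absorbs the common scale).
Defaults mirror the packaged rice-yield trial: 26 × 3 × 3, grand mean
8.7 t/ha, genotype SD 0.5, environment SD 0.17, plot error SD 0.28 (error
MS ≈ 0.08), interaction singular values (2.7, 1.1) — the scale of the
fitted AMMI spectrum. What the generator does *not* emulate: spatial field
trends, unbalanced or non-RCBD layouts, non-Gaussian plot error,
genotype-specific error variances. Passing tests therefore certify the
estimators under the stated model, not robustness to field artifacts.

For the slope-recovery study (500 seeds at the trial design with plot SD
0.3) the generator is configured with an explicit environment gradient of
(−2.3, 0.8, 1.4) — the spread observed for days to maturity in the same
trial — rather than the much flatter yield gradient: with ΣIⱼ² ≈ 0.06 the
per-trial slope SE is ≈0.7 and no finite-seed mean-bias bound near 0.05 is
statistically meaningful, whereas with ΣIⱼ² ≈ 7.5 the Monte-Carlo SE of the
500-seed mean is ≈0.003. Recovery at zero noise is exact (1e-9).

## Numerical conventions and problem sizes

All decompositions use LAPACK via `numpy.linalg.svd`; determinism comes
from the sign convention, not from seeding. Exact identities are asserted
at 1e-9–1e-12 relative; statistics matched against printed values use the
printing precision (1.5 units of the last printed digit for marginals,
0.5% relative floored at the printed rounding for regression statistics).
Monte-Carlo checks use 200 biplots (sector oracle), 500 trials (slope
recovery), 2000 trials (F-test size, acceptance band 5% ± 1.5%), and 100
seeds for the Shapiro–Wilk calibration/power properties — sizes chosen so
the full suite runs in well under a minute on one CPU while keeping
Monte-Carlo error far inside each acceptance band.

## Known limitations

* Mean-level inputs carry their printing precision; statistics recomputed
  from 2–3-decimal cells can differ from those computed upstream on
  replicate data (the published Table of moments is one such case and is
  used as classification input only).
* With `e = 3`, deviation-based tests have 1 df; calls based on them are
  labeled low-power by construction, not fixable at the data's design.
* No mixed models, no heterogeneous error variances, no lattice/alpha
  designs, no AMMI axis tests, no Finlay–Wilkinson/Shukla/Wricke indices.
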