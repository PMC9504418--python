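# metstab

Stability analysis for **multi-environment trials (METs)** in plant
breeding: the same set of genotypes is evaluated at several locations under
a randomized complete block design, and the breeder must decide which
genotypes yield well *and* predictably across environments, and which
locations are worth testing in.

`metstab` implements the classical MET toolkit end to end:

* **Descriptive statistics** — five-number/box-plot summaries with the
  1.5·IQR outlier rule, sample skewness/excess kurtosis with
  lepto-/meso-/platykurtic labels, Shapiro–Wilk normality, histograms.
* **Combined RCBD ANOVA** — sources Location, Variety, Location×Rep,
  Location×Variety, Error; per-location CV% and LSD.
* **Eberhart–Russell joint regression** — for genotype *i* with cell means
  *Y·ᵢⱼ* over environments *j* and environmental index
  *Iⱼ = ȳ·ⱼ − ȳ··*:

  *Yᵢⱼ = mᵢ + bᵢ Iⱼ + δᵢⱼ*,  with slope *bᵢ = Σⱼ(Yᵢⱼ − mᵢ)Iⱼ / ΣⱼIⱼ²* and
  deviation mean square *S²dᵢ = Σⱼδ²ᵢⱼ/(e − 2)*; plus the phenotypic index
  *Pᵢ = mᵢ − ȳ··* and a verbal stability call.
* **AMMI** — additive main effects plus SVD of the doubly-centered
  interaction, IPCA scores and the AMMI1 biplot coordinates.
* **GGE biplot geometry** — rank-2 SVD of the environment-centered matrix
  with which-won-where polygon/sectors and mega-environment grouping,
  mean-vs-stability projections on the average-environment axis,
  discriminativeness-vs-representativeness diagnostics, and ideal-genotype
  ranking.
* **SES grain-shape classification** from kernel length and L/B ratio.
* **A synthetic MET generator** (additive, low-rank-interaction and
  joint-regression modes) for testing and parameter-recovery studies.

A reference dataset ships with the package: the published cell means of a
trial of 26 rice hybrids at three Bangladeshi locations (Barisal, Gazipur,
Ishwardi; Boro season, three replicates), one table per trait, including
the published marginal statistics — kept verbatim, typos and all, because
`validate_means_table` treats printed marginals as claims to verify.

## Worked example

```python
from metstab import datasets, joint_regression, fit_gge, rank_by_ideal

means = datasets.load_trait_means("grain_yield")   # 26 x 3 cell means, t/ha
for r in joint_regression(means)[:2]:
    print(f"{r.genotype:22s} mean={r.mean:.3f} Pi={r.pi:+.3f} "
          f"bi={r.bi:.3f} S2di={r.s2di_paper:.2f} call={r.call.label}")

model = fit_gge(means)
print(f"first two axes explain {100 * model.explained_2d:.2f}% of G+GE")
best = rank_by_ideal(model)
print("closest to ideal:", best.genotypes[list(best.rank).index(1)])
```

prints

```
BRRI35A x BRRI36R      mean=8.075 Pi=-0.614 bi=1.715 S2di=0.01 call=stable
BRRI99A x BRRI36R      mean=9.215 Pi=+0.526 bi=4.243 S2di=0.23 call=stable
first two axes explain 96.20% of G+GE
closest to ideal: BRRI hybrid dhan5
```

The first hybrid responds more than averagely to better environments
(*b* ≈ 1.7) but deviates little from its regression line (*S²d* ≈ 0.01), so
its performance is predictable; its negative *Pᵢ* marks below-average yield.
The rank-2 biplot captures 96.2% of genotype + interaction variation, so
its geometry (sectors, rankings) is a faithful summary; the released check
variety BRRI hybrid dhan5 sits closest to the ideal point (high mean, low
instability).

The same analyses are available from the shell:

```sh
metstab er packaged --trait grain_yield        # joint-regression table
metstab gge packaged --trait grain_yield       # sectors + ideal ranking
metstab run-all --packaged --out report/       # full per-trait report bundle
metstab simulate --seed 7 --out trial.csv      # synthetic balanced trial
```

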