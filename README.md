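# mixpop

Gaussian-mixture deconvolution of a gene's expression distribution across a
tumor cohort, with survival and treatment-response stratification of the
resulting sub-populations.

## The problem

Some genes — the motivating case is *NAT1* (arylamine N-acetyltransferase 1)
in breast cancer — are not unimodally expressed across a patient population.
Their log2 mRNA distribution decomposes into distinct low, intermediate and
high expresser sub-populations, suggesting separate regulatory mechanisms and,
clinically, different outcomes. `mixpop` is a pipeline for analysts who want
to ask, for an index gene in a genes × patients expression matrix plus a
clinical table:

1. Is the distribution a mixture? (Probit diagnostics, a Lilliefors-type
   Kolmogorov–Smirnov normality test, and nonlinear fits of 1–3 Gaussians to
   the binned frequency distribution.)
2. Who belongs to which sub-population, and how many patients does a hard
   cut-off window misassign given the overlap of the fitted components?
3. Which genes co-express with the index gene *within* each sub-population
   (Pearson screen, Bonferroni-controlled, summarised as a three-way Venn
   partition)?
4. Do the sub-populations differ in overall survival? (Kaplan–Meier curves,
   Mantel–Cox and Gehan–Breslow–Wilcoxon log-rank tests, log-rank test for
   trend, at-risk tables — implemented from first principles.)
5. Does low expression predict chemo-resistance? (Resistant/sensitive
   classification at the 5-year boundary with the standard exclusion rules,
   ANOVA/trend across survival-time bins, and a sensitivity/specificity
   decision curve with its cross-over point.)

A synthetic-cohort generator with the same statistical structure (trimodal
index gene, sub-population-specific co-expression blocks, an "absent gene"
background, ER-status linkage, treatment arms, and survival whose hazard
depends on expression only in the chemotherapy arm) makes every stage
testable without access to cohort databases.

## The model

Log2 expression values are binned at width Δ = 0.2 and the bin counts y(x)
at bin centres x are fitted by unweighted nonlinear least squares to a sum
of n = 1…3 Gaussian curves

    y(x) = Σᵢ Aᵢ · exp( −½ ((x − x̄ᵢ)/SDᵢ)² )

with amplitude Aᵢ (counts at peak), mean x̄ᵢ and standard deviation SDᵢ in
log2 units. The area under component i,

    AUCᵢ = Aᵢ · SDᵢ · √(2π),

is proportional to the number of patients in sub-population i; normalized
AUCs are the sub-population weights. Fits are multi-start (quantile-seeded
means with seeded jitter) and count as converged when at least two starts
agree to a relative tolerance of 10⁻³; the number of components is chosen by
small-sample AIC on the Poisson likelihood of the bin counts. Fit quality is
reported as the Pearson correlation between observed and predicted counts
and the residual standard deviation Sy.x = √(SS_res/(n_bins − 3n)).

Patients are assigned by closed cut-off windows (defaults 5–6.5, 7.25–8.5,
10–13 log2 units); the expected percentage of window occupants originating
from the wrong component follows from the normal CDF. Survival uses the
product-limit estimator and weighted log-rank statistics; the decision curve
reports sensitivity(c) = P(value < c | resistant) and specificity(c) =
P(value ≥ c | sensitive) over a cut-off grid, with the cross-over located by
linear interpolation.

## Worked example

Run the whole pipeline on a default synthetic cohort (n = 1980 patients,
302 genes):

```python
from mixpop import PipelineConfig, SyntheticConfig, run_pipeline

summary = run_pipeline(
    PipelineConfig(synthetic=SyntheticConfig(seed=1), seed=1, output_dir="out")
)
print(open("out/summary.txt").read())
```

prints (seed 1):

```
Fitted sub-populations (amplitude, mean, SD, % of patients):
  A=113.3  mean=6.28  sd=0.45  32%
  A=55.0  mean=8.07  sd=0.89  31%
  A=68.1  mean=10.56  sd=0.85  37%
  r(obs,pred)=0.9823  Sy.x=6.50  K-S D=0.1107 (p=6.38e-66)

Co-expression Venn regions: {'low_only': 50, 'intermediate_only': 0,
  'high_only': 50, 'low_intermediate': 0, 'low_high': 0,
  'intermediate_high': 0, 'all_three': 0}
logrank_mantel_cox: chi2=1.159 p=0.56
logrank_trend: chi2=0.381 p=0.537
gehan_breslow_wilcoxon: chi2=0.823 p=0.663
decision curve crossover: cutoff=7.84 sens=spec=0.65
```

Reading this: the three-component fit recovers the generator's trimodal
structure (true means 6.25/7.89/10.58) with observed-vs-predicted
correlation 0.98, and the K-S test soundly rejects a single normal. The
screen recovers exactly the 50-gene block wired to the low sub-population
and the 50-gene block wired to the high one, with nothing shared. Overall
survival pooled across treatment arms barely separates — by construction
expression affects the hazard only in the chemotherapy arm (≈20% of
patients) — while the chemo-arm decision curve is clearly informative: a
low-expression cut-off at 7.84 log2 units identifies treatment-resistant
patients with sensitivity = specificity ≈ 0.65.

The same stages are scriptable from a shell via the `mixpop` command
(`mixpop simulate`, `mixpop fit`, `mixpop assign`, `mixpop coexpress`,
`mixpop survival`, `mixpop response`, `mixpop run --config cfg.yaml`); each
stage reads and writes plain TSV so real cohort exports can be substituted
for the simulator at any point.

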