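# metabomr

Metabolome-wide two-sample Mendelian randomization (MR) for
reproductive-timing outcomes: a tested pipeline covering instrument
selection, causal-effect estimation, pleiotropy and directionality
diagnostics, multivariable BMI adjustment, Bayesian colocalization,
metabolite-set enrichment, and observational cohort validation — with a
seeded synthetic-data generator that emulates the statistical structure
of metabolite and outcome GWAS so every stage can be exercised and
calibrated without access-controlled data.

## The scientific problem

Do circulating metabolites causally shift the timing of menarche and
of natural menopause?  Observational associations are confounded by
lifestyle and prone to reverse causation.  Two-sample MR sidesteps
both by using genetic variants as instruments: for metabolite *X* with
instruments *g₁…g_k*, per-SNP effects on the exposure (β̂ₓ, SD per
allele) from a metabolite GWAS are combined with effects on the
outcome (β̂_y, years per allele) from an independent reproductive-aging
GWAS.  Each SNP's Wald ratio β̂_y/β̂ₓ estimates the causal effect θ
(years per SD of metabolite), and the inverse-variance-weighted (IVW)
meta-analysis

θ̂ = Σ wⱼ β̂ₓⱼ β̂_yⱼ / Σ wⱼ β̂ₓⱼ², wⱼ = 1/se(β̂_yⱼ)²

pools them — equivalently, weighted regression of β̂_y on β̂ₓ through
the origin.  Validity rests on relevance (enforced by P ≤ 5×10⁻⁸
selection, LD clumping at r² < 0.001 within ±500 kb, and a global
F ≥ 10 filter with R² ≈ 2β²f(1−f)), independence (probed by
multivariable MR with BMI), and exclusion restriction (probed by the
MR-Egger intercept, the MR-PRESSO residual-sum-of-squares test,
Cochran's Q, weighted-median/mode estimators, Steiger directionality
filtering and bidirectional MR).  Colocalization with approximate
Bayes factors separates truly shared causal variants (PP(H4) > 0.8)
from LD neighbours, and hypergeometric over-representation plus cohort
regressions close the loop.

Intended users: genetic epidemiologists who want a self-contained,
deterministic implementation of this study design whose statistical
operating characteristics (bias, coverage, test sizes, detection
power) are themselves under test.

## Worked example

The numbered scripts under `analysis/` reproduce a full synthetic
study (50 metabolites, 5 truly causal at θ = 0.25 years/SD, exposure
n = 24,925, outcome n = 201,323, block-AR(1) LD panel):

```bash
python analysis/01_simulate_study.py --seed 0
python analysis/02_select_instruments.py
python analysis/03_estimate_mr.py
python analysis/04_sensitivity.py
python analysis/05_mvmr_bmi.py
python analysis/06_colocalization.py
python analysis/07_reverse_mr.py
python analysis/08_enrichment_validation.py
```

At seed 0 the funnel prints:

```
50 exposures -> 50 with genome-wide instruments -> 50 passing F >= 10
tested 50 metabolites against the outcome (6 instruments entered via LD proxies)
prioritized at FDR <= 0.05: 5 metabolites
metabolite  estimate      se         p     fdr_q  nsnp
 metab_001     0.232 0.00591 4.94e-324 2.47e-322     4
 metab_000     0.249 0.00687 9.81e-287 2.45e-285     5
 ...
colocalized (max PP4 > 0.8): 5 -> ['metab_000', ..., 'metab_004']
reverse IVW p < 0.05 for 0/5 (evidence of outcome -> metabolite effects)
```

All five causal metabolites are recovered with IVW estimates within a
few SEs of the true 0.25 years/SD, every one colocalizes with the
outcome at its instrument loci, reverse MR finds no outcome→metabolite
effect, the enrichment stage flags the annotation class holding the
causal metabolites (p = 4.7×10⁻⁷), and the cohort regression recovers
the metabolite/age association with and without BMI adjustment and the
early-menopause (< 45 y) exclusion.  Tables land under
`results/study/`.

The same machinery is importable directly:

```python
from metabomr import StudyConfig, simulate_study, run_pipeline
bundle = run_pipeline(StudyConfig(seed=1), simulate_study(seed=1))
print(bundle.manifest["counts"])
```

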