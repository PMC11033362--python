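# targetmr

Drug-target Mendelian randomisation (MR) from GWAS summary statistics.

`targetmr` is for epidemiologists and computational biologists who want to
screen drug repositioning candidates genetically: if variants near the gene
encoding a drug's protein target shift both the target's activity and a
disease's risk proportionally, modulating the target pharmacologically is
expected to shift the disease risk too.  The package covers the whole
screening workflow — cis-instrument selection, exposure/outcome
harmonisation, two-sample MR estimation, sensitivity diagnostics — plus a
seeded synthetic-GWAS generator so every stage can be validated end to end
with known causal truth and no external downloads.

## The statistics

For SNP *j*, let β̂ₓⱼ (SE σₓⱼ) be its effect on the exposure (the drug
target's genetically proxied activity) and β̂ᵧⱼ (SE σᵧⱼ) its effect on the
outcome, harmonised to the same effect allele.  The primary estimator is
the inverse-variance-weighted (IVW) combination of per-SNP Wald ratios,

    β̂_IVW = Σⱼ β̂ₓⱼ β̂ᵧⱼ / σᵧⱼ²  ÷  Σⱼ β̂ₓⱼ² / σᵧⱼ² ,

with a multiplicative random-effects standard error floored at the
fixed-effect value: se = (Σβ̂ₓ²/σᵧ²)^(−1/2) · max(1, √(Q/(L−1))), where Q
is Cochran's heterogeneity statistic.  MR-Egger (free intercept; slope =
pleiotropy-adjusted effect, intercept = directional-pleiotropy test) and
the weighted median (bootstrap SE) supplement it, and MR-PRESSO plus
leave-one-out analysis probe outliers and single-SNP leverage.  Estimates
are reported as odds ratios OR = exp(β̂) with 95% CI exp(β̂ ± 1.96·se).

Instruments are selected per target as SNPs within the gene body ± 100 kb
with exposure p < 5×10⁻⁸, greedily LD-clumped to pairwise r² < 0.3
against a user-supplied dosage reference, and filtered to F ≥ 10.
See `docs/methods.md` for every convention and its rationale.

## Worked example

The package bundles a harmonised table of 77 cis instruments across 11
drug targets screened against ovarian cancer (targets of statins,
lonafarnib, aspirin, and quinacrine).  Analysing it takes one call — or
one shell command:

```bash
targetmr fixture --outdir out/
```

```
CASP1   OR=0.914123044  CI=(0.836059318, 0.999475662)   p=0.0486649     n_snp=7
CASP3   OR=0.999272958  CI=(0.998700190, 0.999846055)   p=0.0129078     n_snp=11
CCND1   OR=0.996798602  CI=(0.995203219, 0.998396544)   p=8.72305e-05   n_snp=9
FNTA    OR=0.714571216  CI=(0.597682908, 0.854319265)   p=0.000226306   n_snp=4
FNTB    OR=1.000560808  CI=(1.000092203, 1.001029633)   p=0.0189885     n_snp=9
HMGCR   OR=1.131314709  CI=(1.027776107, 1.245283834)   p=0.0117535     n_snp=5
HSPA5   OR=0.997892376  CI=(0.995974116, 0.999814331)   p=0.031623      n_snp=4
ITGAL   OR=1.001353203  CI=(1.000217008, 1.002490689)   p=0.0195642     n_snp=10
NEU1    OR=0.996386349  CI=(0.993805298, 0.998974103)   p=0.00622622    n_snp=4
PLA2G4A OR=1.097906571  CI=(1.013595152, 1.189231062)   p=0.0219493     n_snp=6
PTGS1   OR=1.002096780  CI=(1.000537343, 1.003658646)   p=0.0083871     n_snp=8
```

Each line is one target's IVW causal odds ratio per unit of genetically
proxied target activity.  OR < 1 (FNTA, HSPA5, NEU1, CCND1, CASP1, CASP3)
means higher proxied activity associates with *lower* ovarian-cancer risk;
OR > 1 (HMGCR, PLA2G4A, ITGAL, PTGS1, FNTB) the reverse — so inhibiting
the latter group (e.g. HMGCR by statins, PTGS1 by aspirin) is the
direction a repositioning hypothesis would take.  Note the scale of an OR
depends on the outcome GWAS's trait coding: targets analysed against a
linear-probability-coded biobank outcome have ORs very close to 1 at
similar statistical strength.  `out/` receives full TSV reports:
per-method estimates (IVW, MR-Egger, weighted median, fixed-effect ratio
combination), sensitivity diagnostics, and a forest-plot-ready
leave-one-out table.

The same analysis from Python:

```python
from targetmr import load_ovarian_instruments, ivw

fnta = load_ovarian_instruments("FNTA")
est = ivw(fnta)
print(est.or_, est.ci_low, est.ci_high, est.pval)
# 0.714571215606842 0.597682907733698 0.8543192645578328 0.00022630590643263375
```

For a full study on your own data, provide a drug→target TSV, gene
regions (BED), exposure/outcome summary-statistic TSVs, SNP positions,
and optionally a dosage matrix for LD clumping, then:

```bash
targetmr run --config study.yaml
```

A synthetic study with known truth (for method validation or teaching):

```bash
targetmr simulate --outdir sim/ --seed 7 --theta 0.3
```

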