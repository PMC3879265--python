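# memphen

Model-based phenotyping of emotional modulation in verbal free recall.

Classical memory scores — how many words someone recalls — confound many
distinct cognitive processes: encoding, forgetting, emotional
amplification of memory traces, and the willingness to guess.  `memphen`
implements a generative computational model of a 30-word free-recall task
(immediate and 5-minute delayed recall of neutral, positive and negative
nouns) that separates these processes into interpretable per-subject
parameters, and provides the machinery to use those parameters as
phenotypes for genetic association.  It is aimed at behavioural-genetics
and computational-psychiatry researchers who want model-derived rather
than raw phenotypes, and at methodologists studying the power of
model-based association.

## The model

Each studied word acquires a latent memory strength at encoding

```
m0 = eps_v * (alpha + N(0, sigma))
```

with learning rate `alpha`, encoding noise `sigma`, and a valence-specific
emotional modulation `eps_v` (`eps_pos` for positive words, `eps_neg` for
negative words, 1 for neutral).  A word is attempted in free recall iff
`m > beta` (decision threshold), and an attempted recall succeeds with
probability `g(m) = 1 / (1 + exp(-s (m - 1)))`; a failed attempt produces
one confabulative error.  Correctly recalled words are boosted by the
repetition factor `c >= 1`; the 5-minute delay multiplies all strengths
by the forgetting rate `gamma < 1`.  The task yields eight performance
measures (PM1–PM8): correct recalls per valence and confabulative errors,
at each of the two time points.

Per subject, five parameters (`alpha, beta, c, eps_pos, eps_neg` in the
selected model) are estimated by minimising

```
chi2 = sum_i (PM_i_obs - PM_i_mod)^2 / var_i      (i = 1..8)
```

where the expected PMs come from exact integration over the encoding
distribution and `var_i` is the cohort variance of PM_i; the remaining
three parameters (`gamma, sigma, s`) are population-level constants.  Fit
adequacy is judged by `P(chi2, nu=3) > 0.05`.  Estimation uses staged
grid search (8^5 free-parameter sets, 4^3 fixed sets at full resolution),
deterministic first-improvement hill climbing (5% then 1% steps), subset
averaging over the ten best fixed sets (all 2^10−1 = 1023 combinations),
and model selection over all C(8,3) = 56 free/fixed partitions.  Fitted
parameters — most prominently the negative modulation `eps_neg` — are
associated with additive allele dosage by Spearman rank correlation with
Bonferroni control, after call-rate / MAF / Hardy–Weinberg marker QC.

The `synthetic_data` module generates complete cohorts (HWE genotypes, a
genotype-dependent `eps_neg` effect, recall logs, PM tables) so the whole
pipeline runs end-to-end without any external data.

## Worked example

Simulate a 60-subject cohort, fit every subject at the fast `desk`
resolution, and inspect the principal components:

```bash
memphen simulate --seed 7 --n-subjects 60 --out-dir demo
memphen fit --seed 7 --pm-table demo/pm_table.tsv --out demo/fits.tsv
memphen pca --pm-table demo/pm_table.tsv --loadings-out demo/loadings.tsv
```

which prints

```
wrote cohort of 60 subjects to demo (seed 7)
fitted 60 subjects: mean chi2 0.1782, 100.0% pass P(chi2, 3) > 0.05
first five components explain 53.6%, 17.5%, 12.4%, 8.0%, 5.1% of variance
```

Every subject passes the chi-square fit test (the model is flexible
enough to reproduce each behavioural profile), and the fitted `eps_neg`
rank-correlates with the generating truth (Spearman rho = 0.58,
p = 1.4e-6 on this cohort).  At n = 60 the genotype association with
fitted `eps_neg` is not yet detectable (rho = 0.10, p = 0.44) — an
effect of this size needs cohorts in the thousands, which is exactly
the kind of power question the synthetic generator is designed to probe.

The same operations are available as library calls
(`memphen.synthetic_data.generate_cohort`, `memphen.fitting.fit_cohort`,
`memphen.association.spearman_association`, ...).

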