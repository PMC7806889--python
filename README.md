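# labiofreq

Usage-based statistics of labiodental consonants in the world's languages.

Labiodentals ([f], [v], marginally [ʋ], [ɱ], [ⱱ]) are articulated with the
lower lip against the upper teeth. A long-standing hypothesis in linguistic
anthropology holds that their use tracks speakers' dentition: populations
with heavy-wear diets — traditional hunter-gatherers (HG) — tend toward
edge-to-edge bites that make labiodentals effortful, while food-producing
populations keep the overbite/overjet that makes them cheap. `labiofreq`
provides the machinery for testing this *in speech usage* rather than in
phoneme inventories, for researchers in comparative linguistics and
cultural evolution working with ASJP-style word lists.

For each doculect (one documented language variety, with word forms over
~40 basic concepts) the package tabulates consonant tokens `C`, labiodental
tokens `F`, and word-initial labiodental tokens `F_wi`, and computes

```
LR = F / C          WILR = F_wi / C        (so WILR ≤ LR)
```

Cross-cultural samples are not independent (Galton's problem: shared
descent and areal contact), so the HG vs non-HG contrast is estimated three
ways, all with linguistic lineage and geographic region as crossed grouping
factors:

1. **Linear mixed model** on logit-transformed ratios (Smithson–Verkuilen
   compression `y = (x(N−1)+½)/N` handles the many all-zero lists), fixed
   effect β for HG, random intercepts `a_lineage`, `a_region`, ML fit,
   likelihood-ratio test against the null without β;
2. **Binomial mixed model** (Laplace ML) on the presence/absence of any
   labiodental in the list;
3. **Bayesian beta mixed model** `y ~ Beta(μφ, (1−μ)φ)`,
   `logit μ = β₀ + β·HG + a_lineage + a_region`, sampled by a seeded
   adaptive MCMC scheme, reporting `Pr(β < 0)`;

plus a model-free **stratified resampling contrast**: per iteration, draw
one doculect per lineage, then one per region within that draw, separately
for each group, and record `mean(non-HG) − mean(HG)`; 5000 iterations give
a disparity distribution whose location answers the directional question.
Uncorrected Pearson chi-square tests cover the contingency-style analyses
(individual speakers' consonant counts, lineage-level presence in
transcribed texts).

Because the underlying databases cannot be redistributed, the package ships
a hierarchical synthetic generator (`labiofreq.simulate`) that emulates the
assumed data structure — doculects in lineages in regions, per-doculect
labiodental probability built on the logit scale — with a worldwide-scale
preset (2729 doculects, 233 lineages, 24 regions) whose expected group LR
means equal the observed 0.0218 (non-HG) and 0.0079 (HG). Every stage of
the pipeline is validated end to end against it; see `docs/methods.md`.

## Worked example

```python
import labiofreq as lf

# the ten-speaker contingency analysis: 88/4645 vs 365/5629 labiodental
# consonant tokens in the two bite-type groups
res = lf.pearson_chi_square([[88, 4557], [365, 5264]])
print(f"chi2 = {res.statistic:.1f}, df = {res.df}, p = {res.p_value:.2e}")

# a full synthetic run at worldwide scale
cfg = lf.paper_mimic_preset(seed=1)
ds = lf.generate_dataset(cfg)
profiles, _ = lf.profile_doculects(ds.doculects)
table = lf.join_metadata(lf.profiles_frame(profiles), ds.metadata, taxonomy="large")
print(lf.summarize_by_group(table.frame, table.group_labels()).round(4).to_string(index=False))

model = lf.fit_lmm(table, response="lr_t")
print(f"HG coefficient = {model.fixed_effect:.3f} (SE {model.fixed_effect_se:.3f}), "
      f"LRT chi2 = {model.lrt_chi2:.2f}, p = {model.p_value:.1e}")

dist = lf.StratifiedContrast(table, statistic="lr").run(iterations=5000, seed=1)
print(f"mean LR disparity = {dist.mean:.4f} (median {dist.median:.4f}), "
      f"fraction positive = {dist.fraction_positive:.3f}")
```

Output:

```
chi2 = 127.2, df = 1, p = 1.68e-29
group    n  lr_mean  lr_sd  wilr_mean  wilr_sd
  all 2729   0.0183 0.0264     0.0090   0.0147
   HG  676   0.0101 0.0146     0.0048   0.0088
nonHG 2053   0.0211 0.0287     0.0104   0.0159
HG coefficient = -1.414 (SE 0.219), LRT chi2 = 38.13, p = 6.6e-10
mean LR disparity = 0.0136 (median 0.0133), fraction positive = 0.996
```

Reading it: the chi-square reproduces the published speaker disparity from
its printed counts. In the synthetic run, hunter-gatherer doculects use
labiodentals at roughly half the non-HG rate (the generating gap is
0.0218 vs 0.0079 in expectation; realized group means wander by
cluster-level Monte-Carlo error). The mixed model recovers a clearly
negative HG coefficient on the transformed scale, and 99.6% of the 5000
lineage/region-controlled contrasts are positive — more labiodental usage
outside HG groups, the predicted direction.

The same pipeline runs from the shell:

```bash
labiofreq simulate --preset --seed 1 --out data/
labiofreq run-all --wordlists data/wordlists.csv --metadata data/metadata.csv \
    --seed 1 --out results/
labiofreq chisq 88 4557 365 5264
```

## Layout

```
src/labiofreq/
  segments.py    tokenization; segment-class tables (data/asjp_segments.csv, data/ipa_segments.csv)
  wordlists.py   doculect containers; long/wide word-list readers
  stats.py       LR/WILR profiles, ratio transforms, group summaries, chi-square
  metadata.py    lineage/region/subsistence joins (two taxonomies), drop accounting
  lmm.py         crossed random-intercepts linear mixed model (profiled ML)
  glmm.py        crossed random-intercepts logistic mixed model (Laplace ML)
  betareg.py     Bayesian beta mixed model (adaptive MCMC)
  resampling.py  stratified lineage-then-region contrast
  simulate.py    hierarchical synthetic word-list generator
  pipeline.py    end-to-end orchestration, text-counts pathway
  cli.py         command-line interface
```
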