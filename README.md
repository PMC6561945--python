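# icrprofiler

Immune-transcriptomic analysis of small paired-biopsy cohorts profiled on a
targeted immune gene panel (NanoString nCounter-style: 770 endogenous
transcripts plus housekeeping and negative/positive control probes).  The
package was built around the analysis of imiquimod-treated breast cancer
skin metastases — 8 patients, same-site biopsies before and after 8 weeks of
treatment, labeled complete responder (CR), partial responder (PR) or
non-responder (NR) — but every stage is a reusable library function.

It is aimed at computational immunologists who need the full chain from raw
panel counts to interpretable immune statistics without a download:

* **Normalization** — per-sample housekeeping scaling (`f_s = G*/G_s` with
  geometric means of housekeeping counts), negative-control background
  subtraction, quantile normalization across samples, `log2(x + 1)`.
* **ssGSEA** — single-sample gene set enrichment for leukocyte signatures:
  per-sample ranks `r`, walk genes from top rank down and accumulate
  `ES = Σ_i [P_in(i) − P_out(i)]` with in-set weights `r^α` (α = 0.25) and a
  uniform out-of-set distribution.
* **ICR** — the 20-gene Immunologic Constant of Rejection signature
  (CXCR3/CCR5 chemokines, Th-1 signaling, effector, immune-regulatory);
  per-sample score = mean log2 expression of the signature genes;
  High/Medium/Low classes from resampled Ward-linkage consensus clustering
  of the 20 gene values, clusters ordered by mean ICR z-score.
* **Differential expression** — paired t-tests (post vs pre, all patients)
  and unpaired pooled-variance t-tests (CR vs NR per timepoint, PR
  excluded), fold change `FC = 2^(Δ mean log2)`, Benjamini–Hochberg
  q-values with an explicit universe size.
* **Enrichment & deconvolution summaries** — one-sided hypergeometric
  over-representation of panel annotation categories in DEG lists;
  per-signature net percent of genes crossing a 1.5-fold threshold; forest
  plot statistics `FC_e = exp(Δ mean ES)` with t-based 95% CIs.
* **Synthetic cohorts** — a negative-binomial generator reproducing the
  paired 8-patient design with known injected effects, so every stage is
  testable with recoverable ground truth.

## Worked example

```python
import icrprofiler as icp

counts, samples, truth = icp.generate_dataset(icp.SyntheticConfig(seed=1))
expr, report = icp.normalize_pipeline(counts)
scores, classes, _ = icp.classify_icr(expr, reps=200, seed=1)
for comp in icp.study_comparisons(samples):
    degs = icp.select_degs(icp.differential_table(expr, comp))
    print(comp.name, len(degs))
print(classes.value_counts().to_dict())
```

prints

```
post_vs_pre 47
CR_vs_NR_pre 44
CR_vs_NR_post 60
{'Medium': 7, 'Low': 6, 'High': 3}
```

— 47 genes move after treatment across all patients, 44 already separate
future responders at baseline, 60 separate them after treatment, and the
three ICR-High samples are exactly the responders' post-treatment biopsies
(the generator injects a +2 log2 ICR shift there).  The `examples/`
directory has one narrative script per capability, and the `icrprofiler`
command exposes the same stages as subcommands
(`synth`, `normalize`, `ssgsea`, `icr`, `deg`, `enrich`, `sigchange`,
`deconv`, `pca`, `run`).

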