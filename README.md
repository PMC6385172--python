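# purityconn

Purity-aware connectivity-map signature reversal for bulk tumour RNA-seq
drug repositioning, built around the clear cell renal cell carcinoma
(ccRCC) setting.

## The problem

Signature-reversal drug repositioning scores a drug by its expected
ability to push a tumour's differential-expression signature back toward
normal tissue. Bulk RNA-seq, however, measures a *mixture*: a ccRCC sample
is typically only 55–80% cancer cells, and the rest — vasculature, immune
and other stromal cells — contributes its own transcripts. A drug that
appears to "reverse" a tumour signature may in fact be reversing genes
expressed by the non-cancerous cells. ccRCC makes the confounding worse in
a specific way: loss of chromosome 3p (or VHL mutation/methylation)
activates the hypoxia-inducible-factor (HIF) programme, which drives
angiogenesis — so the very tumours with the strongest HIF signal are also
the least pure.

`purityconn` implements the full analysis needed to untangle this:

1. **Tumour signatures** — per-sample differential expression against a
   pooled normal-kidney reference: genes at mean reference CPM ≥ 0.5 are
   tested with a z-statistic on log2(CPM+1) and admitted at
   Benjamini–Hochberg FDR < 1%.
2. **Drug signatures** — per-gene concentration slopes from a
   perturbation screen, fitted by OLS with cell line, exposure duration
   and batch as categorical covariates; genes are ranked by the slope
   t-statistic.
3. **Connectivity scores** — the bidirectional Kolmogorov–Smirnov
   running-sum statistic of the signature's up and down sets located in a
   drug ranking of N genes. For a set with sorted ranks V(1..n),

       a = max_j ( j/n − V(j)/N ),   b = max_j ( V(j)/N − (j−1)/n ),
       ES = a  if a ≥ b  else −b,
       score = (ES_up − ES_down) / 2,

   with score ≡ 0 when both enrichments are nonzero with the same sign,
   undefined below 10 signature genes, and a permutation p-value from
   random same-size gene-set pairs. Negative scores mean expected
   (partial) reversal.
4. **Purity confounding** — Spearman association of scores with estimated
   tumour purity, classification of signature genes as more/less
   differentially expressed with increasing purity, signature filtering,
   and negative-enrichment rates (score < 0, permutation p < 0.05).
5. **HIF stratification** — samples are deemed likely HIF-activated when
   both reference HIF inhibitors give strictly negative scores; the purity
   analyses are rerun per stratum.
6. **Covariate models** — univariate nonparametric screens (Bonferroni),
   linear mixed models with batch variables as random intercepts, backward
   elimination at P < 0.05, 1,000-resample bootstrap stability selection
   (keep at ≥ 50%), bootstrap coefficient p-values, and repeated 10-fold
   cross-validation.
7. **Discordant-methylation comparison** — exact statistics over the
   packaged 24-sample table of ccRCC tumours whose methylomes cluster with
   papillary/chromophobe RCC.

A seeded synthetic-cohort generator (`purityconn.synth`) emulates the
TCGA-like setting — purity-weighted tumour/stroma mixtures, a latent
graded HIF activation tied to 3p loss and VHL status and (negatively) to
purity, p53-pathway alterations that inflate signatures, and a LINCS-like
screen with HIF-reversing, stroma-reversing and null drugs — so every
stage can be validated against known ground truth.

## Worked example

```python
from purityconn.synth import desk_config, generate_cohort, generate_drug_screen
from purityconn.signatures import cohort_signatures, all_drug_signatures
from purityconn.connectivity import score_cohort
from purityconn.purity import correlate_connectivity_purity

cfg = desk_config(seed=1)                  # 300 tumours, 40 normals, 1,200 genes
matrix, meta, truth = generate_cohort(cfg)
screen = generate_drug_screen(cfg, truth)

tumours = [m.sample_id for m in meta if m.role == "tumour"]
normals = [m.sample_id for m in meta if m.role == "normal"]
sigs = cohort_signatures(matrix, tumours, normals)
drugs = all_drug_signatures(screen)
results = score_cohort(sigs, drugs, n_perm=200, seed=5)

for drug in ("STROMA-R", "HIFI-A", "NULL-1"):
    a = correlate_connectivity_purity(
        results[results["drug_id"] == drug], truth.samples["purity_pct"])
    print(f"{drug:9s} rho={a.spearman_rho:+.2f} p={a.spearman_p:.2g} n={a.n}")
```

prints

```
STROMA-R  rho=+0.41 p=4.1e-13 n=294
HIFI-A    rho=+0.13 p=0.03 n=294
NULL-1    rho=+0.04 p=0.51 n=294
```

The stroma-reversing drug's scores rise steeply toward neutrality as
purity increases (rho = +0.41): its apparent repositioning signal lives in
the non-cancerous compartment. The HIF inhibitor shows the same trend more
weakly (rho = +0.13) — and after stratifying by likely HIF activation the
trend inside the activated stratum disappears, which is the behaviour that
distinguishes a genuine tumour-cell target from a stromal artefact. The
null drug shows no trend.

The same pipeline runs from the command line:

```bash
purityconn all --seed 1 --outdir results/run1        # simulate + analyse
purityconn discordant --outdir results/              # packaged-table statistics
```

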