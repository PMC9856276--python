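# protpanel

Multi-protein biomarker panel discovery for aptamer proteomics
case–control studies.

Neurodegenerative diseases such as Parkinson's lack reliable fluid
biomarkers. Modern aptamer capture assays measure 1000–4000 proteins per
sample as relative fluorescence units (RFU), and a practical discovery
programme combines machine-learning panel selection across tissue types
(serum, CSF, post-mortem brain) with mechanistic analyses of the same
matrices. `protpanel` packages that analysis as a tested, reusable
pipeline for statisticians and computational biologists working on
case–control proteomics:

* **QC / normalization** — sample acceptance filtering on QC scale
  factors (closed window 0.4–2.5), log2 transform, per-protein Z-scores,
  per-dataset covariate residualization (OLS residuals per protein),
  empirical-Bayes batch adjustment (ComBat), and a PC–confounder scan.
* **Discovery** — protein ranking by a greedy annealing search over
  subsets (acceptance iff the cross-validated logistic fitness strictly
  improves; selection frequency across restarted chains), nested
  random-forest panels on the top-N ranked proteins, and held-out
  evaluation with AUC = P(case outranks control), permutation p-values
  p = (r+1)/(B+1), and stratified bootstrap CIs.
* **Signature replication** — panel compression to one score per sample
  (mean-Z or SVD eigengene, sign-anchored) and association with clinical
  outcomes (logistic for status, linear for MoCA / MDS-UPDRS III).
* **Differential regulation** — per-protein GLM scans (binomial for
  status, Gaussian for continuous outcomes) with covariate adjustment and
  Benjamini–Hochberg FDR, plus an unadjusted targeted-panel mode.
* **Enrichment** — hypergeometric over-representation of a protein list
  against GMT gene sets within an assay-restricted universe.
* **Co-expression** — WGCNA-style modules for proteins: `|cor|^2`
  adjacency, topological overlap, average-linkage clustering with a
  minimum module size of 30, eigengenes, hub proteins (max |kME|), and
  module–trait regression.
* **Severity** — a composite cognitive+motor severity score,
  mild / intermediate / severe stratification (bottom 15% / top 10% by
  default), and stratified classifier evaluation.
* **Synthetic studies** — a generator that emulates matched multi-cohort,
  multi-modality designs with planted case effects, severity-coupled
  signal, co-expression blocks, and batch structure, so the whole
  pipeline runs and is tested without clinical data access.

See `docs/methods.md` for the models, parameters and design choices.

## Worked example

```python
import protpanel as pp

# a reduced synthetic serum cohort: 700 samples, 300 proteins,
# 30 disease-associated proteins planted at log2 effect 0.6
planted = tuple((f"P{i:05d}", 0.6) for i in range(10, 301, 10))
cfg = pp.small_config(n_samples=700, case_fraction=0.5,
                      n_proteins=300, seed=1,
                      informative_proteins=planted)
matrix, meta = pp.generate_cohort(cfg, "serum")

ids = matrix.sample_ids
train, test = ids[:500], ids[500:]
tr = pp.log2_and_standardize(matrix.subset_samples(train))
te = pp.log2_and_standardize(matrix.subset_samples(test))

ranked = pp.sa_rank_proteins(tr, meta.subset(train), seed=1)
panels = pp.sweep_panel_sizes(tr, meta.subset(train), ranked, 5, 60,
                              rf_params={"n_estimators": 200}, seed=1)
best, auc = pp.best_panel_by_test_auc(panels, te, meta.subset(test))
hits = len(set(p for p, _ in planted) & set(best.members))
print(f"best panel N={best.N}, held-out AUC={auc:.3f}, "
      f"planted members {hits}/{best.N}")
```

This prints:

```
best panel N=22, held-out AUC=1.000, planted members 22/22
```

i.e. the search selected a 22-protein panel consisting entirely of the
planted disease-associated proteins, and that panel separates cases from
controls perfectly on the 200 held-out samples. (At the planted effect
size each protein is individually weak — single-protein AUC ≈ 0.8 — so
the perfect held-out AUC reflects the panel, not any one protein.)

The same stages are available from the shell:

```bash
protpanel simulate --seed 1 --out study/ --small
protpanel normalize --expression study/serum_expression.tsv --out norm.tsv
protpanel rank --expression norm.tsv --metadata study/serum_metadata.tsv \
    --iterations 1000 --seed 1 --out ranked.tsv
```

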