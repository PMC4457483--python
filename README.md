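# radmetab

Radiation-induced liver disease (RILD) limits curative radiotherapy of liver
cancers, and no early clinical biomarker exists: injury is usually
recognized months after exposure. One proposed route to early detection is
metabolomic — profile liver tissue and plasma of irradiated mice 24 h after
whole-liver irradiation (WLI: untreated, sham 0 Gy, 10 Gy, 50 Gy) and a
whole-body companion (WBI: 0/10 Gy), and look for metabolites whose plasma
levels track their liver levels with dose.

`radmetab` implements that analysis chain as a tested, reusable Python
package for researchers working with untargeted metabolomics feature tables
(rows = samples, columns = metabolites):

- **Preprocessing** — minimum imputation, normalization of every metabolite
  to mean 1 over the sham (0 Gy) group, natural-log transform.
- **Univariate screen** — Welch's t, Wilcoxon rank sum and one-way ANOVA on
  log data, with Benjamini–Hochberg q-values per tissue × contrast and the
  joint significance gate *p* < 0.05 AND *q* < 0.10.
- **Validation cascade** — a decision tree requiring replicated evidence:
  significance at 50 Gy vs 0 Gy must be confirmed at 50 Gy vs untreated
  (same direction) or, failing that, at the 10 Gy contrasts; cross-tissue
  agreement defines the biomarker panel, and the WBI cohort both rescues
  single-level hits and labels each shared metabolite's response as same-
  or opposite-direction across modalities.
- **Correlation maps** — pooled-group Spearman ρ, liver–plasma concordance
  ranking, average-linkage clustering on 1 − ρ, pathway-level aggregation
  of the correlation matrix (mean/median/min/max over leaf pairs), and
  pathway-association profiles for "known unknown" features.
- **Class separation** — PCA, PLS-DA with VIP scores
  (VIP<sub>j</sub> = √(p·Σ<sub>a</sub> SSY<sub>a</sub>(w<sub>ja</sub>/‖w<sub>a</sub>‖)² / Σ<sub>a</sub> SSY<sub>a</sub>),
  mean VIP² ≡ 1), out-of-bag random forests, and a batch self-organizing
  map with component planes, all reported as confusion matrices with
  per-class error rates.
- **Synthetic cohorts** — a log-normal generator with planted dose effects,
  pathway-block correlation, paired tissues, sign-flipped WBI responses and
  missing-not-at-random dropout, providing ground truth for every stage.

PLS-DA and the SOM are scikit-learn-style estimators (`PLSDAClassifier`,
`SelfOrganizingMap`) and compose with sklearn model selection.

## Worked example

```python
import numpy as np
from radmetab import (
    default_panel_config, generate_cohort, preprocess, run_comparisons,
    run_cascade, cross_tissue_validate, venn_summary, confusion_report,
)

cfg = default_panel_config(seed=1)          # the study-emulation conditions
liver, plasma, meta, truth = generate_cohort(cfg)
v = venn_summary(liver, plasma)
print(f"features: liver={v.liver_detected} plasma={v.plasma_detected} "
      f"shared={v.shared} union={v.union}")

records = {}
for tissue, table in (("liver", liver), ("plasma", plasma)):
    sub = meta[(meta.tissue == tissue) & (meta.modality == "WLI")]
    _, log = preprocess(table, sub)
    records[tissue] = run_cascade(run_comparisons(log, sub), tissue=tissue)
_, _, panel = cross_tissue_validate(records["liver"], records["plasma"])
print(f"cross-tissue panel: {len(panel)} metabolites")
print(panel.head(5).to_string(index=False))

table3_liver = [[8,0,0,0],[1,5,0,0],[0,2,5,0],[0,0,0,8]]
rep = confusion_report(np.array(table3_liver), ["untreated","0Gy","10Gy","50Gy"])
print(f"overall accuracy: {rep.accuracy}%  per-class errors: {rep.per_class_error}")
```

prints

```
features: liver=407 plasma=347 shared=159 union=595
cross-tissue panel: 15 metabolites
metabolite                liver_status               plasma_status    min_q
      S004 validated_primary_confirmed validated_primary_confirmed 0.000003
      S010 validated_primary_confirmed validated_primary_confirmed 0.000004
      S001 validated_primary_confirmed validated_primary_confirmed 0.000019
      S002 validated_primary_confirmed validated_primary_confirmed 0.000020
      S008    single_level_unconfirmed validated_primary_confirmed 0.000026
overall accuracy: 90%  per-class errors: {'untreated': 0, '0Gy': 17, '10Gy': 29, '50Gy': 0}
```

The generator planted 17 cross-tissue biomarkers; at this seed the cascade
recovers 15 of them and no false positives (`S008` shows how a metabolite
unconfirmed in one tissue can still enter the panel through the other).
The confusion report reproduces a reference random-forest table: 90%
overall accuracy with per-class error rates of 0/17/29/0 percent under
half-up integer rounding.

## Command line

The same pipeline runs from a shell, one artifact directory per run:

```bash
radmetab run-all --out run1 --seed 1              # synthetic end-to-end run
radmetab simulate --out run2 --seed 2             # stages individually
radmetab preprocess --dir run2
radmetab stats --dir run2
radmetab validate --dir run2
```

`run-all` executes simulate → preprocess → stats → validate → correlate →
classify → report and writes a manifest (config echo, seed, per-stage
counts, checksums). Identical config and seed reproduce byte-identical
outputs. Real data enter through `RunConfig` paths (wide abundance CSVs, a
sample-metadata CSV, an optional metabolite → pathway ontology CSV).

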