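# ehreval

Statistically sized gold standards and precision/recall evaluation for
clinical NLP (cNLP) systems that read electronic health records (EHRs).

When a cNLP system extracts clinical concepts (diseases, symptoms,
treatments, tests) from free-text EHRs, its output has to be validated
against expert-annotated documents. Two failure modes are common: gold
standards too small to give statistically useful metrics, and "the more,
the better" standards that waste scarce clinician time. `ehreval`
implements the statistical spine of a document-level evaluation that
avoids both:

1. **Exact binomial confidence intervals** (Clopper–Pearson), used
   everywhere a proportion is reported.
2. **Gold-standard sample sizing**: from a desired confidence level and
   CI half-width, the expected precision *P* and recall *R* of the
   system, and the occurrence rate *f* of the primary clinical variable,
   compute how many positive and negative documents to annotate and how
   to share them equally among participating hospitals.
3. **Stratified document selection** (seeded, reproducible): primary
   positives/negatives per hospital, secondary variables represented by
   top-up draws, secondary negatives restricted to documents without the
   primary variable.
4. **Blind double annotation and curator adjudication** into a gold
   standard with per-cell provenance (consensus vs curated).
5. **Evaluation**: per-variable TP/FP/FN/TN, precision = TP/(TP+FP),
   recall = TP/(TP+FN), F1 = their harmonic mean, all with exact CIs;
   inter-annotator agreement (IAA) as pairwise F1; compliance checks of
   achieved CI widths against the widths the study was sized for.

A synthetic-corpus generator emulates multi-hospital corpora, two noisy
annotators, a curator and an imperfect detection system, so the entire
pipeline is testable without any clinical data. No EHR text is ever
consumed or produced; everything operates on document-level
present/absent tables.

## Worked example

Sizing a six-hospital gold standard for an asthma study in which the
event frequency across hospitals is 48.5%, expecting precision 85% and
recall 80%, at 95% confidence with a ±5% interval:

```bash
ehreval slice --confidence 0.95 --width 0.05 --precision 0.85 \
    --recall 0.80 --frequency 0.485 --mode external --hospitals 6
```

```json
{"n_positive": 249, "n_negative": 270, "n_total": 519,
 "per_hospital": [{"hospital_index": 0, "positives": 42,
                   "negatives": 45, "documents": 87}, "..."]}
```

249 documents flagged for asthma and 270 unflagged ones — 519 in total,
87 per hospital (42 positive, 45 negative). After double annotation,
curation (`ehreval gold`) and evaluation (`ehreval evaluate`), the report
layer prints per-variable rows in the `estimate (lower-upper)` style:

```python
from ehreval import ConfusionCounts, metrics, render_report

m = metrics(ConfusionCounts(tp=271, fp=18, fn=10, tn=220), variable="asthma")
print(render_report([m], format="markdown"))
```

```
| Variable | Precision (CI) | Recall (CI) | F1 (CI) |
| --- | --- | --- | --- |
| asthma | 0.94 (0.90-0.96) | 0.96 (0.94-0.98) | 0.95 (0.92-0.97) |
```

Here the system retrieved 289 documents of which 271 were truly positive
(precision 0.94) and missed 10 of the 281 gold positives (recall 0.96);
both intervals are comfortably narrower than the ±5% the study was sized
for, which `check_expected_compliance` confirms programmatically.

The CLI covers each phase: `ci`, `frequency`, `slice`, `sample`, `gold`,
`iaa`, `evaluate`, `simulate`, `report`. Validation errors exit with
code 2 (JSON on stderr), infeasible sampling with code 3.

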