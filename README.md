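# soaptriage

Predicting emergency-department disposition — admission to a ward bed vs.
discharge home — from the free text of the **first SOAP note** of a visit,
and comparing the machine's accuracy against human graders with proper
correlated-ROC statistics.

The package is aimed at clinical-informatics and hospital-operations
researchers who want a tested, reproducible implementation of this kind of
text-classification protocol: corpus cleaning with auditable exclusion
accounting, supervised n-gram featurization, a linear nu-SVC, and the full
evaluation layer (AUROC with confidence intervals, DeLong's test, Youden
cutoffs, Cohen's kappa, concordance tables). Because first-encounter ED
notes are private, a synthetic-corpus generator with controllable class
signal and known contamination ground truth stands in for real EMR data.

## The method

1. **Filtering.** Four exclusion rules with per-class accounting:
   duplicates, explicit final-status leaks (e.g. "HAA", "PD",
   "patient left"), empty records, incomplete SOAP records. Each record is
   claimed by at most one rule, so `initial = removed + final` exactly.
2. **Featurization.** Notes are normalized (lowercase, punctuation and
   digits stripped, stopwords removed, optional stemming) and expanded
   into unigrams, bigrams and trigrams. Each candidate feature *i* gets an
   F-value

       F(i) = [(x̄ᵢ⁺ − x̄ᵢ)² + (x̄ᵢ⁻ − x̄ᵢ)²] / [s²ᵢ⁺ + s²ᵢ⁻],

   the ratio of between-class mean separation to summed within-class
   variance of its raw counts; features strictly above the 65th percentile
   are kept. Matrix cells are max-normalized TF-IDF:

       TFIDF(t,d,D) = f(t,d)/max{f(t′,d) : t′∈d} · log(|D|/df(t)).

3. **Classification.** A nu-SVC with linear kernel (nu = 0.5); the
   decision score is s(x) = w·x + b with admission as the positive class.
4. **Evaluation.** Stratified splitting, finite-population margin of
   error, ROC/AUROC (trapezoidal ≡ Mann-Whitney), DeLong variance and the
   DeLong test for two correlated ROC curves, Youden's J cutoff with
   Wilson CIs for sensitivity/specificity, Cohen's kappa with
   Landis–Koch bands, conservative pooling of rater pairs (disagreement →
   "inpatient"), and five-category machine-vs-physician concordance
   accounting.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import soaptriage as st

cfg = st.ExperimentConfig(
    corpus=st.CorpusConfig(n_records=2000, seed=0),  # signal_strength 0.9
    master_seed=42,
)
results = st.run_experiment(cfg, "out/")
print(open("out/accuracy.tsv").read())
```

prints the accuracy table for the 500 held-out records:

```
	Machine	Novice Physicians	Experienced Physicians
Accuracy	1.00 (1.00–1.00)	0.79 (0.76–0.82)	0.73 (0.69–0.76)
Sensitivity	1.00 (0.98–1.00)	0.97 (0.94–0.99)	0.99 (0.97–1.00)
Specificity	1.00 (0.99–1.00)	0.61 (0.55–0.66)	0.46 (0.40–0.52)
```

Row "Accuracy" is AUROC with its 95% CI; sensitivity and specificity are
taken at the Youden-optimal cutoff with Wilson intervals. On this
strong-signal synthetic corpus the machine separates the classes
essentially perfectly, while the simulated physician groups (novice pair
at sensitivity 0.85 / specificity 0.78, experienced pair at 0.85 / 0.67,
pooled conservatively) sit at their operating points — their high
sensitivity and low specificity reflect the built-in admission-favoring
tie-break. `out/delong.tsv` holds the pairwise DeLong p-values (here the
machine differs from both groups at p < 10⁻⁴), `out/concordance.tsv` the
five-category outcome table, `out/filter_report.tsv` the exclusion
accounting, and `out/manifest.json` the config hash and derived stage
seeds that make the run reproducible bit for bit.

The same pipeline is scriptable from the shell:

```sh
soaptriage generate --out corpus.jsonl --seed 7
soaptriage filter --in corpus.jsonl --out clean.jsonl --report table1.tsv
soaptriage run --out bundle/
```

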