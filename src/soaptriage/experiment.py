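"""End-to-end experiment orchestration.

One config drives the whole reproducible pipeline: generate (or load) a
corpus → inject contamination → filter → stratified split → featurize →
train the nu-SVC → score the test set → simulate two physician pairs →
gate each pair on trial-subset kappa → aggregate conservatively → evaluate
(ROC/AUROC with CIs, Youden cutoff sensitivity/specificity, pairwise
DeLong comparisons, concordance accounting) → write the report bundle.

Every stage's randomness derives from a single master seed by stable
hashing of the stage name, so adding a stage never shifts another stage's
stream. The bundle is a directory of TSV/CSV/JSON files whose layouts
mirror the study's tables, plus a manifest recording the config hash,
derived seeds and per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import corpus as corpus_mod
from .classify import DispositionClassifier, save_model
from .corpus import (
    ContaminationSpec,
    CorpusConfig,
    RaterModel,
    generate_corpus,
    inject_contamination,
    simulate_rater,
)
from .features import SoapVectorizer
from .filtering import filter_corpus
from .records import DISCHARGED, INPATIENT, SoapRecord, read_csv, read_jsonl
from .stats import (
    SplitSpec,
    aggregate_conservative,
    binary_ratings_as_scores,
    cohens_kappa,
    concordance_table,
    delong_test,
    margin_of_error,
    roc_analysis,
    sens_spec_ci,
    stratified_split,
    youden_cutoff,
)

__all__ = ["ExperimentConfig", "validate_config", "run_experiment", "stage_seed"]

_SEED_MOD = 2**31


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage seed from the master seed by stable hashing."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:15], 16) % _SEED_MOD


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    corpus_path: str | None = None  # JSONL/CSV corpus; None -> generate
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    contamination: ContaminationSpec | None = None
    explicit_phrases: tuple[str, ...] = corpus_mod.DEFAULT_EXPLICIT_PHRASES
    stopwords: tuple[str, ...] = ()
    stemmer: str = "identity"
    percentile: float = 65.0
    log_base: float | None = None
    nu: float = 0.5
    test_fraction: float | None = 0.25
    test_counts: dict[str, int] | None = None
    novice_rater: tuple[float, float] = (0.85, 0.78)
    experienced_rater: tuple[float, float] = (0.85, 0.67)
    trial_subset_size: int = 30
    kappa_gate: float = 0.61
    confidence: float = 0.95
    master_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["corpus"] = dataclasses.asdict(self.corpus)
        d["contamination"] = (
            dataclasses.asdict(self.contamination) if self.contamination else None
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "corpus" in d and isinstance(d["corpus"], dict):
            c = dict(d["corpus"])
            if "vocab_sizes" in c:
                c["vocab_sizes"] = tuple(c["vocab_sizes"])
            d["corpus"] = CorpusConfig(**c)
        if d.get("contamination"):
            c = dict(d["contamination"])
            for k in ("n_duplicates", "n_explicit_status", "n_empty", "n_incomplete"):
                if k in c:
                    c[k] = tuple(c[k])
            if "explicit_phrases" in c:
                c["explicit_phrases"] = tuple(c["explicit_phrases"])
            d["contamination"] = ContaminationSpec(**c)
        for k in ("explicit_phrases", "stopwords", "novice_rater", "experienced_rater"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(config: ExperimentConfig) -> list[str]:
    """All violations, not just the first; an empty list means runnable."""
    findings: list[str] = []
    try:
        config.corpus.validate()
    except ValueError as err:
        findings.append(f"corpus: {err}")
    if config.contamination is not None:
        try:
            config.contamination.validate()
        except ValueError as err:
            findings.append(f"contamination: {err}")
    if not 0.0 <= config.percentile <= 100.0:
        findings.append(
            f"percentile: must be in [0, 100], got {config.percentile}"
        )
    if not 0.0 < config.nu <= 1.0:
        findings.append(f"nu: must be in (0, 1], got {config.nu}")
    if (config.test_fraction is None) == (config.test_counts is None):
        findings.append("split: give exactly one of test_fraction or test_counts")
    elif config.test_fraction is not None and not 0.0 < config.test_fraction < 1.0:
        findings.append(
            f"test_fraction: must be in (0, 1), got {config.test_fraction}"
        )
    if not 0.0 < config.confidence < 1.0:
        findings.append(f"confidence: must be in (0, 1), got {config.confidence}")
    for name in ("novice_rater", "experienced_rater"):
        pair = getattr(config, name)
        if not all(0.0 <= v <= 1.0 for v in pair):
            findings.append(f"{name}: sensitivity/specificity must be in [0, 1]")
    if not config.explicit_phrases:
        findings.append("explicit_phrases: must be non-empty")
    if config.trial_subset_size < 2:
        findings.append(
            f"trial_subset_size: must be >= 2, got {config.trial_subset_size}"
        )
    return findings


def _load_corpus(config: ExperimentConfig) -> list[SoapRecord]:
    if config.corpus_path is None:
        seeded = dataclasses.replace(
            config.corpus, seed=stage_seed(config.master_seed, "generate")
        )
        return generate_corpus(seeded)
    path = Path(config.corpus_path)
    if path.suffix == ".csv":
        return read_csv(path)
    return read_jsonl(path)


def _trial_subset(test_records, size: int, seed: int):
    """Roughly class-proportional trial subset used for the kappa gate."""
    spec = SplitSpec(test_fraction=min(size / max(len(test_records), 1), 0.999), seed=seed)
    _, trial = stratified_split(test_records, spec)
    return trial


def _accuracy_rows(name, scores, truth, confidence):
    roc = roc_analysis(scores, truth, confidence)
    thr, sens, spec = youden_cutoff(roc)
    y = np.asarray(truth)
    pred_pos = np.asarray(scores, dtype=float) >= thr
    pos = y == INPATIENT
    tp = int((pred_pos & pos).sum())
    fn = int((~pred_pos & pos).sum())
    tn = int((~pred_pos & ~pos).sum())
    fp = int((pred_pos & ~pos).sum())
    (sens_pt, s_lo, s_hi), (spec_pt, p_lo, p_hi) = sens_spec_ci(
        tp, fn, tn, fp, confidence
    )
    return {
        "grader": name,
        "auroc": roc.auroc,
        "auroc_ci": roc.ci95,
        "cutoff": thr,
        "sensitivity": (sens_pt, s_lo, s_hi),
        "specificity": (spec_pt, p_lo, p_hi),
        "roc": roc,
    }


def _write_accuracy_tsv(rows, path: Path) -> None:
    def fmt(v, lo, hi):
        return f"{v:.2f} ({lo:.2f}–{hi:.2f})"

    graders = [r["grader"] for r in rows]
    lines = ["\t" + "\t".join(graders)]
    lines.append(
        "Accuracy\t" + "\t".join(fmt(r["auroc"], *r["auroc_ci"]) for r in rows)
    )
    lines.append("Sensitivity\t" + "\t".join(fmt(*r["sensitivity"]) for r in rows))
    lines.append("Specificity\t" + "\t".join(fmt(*r["specificity"]) for r in rows))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_roc_csv(roc, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("threshold,fpr,tpr\n")
        for t, f, s in zip(roc.thresholds, roc.fpr, roc.tpr):
            fh.write(f"{t:.12g},{f:.12g},{s:.12g}\n")


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and write the report bundle.

    Returns a results dict (also summarized in ``manifest.json``);
    identical configs produce identical bundles.
    """
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid config: " + "; ".join(findings))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise ValueError(f"output directory {out_dir} is not writable")

    timings: dict[str, float] = {}
    counts: dict[str, int] = {}

    def tick(stage: str, t0: float, n: int) -> None:
        timings[stage] = round(time.perf_counter() - t0, 4)
        counts[stage] = n

    t0 = time.perf_counter()
    records = _load_corpus(config)
    tick("corpus", t0, len(records))

    if config.contamination is not None:
        t0 = time.perf_counter()
        spec = dataclasses.replace(
            config.contamination, seed=stage_seed(config.master_seed, "contaminate")
        )
        records, _ = inject_contamination(records, spec)
        tick("contaminate", t0, len(records))

    t0 = time.perf_counter()
    clean, filter_report = filter_corpus(records, list(config.explicit_phrases))
    (out_dir / "filter_report.tsv").write_text(filter_report.to_tsv(), encoding="utf-8")
    tick("filter", t0, len(clean))

    t0 = time.perf_counter()
    split = SplitSpec(
        test_counts=config.test_counts,
        test_fraction=config.test_fraction,
        seed=stage_seed(config.master_seed, "split"),
    )
    train, test = stratified_split(clean, split)
    if not train or not test:
        raise ValueError("split produced an empty partition")
    tick("split", t0, len(test))

    t0 = time.perf_counter()
    vectorizer = SoapVectorizer(
        percentile=config.percentile,
        stopwords=config.stopwords,
        stemmer=config.stemmer,
        log_base=config.log_base,
    )
    train_texts = [r.text for r in train]
    train_labels = [r.label for r in train]
    X_train = vectorizer.fit(train_texts, train_labels).transform(train_texts)
    X_test = vectorizer.transform([r.text for r in test])
    vectorizer.save_vocabulary(out_dir / "vocabulary.tsv")
    tick("featurize", t0, len(vectorizer.vocabulary_))

    t0 = time.perf_counter()
    clf = DispositionClassifier(nu=config.nu).fit(X_train, train_labels)
    save_model(clf, vectorizer.vocabulary_, out_dir)
    machine_scores = clf.decision_function(X_test)
    tick("train", t0, clf.n_support_)

    # Simulated physician pairs; each pair is gated on trial-subset kappa
    # before its answers are pooled conservatively.
    t0 = time.perf_counter()
    truth = [r.label for r in test]
    raters = {}
    for group, (sens, spec_) in (
        ("novice", config.novice_rater),
        ("experienced", config.experienced_rater),
    ):
        pair = []
        for k in (1, 2):
            model = RaterModel(
                sensitivity=sens,
                specificity=spec_,
                seed=stage_seed(config.master_seed, f"rater-{group}-{k}"),
            )
            pair.append(np.asarray(simulate_rater(test, model)))
        raters[group] = pair

    trial = _trial_subset(
        test, config.trial_subset_size, stage_seed(config.master_seed, "trial")
    )
    trial_ids = {r.record_id for r in trial}
    trial_mask = np.array([r.record_id in trial_ids for r in test])
    kappas = {}
    group_preds = {}
    for group, (a, b) in raters.items():
        kap = cohens_kappa(a[trial_mask], b[trial_mask])
        kappas[group] = kap
        group_preds[group] = aggregate_conservative(a, b)
    gate_ok = {g: kappas[g].kappa >= config.kappa_gate for g in kappas}
    tick("raters", t0, len(test))

    t0 = time.perf_counter()
    scores = {
        "Machine": np.asarray(machine_scores, dtype=float),
        "Novice Physicians": binary_ratings_as_scores(group_preds["novice"]),
        "Experienced Physicians": binary_ratings_as_scores(group_preds["experienced"]),
    }
    rows = [_accuracy_rows(name, s, truth, config.confidence) for name, s in scores.items()]
    _write_accuracy_tsv(rows, out_dir / "accuracy.tsv")
    for row in rows:
        slug = row["grader"].lower().replace(" ", "_")
        _write_roc_csv(row["roc"], out_dir / f"roc_{slug}.csv")

    names = list(scores)
    delong_lines = ["Comparison\tp-value"]
    delong_results = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = delong_test(scores[names[i]], scores[names[j]], truth)
            delong_results[f"{names[i]} vs. {names[j]}"] = res
            delong_lines.append(f"{names[i]} vs. {names[j]}\t{res.p:.4f}")
    (out_dir / "delong.tsv").write_text("\n".join(delong_lines) + "\n", encoding="utf-8")

    table4 = concordance_table(
        clf.predict(X_test), group_preds["novice"], group_preds["experienced"], truth
    )
    (out_dir / "concordance.tsv").write_text(table4.to_tsv(), encoding="utf-8")
    tick("evaluate", t0, len(test))

    results = {
        "filter_report": filter_report,
        "accuracy": rows,
        "delong": delong_results,
        "concordance": table4,
        "kappa": kappas,
        "kappa_gate_passed": gate_ok,
        "margin_of_error": margin_of_error(len(test), len(clean), config.confidence),
        "machine_auroc": rows[0]["auroc"],
    }

    manifest = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "master_seed": config.master_seed,
        "stage_seeds": {
            s: stage_seed(config.master_seed, s)
            for s in ("generate", "contaminate", "split", "trial")
        },
        "counts": counts,
        "timings_s": timings,
        "machine_auroc": rows[0]["auroc"],
        "kappa": {g: kappas[g].kappa for g in kappas},
        "kappa_gate_passed": gate_ok,
        "margin_of_error": results["margin_of_error"],
    }
    # timings are environment-dependent; keep them out of the hashable body
    manifest_body = {k: v for k, v in manifest.items() if k != "timings_s"}
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest_body, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    return results
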