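"""Evaluation: confusion counts, imbalance-aware metrics and the
four-way experiment grid (T->T, S->T, DRDA, RDRDA).

The positive class is cardiomegaly.  Reported metrics are sensitivity,
specificity, their geometric mean (G-Mean), accuracy, precision, F1 and the
rank-based AUC (Mann-Whitney statistic with half-credit for ties).  G-Mean
is the headline number for imbalanced sets: accuracy alone is biased toward
the majority class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .architectures import EncoderConfig, build_bundle
from .manifest import DatasetManifest
from .objectives import ONE_HOT
from .phantom import read_image
from .preprocess import PreprocessConfig, preprocess_pipeline
from .training import TrainingConfig, fit, predict

POSITIVE = "cardiomegaly"


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    g_mean: float
    accuracy: float
    precision: float
    f1: float
    counts: ConfusionCounts
    auc: float | None = None
    mode: str = ""
    domain: str = ""
    degenerate: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        row = {"mode": self.mode, "domain": self.domain,
               "sensitivity": self.sensitivity, "specificity": self.specificity,
               "g_mean": self.g_mean, "accuracy": self.accuracy,
               "precision": self.precision, "f1": self.f1, "auc": self.auc,
               "tp": self.counts.tp, "fp": self.counts.fp,
               "tn": self.counts.tn, "fn": self.counts.fn}
        return row


def confusion(predicted_labels, true_labels) -> ConfusionCounts:
    """Confusion counts with cardiomegaly as the positive class."""
    if len(predicted_labels) != len(true_labels):
        raise EvaluationError("prediction/label length mismatch")
    tp = fp = tn = fn = 0
    for pred, true in zip(predicted_labels, true_labels):
        if pred not in ONE_HOT or true not in ONE_HOT:
            raise EvaluationError(f"unknown label in ({pred!r}, {true!r})")
        if true == POSITIVE:
            tp += pred == POSITIVE
            fn += pred != POSITIVE
        else:
            tn += pred != POSITIVE
            fp += pred == POSITIVE
    return ConfusionCounts(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))


def _ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts, mode: str = "", domain: str = "") -> MetricsReport:
    """The six printed metrics; zero-denominator cases yield 0 with a flag."""
    if c.total == 0:
        raise EvaluationError("empty evaluation set")
    degenerate: list[str] = []
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity", degenerate)
    spec = _ratio(c.tn, c.tn + c.fp, "specificity", degenerate)
    prec = _ratio(c.tp, c.tp + c.fp, "precision", degenerate)
    acc = (c.tp + c.tn) / c.total
    g_mean = math.sqrt(sens * spec)
    f1 = _ratio(2 * sens * prec, sens + prec, "f1", degenerate)
    return MetricsReport(sensitivity=sens, specificity=spec, g_mean=g_mean,
                         accuracy=acc, precision=prec, f1=f1, counts=c,
                         mode=mode, domain=domain, degenerate=degenerate)


def auc_score(scores, true_labels) -> float:
    """Rank-based AUC (Mann-Whitney) with half-credit for ties."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    pos = np.asarray([t == POSITIVE for t in true_labels])
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("auc_score needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_predictions(probs: np.ndarray, true_labels: list[str],
                         mode: str = "", domain: str = "") -> MetricsReport:
    """Metrics + AUC from positive-class probabilities and true labels."""
    pred = ["cardiomegaly" if p[1] > 0.5 else "normal" for p in probs]
    report = metrics_from_counts(confusion(pred, true_labels), mode=mode, domain=domain)
    if len(set(true_labels)) == 2:
        report.auc = auc_score(probs[:, 1], true_labels)
    return report


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------

def load_split_arrays(manifest: DatasetManifest, split: str,
                      pre_cfg: PreprocessConfig) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read and preprocess one split: (images NHWC, one-hot labels, labels)."""
    sub = manifest.subset(split=split)
    if len(sub) == 0:
        raise EvaluationError(f"split {split!r} is empty")
    images = np.stack([preprocess_pipeline(read_image(p), pre_cfg) for p in sub.paths()])
    labels = sub.labels()
    onehot = np.asarray([ONE_HOT[l] for l in labels], dtype=np.float32)
    return images.astype(np.float32), onehot, labels


def train_and_evaluate(mode: str,
                       source_train: tuple[np.ndarray, np.ndarray],
                       target_train: np.ndarray | None,
                       eval_sets: dict[str, tuple[np.ndarray, list[str]]],
                       encoder_cfg: EncoderConfig,
                       train_cfg: TrainingConfig) -> list[MetricsReport]:
    """Train one mode and evaluate on each named evaluation set.

    ``mode`` is an experiment tag: 't2t' and 's2t' train source-only (on the
    labeled set passed as ``source_train``); 'drda'/'rdrda' additionally use
    the unlabeled ``target_train`` images.
    """
    training_mode = "source_only" if mode in ("t2t", "s2t") else mode
    if train_cfg.mode != training_mode:
        train_cfg = TrainingConfig(mode=training_mode,
                                   learning_rate=train_cfg.learning_rate,
                                   epochs=train_cfg.epochs,
                                   batch_size=train_cfg.batch_size,
                                   seed=train_cfg.seed,
                                   checkpoint_path=train_cfg.checkpoint_path)
    bundle = build_bundle(training_mode, encoder_cfg, seed=train_cfg.seed)
    fit(bundle, source_train, target_train, train_cfg)
    reports = []
    for domain_tag, (images, labels) in eval_sets.items():
        probs = predict(bundle, images)
        reports.append(evaluate_predictions(probs, labels, mode=mode, domain=domain_tag))
    return reports


def run_experiment_grid(source_manifest: DatasetManifest,
                        target_manifest: DatasetManifest,
                        modes: tuple[str, ...] = ("t2t", "s2t", "drda", "rdrda"),
                        encoder_cfg: EncoderConfig | None = None,
                        train_cfg: TrainingConfig | None = None,
                        pre_cfg: PreprocessConfig | None = None,
                        out_dir: str | Path | None = None) -> pd.DataFrame:
    """Train and evaluate the requested experiment modes with shared seeds
    and preprocessing; rows mirror the modes x metrics comparison layout.

    Target-train labels are consumed only by 't2t'; 's2t', 'drda' and
    'rdrda' see the target training images unlabeled.
    """
    encoder_cfg = encoder_cfg or EncoderConfig(head_filters=64, input_side=64)
    train_cfg = train_cfg or TrainingConfig.desk("source_only")
    pre_cfg = pre_cfg or PreprocessConfig(output_side=encoder_cfg.input_side)

    src_train = load_split_arrays(source_manifest, "train", pre_cfg)
    tgt_train = load_split_arrays(target_manifest, "train", pre_cfg)
    src_test = load_split_arrays(source_manifest, "test", pre_cfg)
    tgt_test = load_split_arrays(target_manifest, "test", pre_cfg)

    rows = []
    for mode in modes:
        if mode == "t2t":
            labeled = (tgt_train[0], tgt_train[1])
            unlabeled = None
            eval_sets = {"target_test": (tgt_test[0], tgt_test[2])}
        else:
            labeled = (src_train[0], src_train[1])
            unlabeled = None if mode == "s2t" else tgt_train[0]
            eval_sets = {"target_test": (tgt_test[0], tgt_test[2]),
                         "source_test": (src_test[0], src_test[2])}
        reports = train_and_evaluate(mode, labeled, unlabeled, eval_sets,
                                     encoder_cfg, train_cfg)
        rows.extend(r.as_row() for r in reports)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "comparison.csv", index=False)
        (out_dir / "comparison.json").write_text(
            json.dumps(table.to_dict(orient="records"), indent=2, default=float)
        )
    return table
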