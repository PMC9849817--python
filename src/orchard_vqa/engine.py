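"""Training loop, strict-accuracy evaluation per question type, k-fold
cross-validation, and confusion-matrix statistics."""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .backbones import EncoderContract
from .corpus import QUESTION_TYPES, Manifest, VQARecord, build_answer_vocabulary
from .errors import InvalidInputError
from .image_prep import encode_image, preprocess_image
from .model import ModelConfig, VQAModel
from .nn import AdamW, cross_entropy
from .question_prep import WordPieceVocab, encode_question, tokenize_and_pad

__all__ = [
    "TrainConfig", "EvalReport", "ConfusionStats", "FeatureSet",
    "encode_corpus", "train", "predict", "select_answer", "evaluate",
    "kfold_cross_validate", "partition_folds", "confusion_stats",
    "binary_confusion", "confusion_indicators",
]

INDICATORS = ("sensitivity", "specificity", "precision", "accuracy", "f1")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 64
    max_epochs: int = 50
    patience: int | None = None
    weight_decay: float = 0.0
    seed: int = 0
    refit_on_trainval: bool = False

    def validate(self) -> "TrainConfig":
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 0:
            raise InvalidInputError("rates and sizes must be positive")
        return self


@dataclass
class EvalReport:
    accuracy_overall: float
    accuracy_per_type: dict[str, float]
    n_per_type: dict[str, int]
    epoch_selected: int | None = None


@dataclass
class ConfusionStats:
    rows: list[dict]
    mean: dict[str, float]
    sd: dict[str, float]


# ---------------------------------------------------------------------------
# Feature preparation
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Precomputed per-record model inputs for a list of records."""

    records: list[VQARecord]
    grids: np.ndarray            # (N, P, K)
    q_seqs: np.ndarray           # (N, 26, d)
    q_mask: np.ndarray           # (N, 26)
    labels: np.ndarray           # (N,) index into answer_vocab; -1 if unlabeled
    answer_vocab: list[str]
    word_vocab: WordPieceVocab = field(repr=False, default=None)

    def subset(self, idx) -> "FeatureSet":
        idx = np.asarray(idx, dtype=int)
        return FeatureSet(records=[self.records[i] for i in idx],
                          grids=self.grids[idx], q_seqs=self.q_seqs[idx],
                          q_mask=self.q_mask[idx], labels=self.labels[idx],
                          answer_vocab=self.answer_vocab,
                          word_vocab=self.word_vocab)

    def split(self, name: str) -> "FeatureSet":
        return self.subset([i for i, r in enumerate(self.records)
                            if r.split == name])

    def __len__(self):
        return len(self.records)


def encode_corpus(manifest: Manifest,
                  contract: EncoderContract | None = None,
                  q_mode: str = "tiny", q_dim: int = 16,
                  word_vocab: WordPieceVocab | None = None,
                  image_root: str | Path | None = None,
                  preprocess: bool = True, seed: int = 0) -> FeatureSet:
    """Run every record through the image and question pipelines once."""
    contract = contract or EncoderContract(name="tiny", output_channels=8,
                                           grid_side=2, seed=seed)
    if word_vocab is None:
        texts = [r.question for r in manifest.records if r.split != "test"]
        word_vocab = WordPieceVocab.train(texts)
    answer_vocab = manifest.answer_vocab or build_answer_vocabulary(manifest)
    a_index = {a: i for i, a in enumerate(answer_vocab)}

    grid_cache: dict[str, np.ndarray] = {}
    grids, q_seqs, q_masks, labels = [], [], [], []
    for rec in manifest.records:
        if rec.image_id not in grid_cache:
            path = Path(rec.image_path)
            if image_root is not None and not path.exists():
                path = Path(image_root) / path.name
            img = np.asarray(Image.open(path).convert("RGB"))
            if preprocess:
                img = preprocess_image(img)
            grid_cache[rec.image_id] = encode_image(img, contract).grid
        grids.append(grid_cache[rec.image_id])
        seq = tokenize_and_pad(rec.question, word_vocab)
        qf = encode_question(seq, mode=q_mode, dim=q_dim, seed=seed)
        q_seqs.append(qf.sequence)
        q_masks.append(qf.mask)
        labels.append(a_index.get(rec.label, -1) if rec.answers else -1)
    return FeatureSet(records=list(manifest.records),
                      grids=np.asarray(grids), q_seqs=np.asarray(q_seqs),
                      q_mask=np.asarray(q_masks),
                      labels=np.asarray(labels, dtype=int),
                      answer_vocab=answer_vocab, word_vocab=word_vocab)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _strict_accuracy(model: VQAModel, feats: FeatureSet) -> float:
    if len(feats) == 0:
        return 0.0
    preds = predict(model, feats)
    return float(np.mean(preds == feats.labels))


def train(model: VQAModel, features: FeatureSet, cfg: TrainConfig,
          val_features: FeatureSet | None = None
          ) -> tuple[VQAModel, dict]:
    """Minimize cross-entropy with AdamW; keep the checkpoint of the epoch
    with the best validation strict accuracy (training accuracy when no
    validation features are supplied).

    Returns the trained model and a history dict with per-epoch losses and
    accuracies.  `max_epochs == 0` returns the untrained model and an empty
    history.
    """
    cfg.validate()
    if len(features) == 0:
        raise InvalidInputError("training split is empty")
    if (features.labels < 0).any():
        raise InvalidInputError("training records must be labeled")
    history: dict = {"train_loss": [], "val_accuracy": [], "best_epoch": None}
    if cfg.max_epochs == 0:
        return model, history

    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.learning_rate, betas=cfg.betas,
                weight_decay=cfg.weight_decay)
    monitor = val_features if val_features is not None and len(val_features) \
        else features
    best_acc, best_state, best_epoch = -1.0, None, None
    bad_epochs = 0
    n = len(features)
    for epoch in range(cfg.max_epochs):
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model(features.grids[idx], features.q_seqs[idx],
                           features.q_mask[idx])
            loss = cross_entropy(logits, features.labels[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged at epoch {epoch} "
                                   f"(non-finite loss)")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        model.eval()
        acc = _strict_accuracy(model, monitor)
        history["train_loss"].append(epoch_loss / n)
        history["val_accuracy"].append(acc)
        if acc > best_acc:
            best_acc, best_state, best_epoch = acc, model.state_dict(), epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if cfg.patience is not None and bad_epochs > cfg.patience:
                break
        if acc >= 1.0 and val_features is None:
            break  # training set fully fit; nothing left to improve
    if best_state is not None:
        model.load_state_dict(best_state)
    history["best_epoch"] = best_epoch
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# Prediction and evaluation
# ---------------------------------------------------------------------------

def select_answer(logits: np.ndarray, answer_vocab: list[str],
                  candidates: list[str] | None = None) -> int:
    """Answer index per argmax; in multiple-choice mode the argmax is
    restricted to the record's candidates.  Ties break to the lowest index."""
    logits = np.asarray(logits)
    if candidates is None:
        return int(np.argmax(logits))
    cand_idx = [answer_vocab.index(c) for c in candidates if c in answer_vocab]
    if not cand_idx:
        return int(np.argmax(logits))
    cand_idx = sorted(cand_idx)
    return int(cand_idx[int(np.argmax(logits[cand_idx]))])


def predict(model: VQAModel, feats: FeatureSet,
            multiple_choice: bool = False) -> np.ndarray:
    """Predicted answer indices for every record in `feats`."""
    model.eval()
    logits = model(feats.grids, feats.q_seqs, feats.q_mask).data
    out = np.empty(len(feats), dtype=int)
    for i, rec in enumerate(feats.records):
        cands = rec.candidates if multiple_choice else None
        out[i] = select_answer(logits[i], feats.answer_vocab, cands)
    return out


def evaluate(model: VQAModel, feats: FeatureSet,
             multiple_choice: bool = False,
             epoch_selected: int | None = None) -> EvalReport:
    """Strict accuracy overall and per question type."""
    if len(feats) == 0:
        raise InvalidInputError("cannot evaluate an empty split")
    if (feats.labels < 0).any():
        raise InvalidInputError(
            "split has unlabeled records (label-free test split); use "
            "predict() and export the answers instead")
    preds = predict(model, feats, multiple_choice=multiple_choice)
    correct = preds == feats.labels
    per_type, n_per_type = {}, {}
    for qtype in QUESTION_TYPES:
        sel = np.array([r.question_type == qtype for r in feats.records])
        n_per_type[qtype] = int(sel.sum())
        per_type[qtype] = float(correct[sel].mean()) if sel.any() else float("nan")
    return EvalReport(accuracy_overall=float(correct.mean()),
                      accuracy_per_type=per_type, n_per_type=n_per_type,
                      epoch_selected=epoch_selected)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def partition_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded partition of range(n) into k disjoint, covering, near-equal folds."""
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    if k > n:
        raise InvalidInputError(f"k ({k}) exceeds dataset size ({n})")
    order = np.random.default_rng(seed).permutation(n)
    return [order[i::k] for i in range(k)]


def kfold_cross_validate(features: FeatureSet, model_cfg: ModelConfig,
                         train_cfg: TrainConfig, k: int = 10,
                         runs: int = 10, seed: int = 0
                         ) -> list[list[EvalReport]]:
    """`runs` repetitions of seeded k-fold CV: each fold serves once as the
    test set while the remaining folds train a fresh model."""
    reports: list[list[EvalReport]] = []
    for run in range(runs):
        folds = partition_folds(len(features), k, seed=seed + run)
        run_reports = []
        for fold in folds:
            test_idx = np.sort(fold)
            train_idx = np.sort(np.setdiff1d(np.arange(len(features)), fold))
            model = VQAModel(dataclasses.replace(model_cfg, seed=seed + run))
            cfg = dataclasses.replace(train_cfg, seed=seed + run)
            model, history = train(model, features.subset(train_idx), cfg)
            report = evaluate(model, features.subset(test_idx),
                              epoch_selected=history["best_epoch"])
            run_reports.append(report)
        reports.append(run_reports)
    return reports


# ---------------------------------------------------------------------------
# Confusion statistics
# ---------------------------------------------------------------------------

def binary_confusion(y_true: np.ndarray, y_pred: np.ndarray
                     ) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) counts with 1/'yes' as the positive class."""
    t = np.asarray(y_true).astype(bool)
    p = np.asarray(y_pred).astype(bool)
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))
    return tp, fp, tn, fn


def confusion_indicators(tp: int, fp: int, tn: int, fn: int) -> dict:
    """The five confusion-matrix indicators; zero-denominator entries are None."""
    def ratio(num, den):
        return num / den if den else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    acc = ratio(tp + tn, tp + fp + tn + fn)
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "accuracy": acc, "f1": f1}


def confusion_stats(per_run_results: list) -> ConfusionStats:
    """Aggregate per-run confusion results into mean and sample SD.

    Each element of `per_run_results` is either a `(y_true, y_pred)` pair of
    binary outcome arrays or a pre-computed indicator row (a mapping with any
    subset of the five indicator names).  Undefined indicators are excluded
    from the aggregation with a warning.  SD uses the n-1 denominator.
    """
    rows: list[dict] = []
    for item in per_run_results:
        if isinstance(item, dict):
            rows.append({key: item.get(key) for key in INDICATORS})
        else:
            y_true, y_pred = item
            rows.append(confusion_indicators(*binary_confusion(y_true, y_pred)))
    mean, sd = {}, {}
    for key in INDICATORS:
        vals = [r[key] for r in rows if r.get(key) is not None]
        if len(vals) < len(rows):
            warnings.warn(f"indicator {key!r} undefined in "
                          f"{len(rows) - len(vals)} run(s); excluded from mean",
                          stacklevel=2)
        if not vals:
            mean[key] = sd[key] = float("nan")
            continue
        arr = np.asarray(vals, dtype=np.float64)
        mean[key] = float(arr.mean())
        sd[key] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return ConfusionStats(rows=rows, mean=mean, sd=sd)
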