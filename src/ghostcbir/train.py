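"""Training loop and the 5-fold patient-level cross-validation driver.

Per fold: the classifier (backbone + dropout/linear head) is trained with
Adam and early stopping on validation loss, optionally distilling from an
injected teacher; embeddings are then extracted for the training split to
build the retrieval gallery, and every held-out test slice is used both as a
classification sample and as a retrieval query.  Gallery, train and
validation patients are verified disjoint from test patients before any
metric is computed — a leakage failure aborts the fold with a diagnostic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from . import protocol
from .autodiff import Tensor
from .backbone import Backbone, BackboneSpec, extract_features, toy_backbone_spec, full_backbone_spec
from .layers import Dropout, Linear, Module
from .losses import KDConfig, cross_entropy, softmax, total_loss
from .metrics import (AgreementInput, average_precision, classification_metrics,
                      confusion_matrix, cras, mean_ap, prec_at_k)
from .protocol import (AugmentationConfig, assign_patient_folds, build_fold_splits,
                       preprocess, to_network_input)
from .retrieval import build_gallery, retrieve

__all__ = [
    "TrainConfig", "RunConfig", "Adam", "ClassifierHead", "LeakageError",
    "train_classifier", "predict_logits", "run_cv", "toy_run_config",
]


class LeakageError(RuntimeError):
    """A patient appears on both sides of the gallery/query divide."""


class Adam:
    """Standard Adam with decoupled-free L2 weight decay added to gradients."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class ClassifierHead(Module):
    """Dropout followed by a fully connected layer producing class logits."""

    def __init__(self, embedding_dim: int, n_classes: int = 3,
                 dropout: float = 0.3, rng: np.random.Generator | None = None):
        super().__init__()
        self.dropout = Dropout(dropout)
        self.fc = Linear(embedding_dim, n_classes, rng=rng or np.random.default_rng(0))

    def __call__(self, emb: Tensor) -> Tensor:
        return self.fc(self.dropout(emb))


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    weight_decay: float = 1e-4
    dropout: float = 0.3
    epochs: int = 40
    patience: int = 5       # early stopping, epochs without val-loss improvement
    kd_alpha: float = 0.7
    kd_tau: float = 4.0
    kd_direction: str = "teacher"


@dataclass
class RunConfig:
    """Everything one cross-validation run needs, validated on load."""
    backbone: str = "toy"           # "toy" | "full"
    image_size: int = 32
    n_folds: int = 5
    retrieval_k: int = 30
    retrieval_n: int = 10
    ap_convention: str = "as_reported"
    train: TrainConfig = field(default_factory=TrainConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in ("toy", "full"):
            raise ValueError("backbone must be 'toy' or 'full'")
        if self.ap_convention not in ("as_reported", "as_written"):
            raise ValueError("unknown AP convention")

    def backbone_spec(self) -> BackboneSpec:
        return toy_backbone_spec() if self.backbone == "toy" else full_backbone_spec()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "train" in d and isinstance(d["train"], dict):
            extra = set(d["train"]) - set(TrainConfig.__dataclass_fields__)
            if extra:
                raise ValueError(f"unknown training keys: {sorted(extra)}")
            d["train"] = TrainConfig(**d["train"])
        if "augmentation" in d and isinstance(d["augmentation"], dict):
            extra = set(d["augmentation"]) - set(AugmentationConfig.__dataclass_fields__)
            if extra:
                raise ValueError(f"unknown augmentation keys: {sorted(extra)}")
            d["augmentation"] = AugmentationConfig(**d["augmentation"])
        return cls(**d)


def toy_run_config(seed: int = 0, epochs: int = 10) -> RunConfig:
    """Desk-scale configuration used by the synthetic end-to-end study."""
    return RunConfig(
        backbone="toy",
        image_size=32,
        train=TrainConfig(learning_rate=3e-3, batch_size=16, dropout=0.1,
                          epochs=epochs, patience=5),
        augmentation=AugmentationConfig.flips_only(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _onehot(labels: np.ndarray, classes: list) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)))
    for row, lab in enumerate(labels):
        out[row, index[lab]] = 1.0
    return out


def predict_logits(backbone: Backbone, head: ClassifierHead,
                   images: np.ndarray, batch_size: int = 32) -> np.ndarray:
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 3:
        x = x[:, None]
    backbone.eval()
    head.eval()
    outs = []
    for lo in range(0, len(x), batch_size):
        emb = backbone(Tensor(x[lo:lo + batch_size]))
        outs.append(head(emb).data)
    return np.concatenate(outs)


def train_classifier(backbone: Backbone, head: ClassifierHead,
                     train_images: np.ndarray, train_labels: np.ndarray,
                     val_images: np.ndarray, val_labels: np.ndarray,
                     classes: list, cfg: TrainConfig,
                     rng: np.random.Generator,
                     teacher: Callable[[np.ndarray], np.ndarray] | None = None,
                     augment_cfg: AugmentationConfig | None = None) -> dict:
    """Train with Adam + early stopping; returns a history dict.

    ``train_images``/``val_images`` are float arrays in [0, 1] (N, H, W).
    Augmentation, when configured, is applied to training batches only.
    """
    head.dropout.reseed(rng)
    opt = Adam(list(backbone.parameters()) + list(head.parameters()),
               lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    kd = KDConfig(alpha=cfg.kd_alpha, tau=cfg.kd_tau, direction=cfg.kd_direction)
    y_val = _onehot(val_labels, classes)
    best_loss = np.inf
    best_state = None
    stale = 0
    history = {"train_loss": [], "val_loss": [], "stopped_epoch": None}
    n = len(train_images)
    for epoch in range(cfg.epochs):
        backbone.train()
        head.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            batch = train_images[idx]
            if augment_cfg is not None:
                batch = np.stack([
                    np.clip(protocol.augment(img, augment_cfg, rng), 0.0, 1.0)
                    for img in batch])
            x = batch[:, None]
            y = _onehot(train_labels[idx], classes)
            logits = head(backbone(Tensor(x)))
            t_logits = teacher(x) if teacher is not None else None
            loss = total_loss(logits, t_logits, y, kd)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history["train_loss"].append(epoch_loss / n)
        val_logits = predict_logits(backbone, head, val_images, cfg.batch_size)
        val_loss = float(cross_entropy(softmax(val_logits), y_val).data)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_state = (copy.deepcopy(backbone.named_state()),
                          copy.deepcopy(head.named_state()))
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                history["stopped_epoch"] = epoch + 1
                break
    if best_state is not None:
        backbone.load_state(best_state[0])
        head.load_state(best_state[1])
    return history


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------

def _check_leakage(test_pids: set, other_pids: set):
    shared = test_pids & other_pids
    if shared:
        raise LeakageError(
            f"patients {sorted(shared)} appear in both the query/test split and "
            "the gallery/train/validation side")


def run_cv(records, config: RunConfig,
           teacher: Callable[[np.ndarray], np.ndarray] | None = None) -> dict:
    """Full protocol: patient-level stratified folds, per-fold training,
    train-only gallery construction, test-only queries, and metric aggregation."""
    classes = sorted({r.label for r in records}, key=str)
    assignment = assign_patient_folds(records, k=config.n_folds, seed=config.seed)
    prepared = {r.image_id: to_network_input(preprocess(r.pixels, config.image_size))
                for r in records}
    fold_reports = []
    for fold in range(config.n_folds):
        train_recs, val_recs, test_recs = build_fold_splits(records, assignment, fold)
        _check_leakage({r.patient_id for r in test_recs},
                       {r.patient_id for r in train_recs}
                       | {r.patient_id for r in val_recs})
        rng = np.random.default_rng((config.seed * config.n_folds + fold) % (2 ** 31))
        backbone = Backbone(config.backbone_spec(), seed=int(rng.integers(2 ** 31)))
        head = ClassifierHead(config.backbone_spec().embedding_dim, len(classes),
                              config.train.dropout, rng=rng)
        x_train = np.stack([prepared[r.image_id] for r in train_recs])
        y_train = np.array([r.label for r in train_recs])
        x_val = np.stack([prepared[r.image_id] for r in val_recs])
        y_val = np.array([r.label for r in val_recs])
        x_test = np.stack([prepared[r.image_id] for r in test_recs])
        y_test = np.array([r.label for r in test_recs])
        history = train_classifier(backbone, head, x_train, y_train, x_val, y_val,
                                   classes, config.train, rng, teacher=teacher,
                                   augment_cfg=config.augmentation)
        # classification of the held-out fold
        logits = predict_logits(backbone, head, x_test, config.train.batch_size)
        y_pred = np.array([classes[i] for i in logits.argmax(axis=1)])
        conf = confusion_matrix(y_test, y_pred, classes)
        cls_metrics = classification_metrics(conf)
        # gallery from the training split only; queries from the test split only
        gallery = build_gallery(extract_features(x_train, backbone),
                                y_train, np.array([r.patient_id for r in train_recs]),
                                image_ids=np.array([r.image_id for r in train_recs]))
        _check_leakage({r.patient_id for r in test_recs}, set(gallery.patient_ids))
        q_emb = extract_features(x_test, backbone)
        aps, precs, cras_scores, query_rows = [], [], [], []
        for i in range(len(test_recs)):
            result = retrieve(q_emb[i], gallery, k=config.retrieval_k,
                              n=config.retrieval_n)
            rels = (result.labels == y_test[i]).astype(int)
            precs.append(prec_at_k(rels, len(rels)))
            aps.append(average_precision(rels, len(rels), config.ap_convention))
            cras_scores.append(cras(AgreementInput(y_pred[i], result.labels)))
            query_rows.append({
                "fold": fold, "image_id": test_recs[i].image_id,
                "true_label": str(y_test[i]), "predicted_label": str(y_pred[i]),
                "ap": aps[-1], "prec_at_10": precs[-1], "cras": cras_scores[-1],
            })
        fold_reports.append({
            "fold": fold,
            "n_train": len(train_recs), "n_val": len(val_recs), "n_test": len(test_recs),
            "stopped_epoch": history["stopped_epoch"],
            "epochs_run": len(history["train_loss"]),
            "confusion": conf.tolist(),
            **{k: cls_metrics[k] for k in ("accuracy", "precision", "recall", "f1")},
            "map": mean_ap(aps),
            "prec_at_10": float(np.mean(precs)),
            "cras_mean": float(np.mean(cras_scores)),
            "queries": query_rows,
        })
    summary = {}
    for key in ("accuracy", "precision", "recall", "f1", "map", "prec_at_10", "cras_mean"):
        vals = np.array([f[key] for f in fold_reports])
        summary[f"{key}_mean"] = float(vals.mean())
        summary[f"{key}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return {"folds": fold_reports, "summary": summary,
            "classes": [str(c) for c in classes],
            "config": config.to_dict(), "seed": config.seed}
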