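"""Two-stage contrastive training: representation learning, then a linear head.

Stage 1 trains an encoder plus a two-layer projection head by minimising a
contrastive loss over l2-normalized projections of each mini-batch.  Stage 2
freezes the encoder, discards the projection head, and trains a one-layer
classification head (a single affine map to two logits with softmax) on the
encoder's features using cross-entropy or focal loss.  Because the head is
tiny relative to the encoder, most of the learning happens in stage 1 — the
quality of the learned representation under class imbalance is exactly what
the choice of contrastive loss controls.

The module is organised as a model/results pair:

>>> spec = ScenarioSpec(n_total=400, majority_fraction=0.8, seed=0)
>>> ds = generate(spec)
>>> model = TwoStageClassifier(ds, TwoStageConfig(epochs_stage1=5))
>>> res = model.fit()
>>> counts, scores = res.evaluate()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .classification import binary_cross_entropy, focal_loss, focal_loss_grad_p
from .contrastive import ContrastiveConfig, _value_and_grad_arrays
from .data import LabeledDataset, augment_images
from .metrics import ConfusionCounts, accuracy, confusion_counts, unweighted_accuracy

__all__ = [
    "TwoStageConfig",
    "TwoStageClassifier",
    "TwoStageResults",
    "train_feature_stage",
    "train_classifier_stage",
    "evaluate",
]

#: projection-head presets: desk scale, and the deep-encoder shapes
PROJECTION_PRESETS = {"tiny": (32, 16), "resnet18": (512, 128), "resnet50": (2048, 128)}


@dataclass(frozen=True)
class TwoStageConfig:
    """Hyperparameters for both training stages.

    Defaults follow the reference protocol where one exists: learning rate
    1e-2, batch size 128, Adam, temperature 0.07, 20 stage-1 epochs for a
    small encoder and 10 stage-2 epochs.  Desk-scale encoder and projection
    sizes are the package's own defaults.
    """

    encoder: str = "mlp"  # {"mlp", "cnn"}
    encoder_hidden: tuple[int, ...] = (32,)
    feature_dim: int = 32
    cnn_filters: int = 8
    projection_dims: tuple[int, int] = (32, 16)
    contrastive: ContrastiveConfig = field(default_factory=ContrastiveConfig)
    classifier_loss: str = "ce"  # {"ce", "fl"}
    classifier_gamma: float = 2.0
    epochs_stage1: int = 20
    epochs_stage2: int = 10
    learning_rate: float = 1e-2
    batch_size: int = 128
    optimizer: str = "adam"
    augment: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder not in ("mlp", "cnn"):
            raise ValueError("encoder must be 'mlp' or 'cnn'")
        if self.classifier_loss not in ("ce", "fl"):
            raise ValueError("classifier_loss must be 'ce' or 'fl'")
        if self.epochs_stage1 < 1 or self.epochs_stage2 < 1:
            raise ValueError("epoch counts must be >= 1")
        if self.learning_rate <= 0 or self.batch_size < 2:
            raise ValueError("learning_rate must be > 0 and batch_size >= 2")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")

    def to_flat_dict(self) -> dict:
        d = asdict(self)
        c = d.pop("contrastive")
        d.update({f"contrastive.{k}": v for k, v in c.items()})
        return d

    def save(self, path) -> None:
        """Write a flat, human-readable key=value config file."""
        lines = [f"{k} = {json.dumps(v) if not isinstance(v, tuple) else json.dumps(list(v))}"
                 for k, v in self.to_flat_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "TwoStageConfig":
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            kv[k.strip()] = json.loads(v.strip())
        contrastive = ContrastiveConfig(
            **{k.split(".", 1)[1]: v for k, v in kv.items() if k.startswith("contrastive.")}
        )
        rest = {k: v for k, v in kv.items() if not k.startswith("contrastive.")}
        for tup_key in ("encoder_hidden", "projection_dims"):
            if tup_key in rest:
                rest[tup_key] = tuple(rest[tup_key])
        return cls(contrastive=contrastive, **rest)


def _build_encoder(config: TwoStageConfig, sample_shape: tuple, rng) -> nn.Sequential:
    if config.encoder == "mlp":
        n_in = int(np.prod(sample_shape))
        return nn.build_mlp_encoder(n_in, config.encoder_hidden, config.feature_dim, rng)
    if len(sample_shape) != 2:
        raise ValueError("the cnn encoder expects (H, W) image samples")
    return nn.build_cnn_encoder(sample_shape, config.cnn_filters, config.feature_dim, rng)


def _encode(encoder: nn.Sequential, X: np.ndarray, flatten: bool) -> np.ndarray:
    return encoder.forward(X.reshape(X.shape[0], -1) if flatten else X)


def _iter_batches(n: int, batch_size: int, rng) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


def train_feature_stage(
    dataset: LabeledDataset, config: TwoStageConfig
) -> tuple[nn.Sequential, nn.Sequential, list[float]]:
    """Stage 1: fit encoder + projection head with the configured contrastive loss.

    Returns the encoder, the projection head and the per-epoch mean loss.
    Projections are l2-normalized before the loss, as the loss requires.
    Mini-batches with a single sample are skipped (no pairs to contrast).
    """
    y_train = dataset.y_train
    if np.unique(y_train).size < 2:
        raise ValueError("stage-1 training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    flatten = config.encoder == "mlp"
    encoder = _build_encoder(config, dataset.samples.shape[1:], rng)
    hidden, out = config.projection_dims
    head = nn.build_projection_head(config.feature_dim, hidden, out, rng)
    opt = nn.Adam({**_prefix(encoder.params, "enc"), **_prefix(head.params, "head")},
                  lr=config.learning_rate)
    cc = config.contrastive
    X_train = dataset.X_train
    history: list[float] = []
    for _ in range(config.epochs_stage1):
        epoch_losses = []
        for idx in _iter_batches(len(y_train), config.batch_size, rng):
            if idx.size < 2:
                warnings.warn("skipping a single-sample mini-batch", RuntimeWarning)
                continue
            Xb = X_train[idx]
            if config.augment and Xb.ndim == 3:
                Xb = augment_images(Xb, rng)
            feats = _encode(encoder, Xb, flatten)
            v = head.forward(feats)
            # eps-safe normalization: a transiently dead projection row
            # (all-ReLU-off sample) stays a zero vector instead of aborting
            norms = np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-12)
            z = v / norms
            loss, dz = _value_and_grad_arrays(
                z, y_train[idx], cc.tau, cc.effective_eta, cc.effective_gamma,
                cc.reduction, warn_no_positives=False,
            )
            dv = (dz - z * np.sum(z * dz, axis=1, keepdims=True)) / norms
            dfeat = head.backward(dv)
            encoder.backward(dfeat)
            opt.step({**_prefix(encoder.grads, "enc"), **_prefix(head.grads, "head")})
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)) if epoch_losses else float("nan"))
    return encoder, head, history


def _prefix(d: dict, tag: str) -> dict:
    return {f"{tag}.{k}": v for k, v in d.items()}


def _softmax2_p1(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e[:, 1] / e.sum(axis=1)


def train_classifier_stage(
    encoder: nn.Sequential,
    dataset: LabeledDataset,
    config: TwoStageConfig,
) -> tuple[nn.Dense, list[float]]:
    """Stage 2: frozen encoder, train a one-layer softmax head with CE or FL.

    Only the classifier parameters are updated; the encoder is used purely
    as a feature map.  Returns the head and the per-epoch mean loss.
    """
    rng = np.random.default_rng(config.seed + 1)
    flatten = config.encoder == "mlp"
    clf = nn.Dense(config.feature_dim, 2, rng)
    opt = nn.Adam(clf.params, lr=config.learning_rate)
    gamma = config.classifier_gamma if config.classifier_loss == "fl" else 0.0
    X_train, y_train = dataset.X_train, dataset.y_train
    # features are fixed under a frozen encoder: compute them once
    feats_all = _encode(encoder, X_train, flatten)
    history: list[float] = []
    for _ in range(config.epochs_stage2):
        epoch_losses = []
        for idx in _iter_batches(len(y_train), config.batch_size, rng):
            logits = clf.forward(feats_all[idx])
            p = np.clip(_softmax2_p1(logits), 1e-12, 1 - 1e-12)
            yb = y_train[idx]
            loss = (
                binary_cross_entropy(p, yb)
                if gamma == 0.0
                else focal_loss(p, yb, gamma)
            )
            dLdp = focal_loss_grad_p(p, yb, gamma)
            jac = p * (1.0 - p)
            dlogits = np.stack([-dLdp * jac, dLdp * jac], axis=1)
            clf.backward(dlogits)
            opt.step(clf.grads)
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))
    return clf, history


def evaluate(
    encoder: nn.Sequential,
    clf: nn.Dense,
    X: np.ndarray,
    y: np.ndarray,
    flatten: bool = True,
) -> tuple[ConfusionCounts, dict]:
    """Argmax decisions on encoder features; accuracy and UWA via the metrics module."""
    logits = clf.forward(_encode(encoder, X, flatten))
    pred = logits.argmax(axis=1)
    c = confusion_counts(pred, y)
    return c, {"accuracy": accuracy(c), "uwa": unweighted_accuracy(c)}


class TwoStageClassifier:
    """Two-stage contrastive model over a :class:`LabeledDataset`.

    Parameters
    ----------
    dataset : LabeledDataset
        Samples, labels and a train/test partition; stage fitting uses the
        train partition only.
    config : TwoStageConfig, optional
    """

    def __init__(self, dataset: LabeledDataset, config: TwoStageConfig | None = None):
        self.dataset = dataset
        self.config = config or TwoStageConfig()

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        config: TwoStageConfig | None = None,
        train_fraction: float = 0.7,
        seed: int = 0,
    ) -> "TwoStageClassifier":
        """Build from raw arrays with a stratified train/test split."""
        from .data import stratified_split

        ds = LabeledDataset(
            np.asarray(X), np.asarray(y, dtype=int), np.empty(0, int), np.empty(0, int)
        )
        return cls(stratified_split(ds, train_fraction, seed), config)

    def fit(self, seed: int | None = None) -> "TwoStageResults":
        """Run both training stages; deterministic for a fixed seed."""
        config = self.config if seed is None else replace(self.config, seed=seed)
        encoder, head, hist1 = train_feature_stage(self.dataset, config)
        pre_hash = nn.parameter_hash(encoder.params)
        clf, hist2 = train_classifier_stage(encoder, self.dataset, config)
        post_hash = nn.parameter_hash(encoder.params)
        assert pre_hash == post_hash, "encoder parameters changed during stage 2"
        return TwoStageResults(
            model=self,
            config=config,
            encoder=encoder,
            projection_head=head,
            classifier=clf,
            history={"stage1_loss": hist1, "stage2_loss": hist2},
            encoder_hash=post_hash,
        )


@dataclass
class TwoStageResults:
    """Fitted parameters, training history and evaluation helpers."""

    model: TwoStageClassifier
    config: TwoStageConfig
    encoder: nn.Sequential
    projection_head: nn.Sequential
    classifier: nn.Dense
    history: dict
    encoder_hash: str

    @property
    def _flatten(self) -> bool:
        return self.config.encoder == "mlp"

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Frozen-encoder features for new samples."""
        return _encode(self.encoder, np.asarray(X), self._flatten)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax2_p1(self.classifier.forward(self.encode(X)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.forward(self.encode(X)).argmax(axis=1)

    def evaluate(
        self, X: np.ndarray | None = None, y: np.ndarray | None = None
    ) -> tuple[ConfusionCounts, dict]:
        """Confusion counts + metrics; defaults to the held-out test split."""
        if X is None:
            X, y = self.model.dataset.X_test, self.model.dataset.y_test
        return evaluate(self.encoder, self.classifier, X, y, self._flatten)

    def history_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": 1, "epoch": e + 1, "loss": v}
            for e, v in enumerate(self.history["stage1_loss"])
        ] + [
            {"stage": 2, "epoch": e + 1, "loss": v}
            for e, v in enumerate(self.history["stage2_loss"])
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of statistical model results."""
        c, scores = self.evaluate()
        cc = self.config.contrastive
        lines = [
            "Two-stage contrastive classifier",
            "=" * 40,
            f"contrastive loss      {cc.variant.upper()}  (tau={cc.tau}, eta={cc.effective_eta}, gamma={cc.effective_gamma})",
            f"classifier loss       {self.config.classifier_loss.upper()}"
            + (f" (gamma={self.config.classifier_gamma})" if self.config.classifier_loss == "fl" else ""),
            f"encoder               {self.config.encoder} -> {self.config.feature_dim}-d features",
            f"projection head       {self.config.projection_dims}",
            f"epochs (stage 1 / 2)  {self.config.epochs_stage1} / {self.config.epochs_stage2}",
            f"stage-1 loss          {self.history['stage1_loss'][0]:.4f} -> {self.history['stage1_loss'][-1]:.4f}",
            f"stage-2 loss          {self.history['stage2_loss'][0]:.4f} -> {self.history['stage2_loss'][-1]:.4f}",
            "-" * 40,
            f"test confusion        TP={c.tp} TN={c.tn} FP={c.fp} FN={c.fn}",
            f"test accuracy         {100 * scores['accuracy']:.2f}%",
            f"test UWA              {100 * scores['uwa']:.2f}%",
        ]
        return "\n".join(lines)

    def save(self, run_dir) -> None:
        """Persist config, per-epoch losses, final metrics and parameters."""
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        self.config.save(run_dir / "config.txt")
        self.history_frame().to_csv(run_dir / "history.csv", index=False)
        c, scores = self.evaluate()
        pd.DataFrame(
            [{**scores, "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}]
        ).to_csv(run_dir / "metrics.csv", index=False)
        np.savez(
            run_dir / "parameters.npz",
            **_prefix(self.encoder.params, "enc"),
            **_prefix(self.classifier.params, "clf"),
        )
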