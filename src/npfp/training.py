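"""Training protocol: losses, cross-validation folds, Adam + one-cycle.

Each architecture minimises a composite of binary cross-entropy (for the
classification tasks) and root-mean-squared error (for descriptor
regression):

* baseline — BCE of the NP logit.
* aux — the NP task and each of the ``n_aux`` descriptor tasks contribute
  equally: loss = (1/(1+K)) BCE + (K/(1+K)) mean_d RMSE_d.
* ae — BCE of the NP logit plus a reconstruction term weighted so that the
  NP task and the *total* reconstruction loss stand in a 1:100 ratio;
  with 2048 input bits one NP example then weighs ~20.5x one bit.

Models are trained with Adam under a one-cycle learning-rate schedule and
evaluated by random-split 5-fold cross-validation (80% train / 20%
validation per fold, unstratified).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import DEFAULT_SURFACE_DESCRIPTORS, descriptor_matrix, ecfp4_matrix
from .curation import CuratedDataset
from .errors import ShapeError, TrainingDivergedError
from .network import ModelSpec, Network, sigmoid
from .records import MoleculeRecord

# ---------------------------------------------------------------------------
# losses


def _bce_with_logits(z: np.ndarray, t: np.ndarray) -> float:
    # stable form: max(z,0) - z t + log(1 + exp(-|z|)), averaged
    return float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))


def _bce_grad(z: np.ndarray, t: np.ndarray) -> np.ndarray:
    return (sigmoid(z) - t) / z.size


def composite_loss(outputs: dict[str, np.ndarray],
                   targets: dict[str, np.ndarray],
                   spec: ModelSpec) -> float:
    """Scalar training loss for one batch (see module docstring)."""
    z = np.asarray(outputs["np_logit"], dtype=np.float64)
    t = np.asarray(targets["np"], dtype=np.float64)
    if z.shape != t.shape:
        raise ShapeError(f"np logits {z.shape} vs targets {t.shape}")
    bce = _bce_with_logits(z, t)
    if spec.arch == "baseline":
        return bce
    if spec.arch == "aux":
        pred = np.asarray(outputs["aux"], dtype=np.float64)
        y = np.asarray(targets["aux"], dtype=np.float64)
        if pred.shape != y.shape or pred.shape[1] != spec.n_aux:
            raise ShapeError(f"aux predictions {pred.shape} vs targets {y.shape}")
        rmse_per_task = np.sqrt(np.mean((pred - y) ** 2, axis=0))
        k = spec.n_aux
        return (1.0 / (1 + k)) * bce + (k / (1 + k)) * float(rmse_per_task.mean())
    # ae
    zr = np.asarray(outputs["recon_logit"], dtype=np.float64)
    tr = np.asarray(targets["recon"], dtype=np.float64)
    if zr.shape != tr.shape or zr.shape[1] != spec.input_dim:
        raise ShapeError(f"reconstruction {zr.shape} vs targets {tr.shape}")
    recon = _bce_with_logits(zr, tr)  # mean over all (n x bits) entries
    return bce + spec.ae_recon_weight * recon


def _loss_and_grads(outputs, targets, spec
                    ) -> tuple[float, dict[str, np.ndarray]]:
    """Loss plus gradients w.r.t. the raw head outputs."""
    z = outputs["np_logit"]
    t = np.asarray(targets["np"], dtype=np.float64)
    loss = composite_loss(outputs, targets, spec)
    if spec.arch == "baseline":
        return loss, {"np_logit": _bce_grad(z, t)}
    if spec.arch == "aux":
        pred = outputs["aux"]
        y = targets["aux"]
        k = spec.n_aux
        n = pred.shape[0]
        rmse = np.sqrt(np.mean((pred - y) ** 2, axis=0))
        d_aux = np.where(rmse > 1e-12,
                         (pred - y) / (n * np.maximum(rmse, 1e-12)), 0.0)
        return loss, {"np_logit": _bce_grad(z, t) / (1 + k),
                      "aux": d_aux / (1 + k)}
    zr = outputs["recon_logit"]
    tr = targets["recon"]
    d_recon = spec.ae_recon_weight * (sigmoid(zr) - tr) / zr.size
    return loss, {"np_logit": _bce_grad(z, t), "recon_logit": d_recon}


# ---------------------------------------------------------------------------
# folds


@dataclass(frozen=True)
class FoldSplit:
    """Random record-to-fold assignment for k-fold cross-validation."""

    assignments: dict[str, int]
    k: int
    seed: int

    def fold_ids(self, fold: int) -> set[str]:
        return {rid for rid, f in self.assignments.items() if f == fold}


def make_folds(dataset: CuratedDataset | Sequence[MoleculeRecord],
               k: int = 5, seed: int = 0) -> FoldSplit:
    """Random unstratified split into k folds of near-equal size."""
    records = dataset.records if isinstance(dataset, CuratedDataset) else dataset
    ids = [r.id for r in records]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignments = {ids[int(i)]: int(pos % k) for pos, i in enumerate(order)}
    return FoldSplit(assignments=assignments, k=k, seed=seed)


# ---------------------------------------------------------------------------
# featurization for training


@dataclass
class FeaturizedDataset:
    """ECFP4 inputs, NP labels and raw descriptor targets for a dataset."""

    ids: list[str]
    X: np.ndarray          # (n, input_dim) uint8
    y: np.ndarray          # (n,) 1 = natural product
    descriptors: np.ndarray  # (n, n_desc) unstandardized
    npl: np.ndarray        # (n,) NaN where unknown

    @classmethod
    def from_records(cls, records: Sequence[MoleculeRecord],
                     input_dim: int = 2048,
                     descriptor_set: Sequence[str] = DEFAULT_SURFACE_DESCRIPTORS,
                     ) -> "FeaturizedDataset":
        X = ecfp4_matrix(records, length=input_dim)
        y = np.array([1.0 if r.source_class == "natural" else 0.0
                      for r in records])
        D = descriptor_matrix(records, descriptor_set)
        npl = np.array([r.npl if r.npl is not None else np.nan
                        for r in records])
        return cls(ids=[r.id for r in records], X=X, y=y,
                   descriptors=D, npl=npl)

    @classmethod
    def from_dataset(cls, dataset: CuratedDataset, **kw) -> "FeaturizedDataset":
        return cls.from_records(dataset.records, **kw)


@dataclass
class TrainedModel:
    """A trained network plus the preprocessing state it was fitted with."""

    network: Network
    fold_id: int = 0
    scaler_mean: np.ndarray | None = None  # descriptor standardizer (aux)
    scaler_std: np.ndarray | None = None
    train_metrics: dict = field(default_factory=dict)

    @property
    def spec(self) -> ModelSpec:
        return self.network.spec

    def predict(self, X: np.ndarray) -> dict[str, np.ndarray]:
        """Inference-mode forward pass (running BN statistics, no dropout)."""
        return self.network.forward(np.asarray(X, dtype=np.float64),
                                    train=False)

    def save(self, path: str | Path) -> None:
        arrays = {f"param:{k}": v for k, v in self.network.params.items()}
        arrays.update({f"state:{k}": v for k, v in self.network.state.items()})
        if self.scaler_mean is not None:
            arrays["scaler_mean"] = self.scaler_mean
            arrays["scaler_std"] = self.scaler_std
        meta = {"spec": self.spec.to_dict(), "fold_id": self.fold_id,
                "train_metrics": self.train_metrics}
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(),
                                       dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        net = Network(ModelSpec.from_dict(meta["spec"]))
        for key in data.files:
            if key.startswith("param:"):
                net.params[key[6:]] = data[key]
            elif key.startswith("state:"):
                net.state[key[6:]] = data[key]
        return cls(
            network=net, fold_id=int(meta["fold_id"]),
            scaler_mean=data["scaler_mean"] if "scaler_mean" in data else None,
            scaler_std=data["scaler_std"] if "scaler_std" in data else None,
            train_metrics=meta["train_metrics"],
        )


# ---------------------------------------------------------------------------
# optimization


def one_cycle_lr(step: int, total_steps: int, lr_max: float,
                 pct_start: float = 0.3, div: float = 25.0,
                 final_div: float = 1e4) -> float:
    """One-cycle schedule: cosine ramp to lr_max, cosine anneal to ~0."""
    if total_steps <= 1:
        return lr_max
    up = max(int(round(pct_start * total_steps)), 1)
    if step < up:
        frac = step / up
        lo = lr_max / div
        return lo + (lr_max - lo) * 0.5 * (1 - np.cos(np.pi * frac))
    frac = (step - up) / max(total_steps - up, 1)
    lo = lr_max / final_div
    return lo + (lr_max - lo) * 0.5 * (1 + np.cos(np.pi * frac))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training


def train_fold(data: FeaturizedDataset, split: FoldSplit, fold: int,
               spec: ModelSpec) -> TrainedModel:
    """Train one model on the 4/5 training portion of ``fold``.

    Descriptor targets (aux) are standardized with the training portion's
    mean and SD; the held-out fold reuses that standardizer, so no
    information leaks across the split.  Validation metrics: AUC of the NP
    classification on the held-out fold, and the same AUC restricted to
    molecules with NPL < 0 (the region where the two classes overlap).
    """
    from .evaluation import auc_from_ranking

    val_ids = split.fold_ids(fold)
    val_mask = np.array([rid in val_ids for rid in data.ids])
    train_mask = ~val_mask
    X_tr, y_tr = data.X[train_mask].astype(np.float64), data.y[train_mask]
    X_va, y_va = data.X[val_mask].astype(np.float64), data.y[val_mask]

    scaler_mean = scaler_std = None
    targets_tr: dict[str, np.ndarray] = {"np": y_tr}
    if spec.arch == "aux":
        D_tr = data.descriptors[train_mask]
        scaler_mean = D_tr.mean(axis=0)
        scaler_std = D_tr.std(axis=0)
        scaler_std = np.where(scaler_std > 1e-12, scaler_std, 1.0)
        targets_tr["aux"] = (D_tr - scaler_mean) / scaler_std
    if spec.arch == "ae":
        targets_tr["recon"] = X_tr

    net = Network(spec)
    opt = _Adam(net.params)
    rng = np.random.default_rng((spec.seed * 100003 + fold * 1009 + 1) % (2**31))
    n = X_tr.shape[0]
    batch = min(spec.optimizer.batch_size, n)
    n_batches = int(np.ceil(n / batch))
    total_steps = spec.optimizer.epochs * n_batches
    epoch_losses: list[float] = []
    step = 0
    for _epoch in range(spec.optimizer.epochs):
        order = rng.permutation(n)
        running = 0.0
        for b in range(n_batches):
            idx = order[b * batch:(b + 1) * batch]
            batch_targets = {k: v[idx] for k, v in targets_tr.items()}
            out = net.forward(X_tr[idx], train=True, rng=rng)
            loss, grad_out = _loss_and_grads(out, batch_targets, spec)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at step {step}: {loss}")
            grads = net.backward(grad_out)
            opt.step(net.params, grads,
                     one_cycle_lr(step, total_steps, spec.optimizer.lr_max))
            running += loss * len(idx)
            step += 1
        epoch_losses.append(running / n)

    model = TrainedModel(network=net, fold_id=fold,
                         scaler_mean=scaler_mean, scaler_std=scaler_std)
    scores = model.predict(X_va)["np_logit"]
    metrics: dict[str, float | list[float]] = {
        "epoch_losses": epoch_losses,
        "val_auc": auc_from_ranking(list(zip(scores, y_va > 0.5))),
    }
    npl_va = data.npl[val_mask]
    low = np.isfinite(npl_va) & (npl_va < 0)
    if low.any() and len(set(y_va[low])) == 2:
        metrics["val_auc_npl_lt0"] = auc_from_ranking(
            list(zip(scores[low], y_va[low] > 0.5)))
    model.train_metrics = metrics
    return model


def cross_validate(data: FeaturizedDataset, spec: ModelSpec, k: int = 5,
                   seed: int | None = None
                   ) -> tuple[list[TrainedModel], dict[str, dict[str, float]]]:
    """k-fold cross-validation; returns the k models and metric summaries.

    The summary maps each scalar validation metric to its mean and SD over
    the folds.
    """
    seed = spec.seed if seed is None else seed
    split = make_folds(_id_records(data.ids), k=k, seed=seed)
    models = [train_fold(data, split, fold, spec) for fold in range(k)]
    summary: dict[str, dict[str, float]] = {}
    for key in ("val_auc", "val_auc_npl_lt0"):
        vals = [m.train_metrics[key] for m in models
                if key in m.train_metrics]
        if vals:
            summary[key] = {"mean": float(np.mean(vals)),
                            "sd": float(np.std(vals, ddof=0)),
                            "n_folds": len(vals)}
    return models, summary


def _id_records(ids: Sequence[str]) -> list[MoleculeRecord]:
    return [MoleculeRecord(id=rid, smiles="C") for rid in ids]
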