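"""Feed-forward networks over ECFP4 inputs, implemented in NumPy.

Three architectures share one encoder trunk::

    input -> [linear -> ReLU -> dropout -> batch-norm] x H
          -> linear(fp_dim) -> batch-norm -> Tanh      <- fingerprint layer

The 64-unit Tanh layer is the *fingerprint layer*: its activations are the
dense molecular fingerprint the whole package exists to produce.  On top of
it sits one more linear transformation with a ReLU, then the prediction
heads:

* ``baseline`` — a single natural-product logit.
* ``aux``      — the NP logit plus ``n_aux`` linear regression outputs for
  surface descriptors, forcing the fingerprint to retain structural detail.
* ``ae``       — the NP logit plus a decoder (mirror of the encoder widths)
  that reconstructs the input fingerprint bitwise, autoencoder-style.

All heads emit raw logits; sigmoids are applied at loss / scoring time.
Forward and backward passes are hand-written; parameters live in a flat
name -> array dict, which makes optimizer state and serialization trivial.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DimMismatchError, SpecError

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class OptimizerConfig:
    lr_max: float = 1e-3
    epochs: int = 30
    batch_size: int = 256

    def to_dict(self) -> dict:
        return {"lr_max": self.lr_max, "epochs": self.epochs,
                "batch_size": self.batch_size}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture + training configuration of one network."""

    arch: str = "baseline"  # baseline | aux | ae
    input_dim: int = 2048
    hidden_dims: tuple[int, ...] = (1024, 256)
    fp_dim: int = 64
    dropout: float = 0.2
    n_aux: int = 48
    ae_recon_weight: float = 100.0  # NP-loss : total reconstruction = 1 : this
    seed: int = 0
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)

    def __post_init__(self) -> None:
        if self.arch not in ("baseline", "aux", "ae"):
            raise SpecError(f"unknown architecture {self.arch!r}")
        if self.input_dim <= 0 or self.fp_dim <= 0:
            raise SpecError("dimensions must be positive")
        if any(h <= 0 for h in self.hidden_dims):
            raise SpecError("hidden_dims must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise SpecError("dropout must be in [0, 1)")
        if self.arch == "aux" and self.n_aux <= 0:
            raise SpecError("aux architecture requires n_aux > 0")

    @property
    def output_dim(self) -> int:
        if self.arch == "baseline":
            return 1
        if self.arch == "aux":
            return 1 + self.n_aux
        return 1 + self.input_dim

    def to_dict(self) -> dict:
        return {
            "arch": self.arch, "input_dim": self.input_dim,
            "hidden_dims": list(self.hidden_dims), "fp_dim": self.fp_dim,
            "dropout": self.dropout, "n_aux": self.n_aux,
            "ae_recon_weight": self.ae_recon_weight, "seed": self.seed,
            "optimizer": self.optimizer.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            arch=d["arch"], input_dim=int(d["input_dim"]),
            hidden_dims=tuple(int(h) for h in d["hidden_dims"]),
            fp_dim=int(d["fp_dim"]), dropout=float(d["dropout"]),
            n_aux=int(d["n_aux"]), ae_recon_weight=float(d["ae_recon_weight"]),
            seed=int(d["seed"]),
            optimizer=OptimizerConfig(**d["optimizer"]),
        )


# ---------------------------------------------------------------------------
# layers


class _Linear:
    def __init__(self, params: dict, name: str, n_in: int, n_out: int,
                 rng: np.random.Generator):
        self.name = name
        # He initialization, appropriate for ReLU trunks
        params[f"{name}.W"] = rng.normal(
            0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        params[f"{name}.b"] = np.zeros(n_out)

    def forward(self, params, x, cache):
        cache[self.name] = x
        return x @ params[f"{self.name}.W"] + params[f"{self.name}.b"]

    def backward(self, params, grads, dy, cache):
        x = cache[self.name]
        grads[f"{self.name}.W"] += x.T @ dy
        grads[f"{self.name}.b"] += dy.sum(axis=0)
        return dy @ params[f"{self.name}.W"].T


class _BatchNorm:
    def __init__(self, params: dict, state: dict, name: str, dim: int):
        self.name = name
        params[f"{name}.gamma"] = np.ones(dim)
        params[f"{name}.beta"] = np.zeros(dim)
        state[f"{name}.running_mean"] = np.zeros(dim)
        state[f"{name}.running_var"] = np.ones(dim)

    def forward(self, params, state, x, cache, train: bool):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            n = x.shape[0]
            unbiased = var * n / max(n - 1, 1)
            state[f"{self.name}.running_mean"] = (
                (1 - _BN_MOMENTUM) * state[f"{self.name}.running_mean"]
                + _BN_MOMENTUM * mu)
            state[f"{self.name}.running_var"] = (
                (1 - _BN_MOMENTUM) * state[f"{self.name}.running_var"]
                + _BN_MOMENTUM * unbiased)
        else:
            mu = state[f"{self.name}.running_mean"]
            var = state[f"{self.name}.running_var"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu) * inv_std
        cache[self.name] = (xhat, inv_std)
        return params[f"{self.name}.gamma"] * xhat + params[f"{self.name}.beta"]

    def backward(self, params, grads, dy, cache):
        xhat, inv_std = cache[self.name]
        n = xhat.shape[0]
        gamma = params[f"{self.name}.gamma"]
        grads[f"{self.name}.gamma"] += (dy * xhat).sum(axis=0)
        grads[f"{self.name}.beta"] += dy.sum(axis=0)
        dxhat = dy * gamma
        if not cache["train"]:
            # running statistics are constants: BN is a fixed affine map
            return dxhat * inv_std
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))


# ---------------------------------------------------------------------------
# model


class Network:
    """One instantiated architecture with its parameters and BN state."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.params: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(spec.seed)

        self._enc_linears: list[_Linear] = []
        self._enc_bns: list[_BatchNorm] = []
        widths = [spec.input_dim, *spec.hidden_dims]
        for i, (n_in, n_out) in enumerate(zip(widths[:-1], widths[1:])):
            self._enc_linears.append(
                _Linear(self.params, f"enc{i}", n_in, n_out, rng))
            self._enc_bns.append(
                _BatchNorm(self.params, self.state, f"enc{i}.bn", n_out))
        self._fp_linear = _Linear(self.params, "fp", widths[-1], spec.fp_dim, rng)
        self._fp_bn = _BatchNorm(self.params, self.state, "fp.bn", spec.fp_dim)
        # extra transformation between fingerprint and prediction heads
        self._pred_linear = _Linear(self.params, "pred", spec.fp_dim,
                                    spec.fp_dim, rng)
        self._np_head = _Linear(self.params, "np_head", spec.fp_dim, 1, rng)
        if spec.arch == "aux":
            self._aux_head = _Linear(self.params, "aux_head", spec.fp_dim,
                                     spec.n_aux, rng)
        if spec.arch == "ae":
            self._dec_linears = []
            dec_widths = [spec.fp_dim, *reversed(spec.hidden_dims),
                          spec.input_dim]
            for i, (n_in, n_out) in enumerate(zip(dec_widths[:-1],
                                                  dec_widths[1:])):
                self._dec_linears.append(
                    _Linear(self.params, f"dec{i}", n_in, n_out, rng))

    # -- forward ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
        """Run the network; returns fingerprint and raw head logits.

        Dropout requires ``rng`` when ``train`` is set.  In inference mode
        batch-norm uses running statistics, so outputs are batch-size
        invariant and deterministic.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.spec.input_dim:
            raise DimMismatchError(
                f"expected input (n, {self.spec.input_dim}), got {x.shape}")
        cache: dict = {"train": train}
        h = x
        p = self.spec.dropout
        for i, (lin, bn) in enumerate(zip(self._enc_linears, self._enc_bns)):
            h = lin.forward(self.params, h, cache)
            relu_mask = h > 0
            cache[f"enc{i}.relu"] = relu_mask
            h = h * relu_mask
            if train and p > 0:
                drop = (rng.random(h.shape) >= p) / (1.0 - p)
                cache[f"enc{i}.drop"] = drop
                h = h * drop
            h = bn.forward(self.params, self.state, h, cache, train)
        h = self._fp_linear.forward(self.params, h, cache)
        h = self._fp_bn.forward(self.params, self.state, h, cache, train)
        fingerprint = np.tanh(h)
        cache["fp.tanh"] = fingerprint

        ph = self._pred_linear.forward(self.params, fingerprint, cache)
        pred_mask = ph > 0
        cache["pred.relu"] = pred_mask
        ph = ph * pred_mask
        cache["pred.h"] = ph

        out = {"fingerprint": fingerprint,
               "np_logit": self._np_head.forward(self.params, ph, cache)[:, 0]}
        if self.spec.arch == "aux":
            out["aux"] = self._aux_head.forward(self.params, ph, cache)
        if self.spec.arch == "ae":
            d = fingerprint
            cache["dec.relu"] = []
            for i, lin in enumerate(self._dec_linears):
                d = lin.forward(self.params, d, cache)
                if i < len(self._dec_linears) - 1:
                    mask = d > 0
                    cache["dec.relu"].append(mask)
                    d = d * mask
            out["recon_logit"] = d
        self._cache = cache
        return out

    # -- backward --------------------------------------------------------
    def backward(self, grad_out: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Backpropagate head gradients; returns parameter gradients.

        ``grad_out`` maps ``np_logit`` / ``aux`` / ``recon_logit`` to the
        gradients of the loss w.r.t. those raw outputs, using the shapes
        the forward pass returned.
        """
        cache = self._cache
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}

        d_fp = np.zeros_like(cache["fp.tanh"])

        d_ph = self._np_head.backward(
            self.params, grads, grad_out["np_logit"][:, None], cache)
        if "aux" in grad_out:
            d_ph += self._aux_head.backward(
                self.params, grads, grad_out["aux"], cache)
        d_ph = d_ph * cache["pred.relu"]
        d_fp += self._pred_linear.backward(self.params, grads, d_ph, cache)

        if "recon_logit" in grad_out:
            d = grad_out["recon_logit"]
            for i in range(len(self._dec_linears) - 1, -1, -1):
                if i < len(self._dec_linears) - 1:
                    d = d * cache["dec.relu"][i]
                d = self._dec_linears[i].backward(self.params, grads, d, cache)
            d_fp += d

        dh = d_fp * (1.0 - cache["fp.tanh"] ** 2)
        dh = self._fp_bn.backward(self.params, grads, dh, cache)
        dh = self._fp_linear.backward(self.params, grads, dh, cache)
        for i in range(len(self._enc_linears) - 1, -1, -1):
            dh = self._enc_bns[i].backward(self.params, grads, dh, cache)
            if cache["train"] and self.spec.dropout > 0:
                dh = dh * cache[f"enc{i}.drop"]
            dh = dh * cache[f"enc{i}.relu"]
            dh = self._enc_linears[i].backward(self.params, grads, dh, cache)
        return grads

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {f"param:{k}": v for k, v in self.params.items()}
        arrays.update({f"state:{k}": v for k, v in self.state.items()})
        np.savez(path, spec=np.frombuffer(
            json.dumps(self.spec.to_dict()).encode(), dtype=np.uint8),
            **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        data = np.load(path)
        spec = ModelSpec.from_dict(json.loads(bytes(data["spec"]).decode()))
        net = cls(spec)
        for key in data.files:
            if key.startswith("param:"):
                net.params[key[6:]] = data[key]
            elif key.startswith("state:"):
                net.state[key[6:]] = data[key]
        return net


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)
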