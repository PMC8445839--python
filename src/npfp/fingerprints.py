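"""Neural fingerprints and the neural natural-product score.

The dense fingerprint of a molecule is the activation vector of a trained
network's fingerprint layer (post batch-norm, post Tanh — every entry in
(-1, 1), 64 values by default).  The neural NP score is the raw activation
of the output neuron responsible for the natural-product prediction; its
sigmoid is the model's probability that the molecule is a natural product.
The logit is the default reported scalar: unlike the probability it is not
squashed into (0, 1), so it retains resolution at both ends of the scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import BitFingerprint, ecfp4_matrix
from .errors import DimMismatchError, ParseError
from .network import sigmoid
from .records import MoleculeRecord
from .training import TrainedModel


@dataclass(frozen=True)
class DenseFingerprint:
    """Neural fingerprint of one molecule under one trained model."""

    values: np.ndarray
    model_id: str = ""
    molecule_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=np.float64))


@dataclass(frozen=True)
class NPScore:
    """Raw NP-neuron activation and its sigmoid probability."""

    logit: float
    probability: float


def _as_input(model: TrainedModel, fp: BitFingerprint | np.ndarray) -> np.ndarray:
    bits = fp.bits if isinstance(fp, BitFingerprint) else np.asarray(fp)
    if bits.ndim == 1:
        bits = bits[None, :]
    if bits.shape[1] != model.spec.input_dim:
        raise DimMismatchError(
            f"fingerprint length {bits.shape[1]} != model input "
            f"{model.spec.input_dim}")
    return bits.astype(np.float64)


def extract_fingerprint(model: TrainedModel,
                        fp: BitFingerprint | np.ndarray,
                        molecule_id: str = "") -> DenseFingerprint:
    """Fingerprint-layer activations for one molecule (inference mode)."""
    out = model.predict(_as_input(model, fp))
    return DenseFingerprint(values=out["fingerprint"][0],
                            model_id=model.spec.arch,
                            molecule_id=molecule_id)


def np_score(model: TrainedModel, fp: BitFingerprint | np.ndarray) -> NPScore:
    """Neural natural-product score for one molecule."""
    logit = float(model.predict(_as_input(model, fp))["np_logit"][0])
    return NPScore(logit=logit, probability=float(sigmoid(logit)))


def batch_featurize(
    model: TrainedModel,
    records: Sequence[MoleculeRecord],
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """Fingerprints and NP scores for many molecules.

    Returns ``(fingerprints, scores, failures)``; rows keep the input
    order, a failed record (unparseable SMILES) is collected in
    ``failures`` as ``(id, message)`` rather than aborting the batch.
    """
    ok: list[MoleculeRecord] = []
    failures: list[tuple[str, str]] = []
    for rec in records:
        try:
            ecfp4_matrix([rec], length=model.spec.input_dim)
            ok.append(rec)
        except ParseError as exc:
            failures.append((rec.id, str(exc)))
    if not ok:
        fp_cols = [f"v{i}" for i in range(model.spec.fp_dim)]
        return (pd.DataFrame(columns=["molecule_id", *fp_cols]),
                pd.DataFrame(columns=["molecule_id", "logit", "probability"]),
                failures)
    X = ecfp4_matrix(ok, length=model.spec.input_dim).astype(np.float64)
    out = model.predict(X)
    fp_frame = pd.DataFrame(out["fingerprint"],
                            columns=[f"v{i}" for i in range(model.spec.fp_dim)])
    fp_frame.insert(0, "molecule_id", [r.id for r in ok])
    logits = out["np_logit"]
    score_frame = pd.DataFrame({
        "molecule_id": [r.id for r in ok],
        "logit": logits,
        "probability": sigmoid(logits),
    })
    return fp_frame, score_frame, failures


def fingerprint_matrix(model: TrainedModel,
                       records: Sequence[MoleculeRecord]) -> np.ndarray:
    """(n, fp_dim) dense fingerprints in record order; raises on bad SMILES."""
    X = ecfp4_matrix(records, length=model.spec.input_dim).astype(np.float64)
    return model.predict(X)["fingerprint"]
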