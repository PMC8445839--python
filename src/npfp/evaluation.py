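"""Similarity-search validation: ranking metrics and screening protocols.

Three protocols are covered:

* 1-nn identification — classify each molecule by the label of its single
  most similar neighbour, 10-fold cross-validated (NP-vs-synthetic task).
* per-target similarity search — each active is used once as the query
  against the remaining molecules of its target; performance is the ROC
  AUC of the similarity ranking and the enrichment factor in the top 1%.
* the mixed benchmark pre-filter — drop natural products whose NPL score
  exceeds a threshold, so the search cannot succeed by NP-likeness alone.

AUC is computed as the Mann-Whitney concordance probability with the 1/2
tie convention, so it is independent of how ties are ordered in the
ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .chem import cosine_matrix, ecfp4_matrix, tanimoto_matrix
from .errors import (
    DegenerateLabelsError,
    NoActivesError,
    TargetTooSmallError,
)
from .nplikeness import FragmentFrequencyTable, npl_score
from .records import MoleculeRecord


@dataclass
class SearchResult:
    """One query's ranked library with activity flags."""

    query_id: str
    ranked: list[tuple[str, float, bool]]  # (molecule_id, similarity, is_active)

    def __post_init__(self) -> None:
        sims = [s for _, s, _ in self.ranked]
        if any(b > a + 1e-12 for a, b in zip(sims, sims[1:])):
            raise ValueError("ranked similarities must be non-increasing")
        if any(mid == self.query_id for mid, _, _ in self.ranked):
            raise ValueError("query must not appear in its own ranking")


@dataclass
class TargetMetrics:
    auc_mean: float
    auc_sd: float
    ef1_mean: float
    ef1_sd: float
    n_queries: int


@dataclass
class ScreenReport:
    """Per-target and overall AUC / EF of a similarity-search experiment."""

    per_target: dict[str, TargetMetrics]
    overall: TargetMetrics
    fraction: float = 0.01

    def to_dict(self) -> dict:
        def tm(m: TargetMetrics) -> dict:
            return {"auc_mean": m.auc_mean, "auc_sd": m.auc_sd,
                    "ef1_mean": m.ef1_mean, "ef1_sd": m.ef1_sd,
                    "n_queries": m.n_queries}
        return {"fraction": self.fraction,
                "per_target": {k: tm(v) for k, v in self.per_target.items()},
                "overall": tm(self.overall)}


# ---------------------------------------------------------------------------
# metrics


def auc_from_ranking(labels_with_scores: Sequence[tuple[float, bool]]) -> float:
    """ROC AUC of a scored binary labelling (Mann-Whitney concordance).

    Ties in score contribute 1/2 per active-inactive pair, which is the
    trapezoidal area under the ROC curve.
    """
    scores = np.array([s for s, _ in labels_with_scores], dtype=np.float64)
    labels = np.array([bool(a) for _, a in labels_with_scores])
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("need at least one active and one inactive")
    ranks = rankdata(scores)  # average ranks implement the 1/2 tie rule
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def enrichment_factor(result: SearchResult, fraction: float = 0.01) -> float:
    """Active-rate in the top ``fraction`` of the ranking over the base rate.

    The window holds ceil(fraction * N) molecules, never zero.  EF is
    bounded above by 1/fraction.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n = len(result.ranked)
    if n == 0:
        raise NoActivesError("empty ranking")
    n_active = sum(1 for _, _, a in result.ranked if a)
    if n_active == 0:
        raise NoActivesError("ranking contains no active molecule")
    top = math.ceil(fraction * n)
    hits = sum(1 for _, _, a in result.ranked[:top] if a)
    return (hits / top) / (n_active / n)


# ---------------------------------------------------------------------------
# 1-nn identification


def knn_identification_cv(
    fps: np.ndarray,
    labels: Sequence[bool],
    k: int = 1,
    folds: int = 10,
    metric: str = "cosine",
    seed: int = 0,
) -> float:
    """Mean AUC of 1-nn classification over ``folds``-fold CV.

    Each held-out molecule is scored by its nearest training neighbour's
    label (1 = positive class); ``metric`` is ``cosine`` for dense
    fingerprints or ``tanimoto`` for bit fingerprints.  Neighbour ties are
    resolved toward the lowest input index (deterministic).
    """
    fps = np.asarray(fps, dtype=np.float64)
    y = np.asarray([bool(l) for l in labels])
    if y.sum() < folds or (~y).sum() < folds:
        raise DegenerateLabelsError(
            f"need at least {folds} examples per class")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    fold_of = np.empty(len(y), dtype=int)
    fold_of[order] = np.arange(len(y)) % folds
    sim_fn = cosine_matrix if metric == "cosine" else tanimoto_matrix
    aucs = []
    for f in range(folds):
        test = fold_of == f
        sims = sim_fn(fps[test], fps[~test])
        # argmax returns the first (lowest-index) maximum: the tie rule
        nn = np.argmax(sims, axis=1)
        scores = y[~test][nn].astype(float)
        aucs.append(auc_from_ranking(list(zip(scores, y[test]))))
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# per-target similarity search


def rank_library(query_id: str, sims: np.ndarray, ids: Sequence[str],
                 active: Sequence[bool]) -> SearchResult:
    """Build a SearchResult from similarities (stable sort breaks ties)."""
    order = np.argsort(-np.asarray(sims), kind="stable")
    ranked = [(ids[int(i)], float(sims[int(i)]), bool(active[int(i)]))
              for i in order]
    return SearchResult(query_id=query_id, ranked=ranked)


def per_target_screen(
    benchmark: Sequence[MoleculeRecord],
    featurizer: Callable[[Sequence[MoleculeRecord]], np.ndarray],
    metric: str = "auto",
    fraction: float = 0.01,
) -> ScreenReport:
    """Query-wise similarity search per target, aggregated per protocol.

    Every active molecule of a target serves once as the query; the rest of
    that target's table (actives and inactives, query excluded) is the
    library.  AUC and EF are averaged over queries within a target, then
    over targets for the overall row.  ``metric='auto'`` picks Tanimoto for
    0/1-valued feature matrices and cosine otherwise.
    """
    by_target: dict[str, list[MoleculeRecord]] = {}
    for rec in benchmark:
        by_target.setdefault(rec.target_id or "default", []).append(rec)

    per_target: dict[str, TargetMetrics] = {}
    for target, records in sorted(by_target.items()):
        feats = np.asarray(featurizer(records), dtype=np.float64)
        active = np.array([r.activity == "active" for r in records])
        if active.sum() < 2:
            raise TargetTooSmallError(
                f"target {target} needs >=2 actives, has {int(active.sum())}")
        if metric == "auto":
            use = "tanimoto" if np.isin(feats, (0.0, 1.0)).all() else "cosine"
        else:
            use = metric
        sim_fn = tanimoto_matrix if use == "tanimoto" else cosine_matrix
        ids = [r.id for r in records]
        aucs, efs = [], []
        for qi in np.nonzero(active)[0]:
            lib_mask = np.ones(len(records), dtype=bool)
            lib_mask[qi] = False
            sims = sim_fn(feats[qi][None, :], feats[lib_mask])[0]
            result = rank_library(ids[int(qi)], sims,
                                  [i for i, m in zip(ids, lib_mask) if m],
                                  active[lib_mask])
            aucs.append(auc_from_ranking(
                [(s, a) for _, s, a in result.ranked]))
            efs.append(enrichment_factor(result, fraction))
        per_target[target] = TargetMetrics(
            auc_mean=float(np.mean(aucs)), auc_sd=float(np.std(aucs)),
            ef1_mean=float(np.mean(efs)), ef1_sd=float(np.std(efs)),
            n_queries=len(aucs))

    vals = list(per_target.values())
    overall = TargetMetrics(
        auc_mean=float(np.mean([t.auc_mean for t in vals])),
        auc_sd=float(np.mean([t.auc_sd for t in vals])),
        ef1_mean=float(np.mean([t.ef1_mean for t in vals])),
        ef1_sd=float(np.mean([t.ef1_sd for t in vals])),
        n_queries=sum(t.n_queries for t in vals))
    return ScreenReport(per_target=per_target, overall=overall,
                        fraction=fraction)


def npl_prefilter(records: Sequence[MoleculeRecord],
                  table: FragmentFrequencyTable | None = None,
                  threshold: float = 1.0) -> list[MoleculeRecord]:
    """Drop natural-class records with NPL strictly above ``threshold``.

    Guards the mixed benchmark against being solvable by NP-likeness
    alone.  Synthetic records pass through untouched; records without a
    stored score are scored with ``table`` on the fly.
    """
    out = []
    for rec in records:
        if rec.source_class != "natural":
            out.append(rec)
            continue
        score = rec.npl
        if score is None:
            if table is None:
                raise ValueError(f"record {rec.id} has no NPL and no table given")
            score = npl_score(rec, table)
        if score <= threshold:
            out.append(rec)
    return out


def ecfp4_featurizer(length: int = 2048
                     ) -> Callable[[Sequence[MoleculeRecord]], np.ndarray]:
    """Featurizer closure computing raw ECFP4 matrices (the classical baseline)."""
    def _feat(records: Sequence[MoleculeRecord]) -> np.ndarray:
        return ecfp4_matrix(records, length=length).astype(np.float64)
    return _feat


def neural_featurizer(model) -> Callable[[Sequence[MoleculeRecord]], np.ndarray]:
    """Featurizer closure producing dense neural fingerprints of a model."""
    from .fingerprints import fingerprint_matrix

    def _feat(records: Sequence[MoleculeRecord]) -> np.ndarray:
        return fingerprint_matrix(model, records)
    return _feat
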