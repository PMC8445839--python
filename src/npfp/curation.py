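"""Training-set curation: filtering, decoy mining, exclusion screening.

The training task is to tell natural products (NPs) apart from synthetic
molecules that *look* like NPs.  Decoys are therefore mined from a
synthetic library by ECFP4/Tanimoto similarity search around each NP
query, keeping only library molecules that are at least ``min_sim`` similar
to the query (so the classification stays hard) yet score below
``npl_max`` on the fragment-based NPL scale (so no mislabelled natural
material enters the negative class), capped at the ``top_k`` most similar
per query (so popular chemotypes do not dominate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chem import canonicalize, ecfp4_matrix, tanimoto_matrix
from .errors import EmptyDatasetError, ParseError, ScoreUndefinedError
from .nplikeness import FragmentFrequencyTable, npl_score
from .records import MoleculeRecord


@dataclass(frozen=True)
class CurationParams:
    min_sim: float = 0.5
    npl_max: float = 0.0
    top_k: int = 10
    fp_length: int = 2048
    strip_library_stereo: bool = True

    def to_dict(self) -> dict:
        return {
            "min_sim": self.min_sim,
            "npl_max": self.npl_max,
            "top_k": self.top_k,
            "fp_length": self.fp_length,
            "strip_library_stereo": self.strip_library_stereo,
        }


@dataclass
class Provenance:
    """Which NP query a decoy was mined for, and at what similarity."""

    query_id: str
    similarity: float


@dataclass
class CuratedDataset:
    """NPs plus mined decoys, with decoy provenance and the parameters used."""

    records: list[MoleculeRecord]
    provenance: dict[str, Provenance]
    params: CurationParams

    @property
    def naturals(self) -> list[MoleculeRecord]:
        return [r for r in self.records if r.source_class == "natural"]

    @property
    def synthetics(self) -> list[MoleculeRecord]:
        return [r for r in self.records if r.source_class == "synthetic"]

    def write(self, directory: str | Path) -> None:
        from .records import write_molecules

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_molecules(self.records, directory / "dataset.csv")
        prov = {k: {"query_id": v.query_id, "similarity": v.similarity}
                for k, v in self.provenance.items()}
        (directory / "provenance.json").write_text(json.dumps(prov, indent=1))
        (directory / "curation_config.json").write_text(
            json.dumps(self.params.to_dict(), indent=1))


def filter_parseable(
    records: Sequence[MoleculeRecord],
    table: FragmentFrequencyTable | None = None,
    strip_stereo: bool = False,
) -> tuple[list[MoleculeRecord], list[tuple[str, str]]]:
    """Keep canonicalizable, unique, NPL-scorable molecules.

    Returns ``(kept, rejected)`` where each rejection is ``(id, reason)``
    with reason in {"parse", "duplicate", "npl"}.  Kept records carry their
    canonical SMILES; order is preserved and the first of any duplicate
    pair wins.  NPL-scorability is only checked when a fragment table is
    supplied.
    """
    kept: list[MoleculeRecord] = []
    rejected: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        try:
            smiles = canonicalize(rec.smiles, strip_stereo=strip_stereo)
        except ParseError:
            rejected.append((rec.id, "parse"))
            continue
        if smiles in seen:
            rejected.append((rec.id, "duplicate"))
            continue
        if table is not None:
            try:
                npl_score(smiles, table)
            except ScoreUndefinedError:
                rejected.append((rec.id, "npl"))
                continue
        seen.add(smiles)
        kept.append(rec.with_smiles(smiles))
    return kept, rejected


class FingerprintIndex:
    """Exact exhaustive Tanimoto search over a fingerprint library.

    Deliberately brute-force: exactness is the contract at this scale, and
    the interface (``search`` returning (positions, similarities) sorted by
    descending similarity) is what a faster backend would plug into.
    """

    def __init__(self, records: Sequence[MoleculeRecord], fp_length: int = 2048):
        self.records = list(records)
        self.fp_length = fp_length
        self._bits = ecfp4_matrix(self.records, length=fp_length)

    def search(self, query: MoleculeRecord, min_sim: float = 0.0
               ) -> tuple[np.ndarray, np.ndarray]:
        qbits = ecfp4_matrix([query], length=self.fp_length)
        sims = tanimoto_matrix(qbits, self._bits)[0]
        mask = sims >= min_sim
        pos = np.nonzero(mask)[0]
        # stable sort keeps input order among exact ties
        order = np.argsort(-sims[pos], kind="stable")
        pos = pos[order]
        return pos, sims[pos]


def mine_decoys(
    query: MoleculeRecord,
    library_index: FingerprintIndex,
    table: FragmentFrequencyTable,
    min_sim: float = 0.5,
    npl_max: float = 0.0,
    top_k: int = 10,
) -> list[tuple[MoleculeRecord, float]]:
    """Similarity-matched decoys for one NP query.

    Returns up to ``top_k`` library molecules with Tanimoto >= ``min_sim``
    to the query and NPL strictly below ``npl_max``, ordered by descending
    similarity.  Molecules that meet the similarity bar but fail the NPL
    gate are skipped and do not count toward ``top_k``.
    """
    pos, sims = library_index.search(query, min_sim=min_sim)
    out: list[tuple[MoleculeRecord, float]] = []
    for p, sim in zip(pos, sims):
        rec = library_index.records[int(p)]
        npl = rec.npl if rec.npl is not None else npl_score(rec, table)
        if npl < npl_max:
            out.append((rec, float(sim)))
            if len(out) == top_k:
                break
    return out


def screen_exclusions(
    candidates: Sequence[MoleculeRecord],
    exclusion_sets: Sequence[Iterable[str]],
) -> list[MoleculeRecord]:
    """Drop candidates whose canonical SMILES occurs in any exclusion set."""
    excluded: set[str] = set()
    for exc in exclusion_sets:
        excluded.update(exc)
    return [r for r in candidates if r.smiles not in excluded]


def assemble_training_set(
    np_records: Sequence[MoleculeRecord],
    syn_library: Sequence[MoleculeRecord],
    table: FragmentFrequencyTable,
    params: CurationParams = CurationParams(),
    exclusion_sets: Sequence[Iterable[str]] = (),
) -> CuratedDataset:
    """End-to-end curation: filter, mine decoys per NP, dedupe, exclude.

    Decoys duplicated across queries keep a single record whose provenance
    points at the highest-similarity query (ties broken by smallest query
    id), so the output is invariant to the order of ``np_records`` up to
    that rule.
    """
    nps, _ = filter_parseable(np_records, table)
    lib, _ = filter_parseable(syn_library, table,
                              strip_stereo=params.strip_library_stereo)
    if not nps:
        raise EmptyDatasetError("no parseable natural products")
    lib = [r.with_npl(npl_score(r, table)) if r.npl is None else r for r in lib]
    index = FingerprintIndex(lib, fp_length=params.fp_length)

    best: dict[str, tuple[MoleculeRecord, Provenance]] = {}
    for query in nps:
        for rec, sim in mine_decoys(query, index, table,
                                    min_sim=params.min_sim,
                                    npl_max=params.npl_max,
                                    top_k=params.top_k):
            key = rec.smiles
            prov = Provenance(query_id=query.id, similarity=sim)
            if key not in best:
                best[key] = (rec, prov)
            else:
                cur = best[key][1]
                if prov.similarity > cur.similarity or (
                        prov.similarity == cur.similarity
                        and prov.query_id < cur.query_id):
                    best[key] = (rec, prov)

    decoys = [rec for rec, _ in best.values()]
    decoys = screen_exclusions(decoys, exclusion_sets)
    np_smiles = {r.smiles for r in nps}
    decoys = [r for r in decoys if r.smiles not in np_smiles]
    kept_smiles = {r.smiles for r in decoys}
    provenance = {rec.id: prov for rec, prov in best.values()
                  if rec.smiles in kept_smiles}
    if not decoys:
        raise EmptyDatasetError("no decoys passed the similarity and NPL gates")

    records = (
        [MoleculeRecord(id=r.id, smiles=r.smiles, source_class="natural",
                        activity=r.activity, target_id=r.target_id, npl=r.npl)
         for r in nps]
        + [MoleculeRecord(id=r.id, smiles=r.smiles, source_class="synthetic",
                          activity=r.activity, target_id=r.target_id, npl=r.npl)
           for r in sorted(decoys, key=lambda r: r.id)]
    )
    return CuratedDataset(records=records, provenance=provenance, params=params)


def audit_dataset(dataset: CuratedDataset,
                  table: FragmentFrequencyTable) -> list[str]:
    """Recompute every curation invariant from scratch; return violations.

    Checks: no duplicate canonical SMILES; every decoy's provenance
    similarity is >= min_sim and matches an exact Tanimoto recomputation;
    every decoy's NPL < npl_max; at most top_k decoys per query.
    """
    from .chem import ecfp4, tanimoto

    problems: list[str] = []
    seen: set[str] = set()
    for r in dataset.records:
        canon = canonicalize(r.smiles)
        if canon in seen:
            problems.append(f"duplicate SMILES {canon}")
        seen.add(canon)
    by_id = {r.id: r for r in dataset.records}
    per_query: dict[str, int] = {}
    for decoy_id, prov in dataset.provenance.items():
        decoy = by_id[decoy_id]
        query = by_id[prov.query_id]
        per_query[prov.query_id] = per_query.get(prov.query_id, 0) + 1
        sim = tanimoto(ecfp4(decoy, length=dataset.params.fp_length),
                       ecfp4(query, length=dataset.params.fp_length))
        if abs(sim - prov.similarity) > 1e-9:
            problems.append(f"{decoy_id}: stored similarity {prov.similarity} "
                            f"!= recomputed {sim}")
        if sim < dataset.params.min_sim:
            problems.append(f"{decoy_id}: similarity {sim} below threshold")
        if npl_score(decoy, table) >= dataset.params.npl_max:
            problems.append(f"{decoy_id}: NPL gate violated")
    for qid, n in per_query.items():
        if n > dataset.params.top_k:
            problems.append(f"query {qid} has {n} decoys > top_k")
    return problems
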