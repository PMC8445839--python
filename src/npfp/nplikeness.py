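"""Fragment-frequency natural-product-likeness (NPL) scoring.

The scorer follows the classic Ertl scheme: atom-centered circular
fragments (Morgan environments, radii 0..R) are counted in a
natural-product reference set and a synthetic reference set; each
fragment's contribution is the clipped log10 ratio of its relative
frequencies in the two sets, Laplace-smoothed; a molecule's score is the
mean contribution over its fragment multiset.  Positive scores mean
NP-like chemistry, negative scores synthetic-like.

Scores are comparable only within a single table — no rescaling to any
published numeric range is attempted, so thresholds (such as the 0 used to
gate decoys or the 1 used to pre-filter easy benchmarks) are parameters of
the operations that consume them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit.Chem import rdFingerprintGenerator

from .chem import mol_from_smiles
from .errors import EmptyReferenceError, ScoreUndefinedError
from .records import MoleculeRecord

_FORMAT_VERSION = 1


def molecule_fragments(smiles: str, radius: int = 2) -> dict[int, int]:
    """Multiset of Morgan-environment fragment keys (radii 0..radius)."""
    mol = mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    counts = gen.GetSparseCountFingerprint(mol).GetNonzeroElements()
    return {int(k): int(v) for k, v in counts.items()}


@dataclass
class FragmentFrequencyTable:
    """Per-fragment occurrence counts in NP vs synthetic reference sets."""

    counts: dict[int, tuple[int, int]]  # fragment key -> (n_np, n_syn)
    totals: tuple[int, int]             # (N_np, N_syn) = molecules per class
    radius: int = 2
    pseudocount: float = 1.0
    clip: float = 3.0

    def swap(self) -> "FragmentFrequencyTable":
        """Exchange the roles of the two reference sets (negates scores)."""
        return FragmentFrequencyTable(
            counts={k: (s, n) for k, (n, s) in self.counts.items()},
            totals=(self.totals[1], self.totals[0]),
            radius=self.radius,
            pseudocount=self.pseudocount,
            clip=self.clip,
        )

    # -- persistence (versioned JSON) ------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": _FORMAT_VERSION,
            "radius": self.radius,
            "pseudocount": self.pseudocount,
            "clip": self.clip,
            "totals": list(self.totals),
            "counts": {str(k): list(v) for k, v in self.counts.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FragmentFrequencyTable":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unsupported fragment-table format version")
        return cls(
            counts={int(k): (int(v[0]), int(v[1]))
                    for k, v in payload["counts"].items()},
            totals=(int(payload["totals"][0]), int(payload["totals"][1])),
            radius=int(payload["radius"]),
            pseudocount=float(payload["pseudocount"]),
            clip=float(payload["clip"]),
        )


def build_fragment_table(
    np_set: Sequence[MoleculeRecord],
    syn_set: Sequence[MoleculeRecord],
    radius: int = 2,
    pseudocount: float = 1.0,
    clip: float = 3.0,
) -> FragmentFrequencyTable:
    """Count circular fragments per reference class.

    A fragment occurring k times in one molecule contributes k to that
    class's count; totals record the number of molecules per class.
    """
    if not np_set or not syn_set:
        raise EmptyReferenceError("both reference sets must be nonempty")
    counts: dict[int, list[int]] = {}
    for records, slot in ((np_set, 0), (syn_set, 1)):
        for rec in records:
            for key, k in molecule_fragments(rec.smiles, radius).items():
                counts.setdefault(key, [0, 0])[slot] += k
    return FragmentFrequencyTable(
        counts={k: (v[0], v[1]) for k, v in counts.items()},
        totals=(len(np_set), len(syn_set)),
        radius=radius,
        pseudocount=pseudocount,
        clip=clip,
    )


def fragment_contribution(key: int, table: FragmentFrequencyTable) -> float:
    """Clipped log10 frequency ratio of one fragment.

    clip( log10( ((n_np + a)/N_np) / ((n_syn + a)/N_syn) ), -clip, clip )
    with pseudocount a; unseen fragments use n = 0.
    """
    n_np, n_syn = table.counts.get(key, (0, 0))
    a = table.pseudocount
    n_total_np, n_total_syn = table.totals
    ratio = ((n_np + a) / n_total_np) / ((n_syn + a) / n_total_syn)
    return float(np.clip(np.log10(ratio), -table.clip, table.clip))


def npl_score(record: MoleculeRecord | str,
              table: FragmentFrequencyTable) -> float:
    """Mean fragment contribution over the molecule's fragment multiset."""
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    frags = molecule_fragments(smiles, table.radius)
    if not frags:
        raise ScoreUndefinedError(f"molecule {smiles!r} yields no fragments")
    total = 0.0
    weight = 0
    for key, k in frags.items():
        total += k * fragment_contribution(key, table)
        weight += k
    return total / weight


def score_records(records: Iterable[MoleculeRecord],
                  table: FragmentFrequencyTable) -> list[MoleculeRecord]:
    """Return copies of the records with their ``npl`` field populated."""
    return [r.with_npl(npl_score(r, table)) for r in records]
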