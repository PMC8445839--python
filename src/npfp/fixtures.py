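"""Deterministic generator of NP-like / synthetic-like molecule fixtures.

Molecules are assembled from two fragment grammars — SMILES templates with
substitution slots filled from curated substituent pools — and validated
with RDKit, so every generated structure parses and canonicalizes.

* The *NP grammar* combines fused saturated ring cores (decalin,
  hydrindane, pyranose, lactone, terpene-like bridged systems) with
  sp3-rich, oxygen-rich substituents: rigid, saturated, oxygenated
  chemistry.
* The *synthetic grammar* mixes two populations: flat aromatic amide /
  sulfonamide drug-like chemistry, and "decoy-like" molecules that reuse
  the NP ring cores but carry synthetic decorations (halogens, nitriles,
  sulfonyl and aryl groups).  The second population is what makes
  similarity-matched decoy mining possible on fixtures: it is structurally
  close to the NP class while its fragment statistics lean synthetic.

The two grammars differ *structurally*, not by label noise, so class
separability in downstream tests is a constructed property of the data.
Generation is a pure function of (n, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import canonicalize, sp3_carbon_fraction
from .errors import ParseError
from .records import MoleculeRecord

# -- NP grammar -------------------------------------------------------------

NP_CORES: tuple[str, ...] = (
    "C1CCC2CCCCC2C1",              # decalin
    "C1CCC2CCCC2C1",               # hydrindane
    "OC1OC(CO)C(O)C(O)C1O",        # pyranose
    "O=C1CCCCO1",                  # delta-lactone
    "CC1(C)C2CCC1(C)CC2",          # pinane-like bridged bicycle
    "C1CC2CCC3CCCC3C2C1",          # linear tricycle
    "O1CCC2CCCCC21",               # spiro/fused oxacycle
    "CC1CCC2C(C)CCCC2C1",          # dimethyl decalin
)

NP_SUBS: tuple[str, ...] = (
    "", "(C)", "(O)", "(CO)", "(CC)", "(C(C)O)", "(CCO)", "(OC(C)=O)",
    "(C(C)(C)O)", "(CC(C)O)",
)

# -- synthetic grammar -------------------------------------------------------

AROMATIC_TEMPLATES: tuple[str, ...] = (
    "c1cc({0})cc({1})c1",
    "c1ccc(-c2ccc({0})cc2{1})cc1",
    "O=C(Nc1ccc({0})cc1)c1ccc({1})cc1",
    "O=S(=O)(Nc1ccc({0})cc1)c1ccc({1})cc1",
    "c1cc({1})ccc1C(=O)N1CCN({0})CC1",
    "c1cc({0})c2nc({1})ccc2c1",
    "O=C(N{0})c1cccnc1{1}",
    "c1cc({1})nc({0})n1",
    "O=C(N{0})c1ccc({1})cc1",
    "c1ccc(Oc2ccc({0})cc2{1})cc1",
    "O=S(=O)(N1CCC({0})CC1)c1ccc({1})cc1",
    "c1cc({0})sc1{1}",
)

AROMATIC_SUBS: tuple[str, ...] = (
    "C", "F", "Cl", "Br", "OC", "C(F)(F)F", "C#N", "N(C)C", "CC",
    "S(=O)(=O)C", "OC(F)F", "OCC", "N", "C(C)C", "OC(C)C", "[N+](=O)[O-]",
)

#: Synthetic decorations grafted onto NP cores to build decoy-like molecules.
DECOY_SUBS: tuple[str, ...] = (
    "(Cl)", "(F)", "(Br)", "(C#N)", "(S(=O)(=O)C)", "(N(C)C)",
    "(c9ccccc9)", "(C(F)(F)F)", "",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Size and seed of an activity benchmark fixture."""

    n_np: int = 40              # naturals per target (incl. actives)
    n_syn: int = 160            # synthetics per target
    n_targets: int = 3
    actives_per_target: int = 10
    seed: int = 0
    grammar: str = "default"

    def __post_init__(self) -> None:
        if min(self.n_np, self.n_syn, self.n_targets,
               self.actives_per_target) <= 0:
            raise ValueError("all FixtureSpec counts must be positive")
        if self.actives_per_target >= self.n_np:
            raise ValueError("actives_per_target must be < n_np")


def _fill(template: str, slots: int, pool: Sequence[str],
          rng: np.random.Generator) -> str:
    return template.format(*(pool[rng.integers(len(pool))]
                             for _ in range(slots)))


def _n_slots(template: str) -> int:
    return sum(template.count("{%d}" % i) and 1
               for i in range(4) if ("{%d}" % i) in template)


def _core_with_slots(core: str, rng: np.random.Generator,
                     pool: Sequence[str], max_subs: int = 3) -> str:
    """Decorate a ring core by appending substituent branches at ring
    carbons (positions where a branch keeps the SMILES valid)."""
    n_subs = int(rng.integers(1, max_subs + 1))
    smiles = core
    for _ in range(n_subs):
        sub = pool[rng.integers(len(pool))]
        if not sub:
            continue
        # insert after a ring-carbon token: find candidate positions
        positions = [i for i in range(1, len(smiles))
                     if smiles[i - 1] == "C" and
                     (i == len(smiles) or smiles[i] not in "(@=#1234567890")]
        if not positions:
            break
        at = positions[int(rng.integers(len(positions)))]
        smiles = smiles[:at] + sub + smiles[at:]
    return smiles


def _generate(n: int, seed: int, make_one, tag: str) -> list[MoleculeRecord]:
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    attempts = 0
    max_attempts = 500 * n
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"fixture grammar exhausted after {attempts} attempts "
                f"({len(out)}/{n} unique molecules)")
        raw = make_one(rng)
        try:
            smiles = canonicalize(raw)
        except ParseError:
            continue
        if smiles in seen:
            continue
        seen.add(smiles)
        out.append(MoleculeRecord(
            id=f"{tag}_{len(out):05d}", smiles=smiles,
            source_class="natural" if tag.startswith("np") else "synthetic"))
    return out


def generate_np_like(n: int, seed: int = 0) -> list[MoleculeRecord]:
    """n unique NP-like molecules: fused sp3 ring cores, O-rich decoration."""
    def make_one(rng: np.random.Generator) -> str:
        core = NP_CORES[int(rng.integers(len(NP_CORES)))]
        return _core_with_slots(core, rng, NP_SUBS)
    return _generate(n, seed, make_one, "np")


def generate_synthetic_like(n: int, seed: int = 0,
                            decoy_fraction: float = 0.4
                            ) -> list[MoleculeRecord]:
    """n unique synthetic-like molecules (see module docstring).

    ``decoy_fraction`` of the set reuses NP ring cores with synthetic
    decorations; the rest is flat aromatic drug-like chemistry.
    """
    def make_one(rng: np.random.Generator) -> str:
        if rng.random() < decoy_fraction:
            core = NP_CORES[int(rng.integers(len(NP_CORES)))]
            return _core_with_slots(core, rng, DECOY_SUBS, max_subs=2)
        template = AROMATIC_TEMPLATES[int(rng.integers(len(AROMATIC_TEMPLATES)))]
        return _fill(template, _n_slots(template), AROMATIC_SUBS, rng)
    return _generate(n, seed, make_one, "syn")


def generate_activity_benchmark(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Per-target activity tables for similarity-search evaluation.

    Per target: ``actives_per_target`` active naturals share one scaffold
    (NP-decorated); an equal number of *confuser* synthetics carry the same
    scaffold with synthetic decorations, so a bit-fingerprint search cannot
    separate them from the actives by scaffold alone; the rest of the
    library is inactive background from both grammars.
    """
    records: list[MoleculeRecord] = []
    for t in range(spec.n_targets):
        target_id = f"T{t}"
        rng = np.random.default_rng(
            (spec.seed * 1_000_003 + t * 7919 + 17) % (2**31))
        # successive targets take chemically distinctive cores (sugar,
        # bridged terpene, decalin, ...) so chemotypes do not collide
        scaffold = NP_CORES[(2, 4, 0, 3, 6, 1, 5, 7)[t % len(NP_CORES)]]

        def unique_batch(count: int, build, tag: str) -> list[str]:
            seen: set[str] = set(r.smiles for r in records)
            out: list[str] = []
            attempts = 0
            while len(out) < count:
                attempts += 1
                if attempts > 2000 * count:
                    raise RuntimeError(f"could not build {count} unique "
                                       f"{tag} molecules for {target_id}")
                try:
                    smiles = canonicalize(build(rng))
                except ParseError:
                    continue
                if smiles in seen:
                    continue
                seen.add(smiles)
                out.append(smiles)
            return out

        actives = unique_batch(
            spec.actives_per_target,
            lambda r: _core_with_slots(scaffold, r, NP_SUBS), "active")
        # confusers mimic mined decoys: the target scaffold with NP-style
        # decoration plus one synthetic group, so they sit next to the
        # actives in ECFP space while their chemistry leans synthetic
        def build_confuser(r: np.random.Generator) -> str:
            smiles = _core_with_slots(scaffold, r, NP_SUBS, max_subs=2)
            return _core_with_slots(smiles, r,
                                    [s for s in DECOY_SUBS if s],
                                    max_subs=1)

        confusers = unique_batch(
            min(2 * spec.actives_per_target, spec.n_syn),
            build_confuser, "confuser")
        # inactive naturals come from *other* chemotypes: reusing the
        # target's scaffold would plant structural actives in the
        # background with an inactive label
        other_cores = tuple(c for c in NP_CORES if c != scaffold)
        np_background = unique_batch(
            spec.n_np - spec.actives_per_target,
            lambda r: _core_with_slots(
                other_cores[int(r.integers(len(other_cores)))], r, NP_SUBS),
            "np-background")
        syn_needed = spec.n_syn - len(confusers)

        def build_syn(r: np.random.Generator) -> str:
            template = AROMATIC_TEMPLATES[int(r.integers(len(AROMATIC_TEMPLATES)))]
            return _fill(template, _n_slots(template), AROMATIC_SUBS, r)

        syn_background = unique_batch(syn_needed, build_syn, "syn-background")

        def add(smiles_list, source, activity):
            for s in smiles_list:
                records.append(MoleculeRecord(
                    id=f"{target_id}_m{len(records):05d}", smiles=s,
                    source_class=source, activity=activity,
                    target_id=target_id))

        add(actives, "natural", "active")
        add(confusers, "synthetic", "inactive")
        add(np_background, "natural", "inactive")
        add(syn_background, "synthetic", "inactive")
    return records


def mean_sp3_fraction(records: Sequence[MoleculeRecord]) -> float:
    """Average sp3-carbon fraction of a record set (grammar diagnostic)."""
    return float(np.mean([sp3_carbon_fraction(r.smiles) for r in records]))
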