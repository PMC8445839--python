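"""Mine similarity-matched decoys for natural-product queries.

For each NP query, the synthetic library is searched by ECFP4/Tanimoto;
candidates must be at least 0.5 similar to the query (so the negative
class stays structurally challenging) but score below 0 on the NPL scale
(so no natural-looking material enters it), capped at the 10 most similar
per query.
"""

from npfp import (
    assemble_training_set,
    build_fragment_table,
    generate_np_like,
    generate_synthetic_like,
)

table = build_fragment_table(generate_np_like(200, seed=1),
                             generate_synthetic_like(200, seed=2))
queries = generate_np_like(50, seed=10)
library = generate_synthetic_like(500, seed=11)

dataset = assemble_training_set(queries, library, table)
print(f"curated dataset: {len(dataset.naturals)} naturals, "
      f"{len(dataset.synthetics)} mined decoys")
for decoy in dataset.synthetics[:5]:
    prov = dataset.provenance[decoy.id]
    print(f"  decoy {decoy.id}: Tanimoto {prov.similarity:.3f} "
          f"to query {prov.query_id}")

print("\nEach decoy is structurally close to one NP query yet carries")
print("synthetic fragment statistics — the hard negatives the networks")
print("are trained against.")
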