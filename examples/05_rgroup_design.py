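"""Two-stage R-group design: one-region libraries, top-3 selection,
81-compound cross-combination, and the methylene-deletion variant.

Scores here come from a table-backed scorer (standing in for external
docking results); the aggregate is the minimum over the two receptor
conformations, and the shortlist threshold is -10.00 kcal/mol.
"""

import numpy as np

import bindsight as bs

# stage 1: 42 single-region modifications of the parent scaffold
one_region = bs.enumerate_one_region(bs.default_scaffold(),
                                     bs.default_libraries(),
                                     bs.default_base_groups())
print(f"one-region library: {len(one_region)} compounds "
      f"(R1 13 + R2 8 + R3 9 + R4 12)")

# stage 2: cross the three best groups per region (3^4 = 81 compounds)
combos = bs.combine_regions(bs.combination_scaffold(),
                            bs.combination_libraries())
print(f"combination library: {len(combos)} uniquely named compounds")

c2213 = next(c for c in combos if c.name == "C2213")
variant = bs.apply_variant(c2213)  # delete the benzylic methylene
print(f"\n{c2213.name}:   {c2213.smiles}")
print(f"{variant.name}: {variant.smiles}")
print(f"heavy atoms {c2213.heavy_atoms} -> {variant.heavy_atoms} "
      "(one CH2 removed; the piperazine now sits directly on the ring)")

# ensemble scoring with a score table (two receptor conformations)
rng = np.random.default_rng(0)
table = {}
for c in combos:
    base_score = rng.normal(-9.5, 0.5)
    table[(c.name, "Cluster1")] = round(base_score, 2)
    table[(c.name, "Cluster2")] = round(base_score + abs(rng.normal(0, 0.3)), 2)
scorer = bs.TableScorer(table)

dummy = bs.generate_complex(bs.SyntheticSpec(seed=0))
ensemble = bs.ReceptorEnsemble(members=[("Cluster1", dummy),
                                        ("Cluster2", dummy)])
records = [bs.score_compound(c, ensemble, scorer) for c in combos]
ranked, shortlist = bs.rank_and_shortlist(records, threshold=-10.0)
print(f"\n{len(shortlist)} compounds scored at or below -10.00 kcal/mol:")
for r in shortlist[:6]:
    print(f"  {r.name}: min over ensemble = {r.aggregate:.2f} kcal/mol")
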