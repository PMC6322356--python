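"""Annotate m/z features by exact mass and summarise pathway involvement.

Uses the bundled 16-metabolite library: each compound's monoisotopic mass
is computed from its formula, converted to the adduct m/z it was observed
as, and matched back within 10 ppm; pathway over-representation and
topology impact are then computed on the annotated set.
"""

from vkmet import simdata
from vkmet.annotate import ADDUCTS, adduct_mz, match_library, monoisotopic_mass
from vkmet.pathways import PathwayDef, pathway_summary

library = simdata.table1_library()

queries = []
for k, comp in enumerate(library):
    adduct = comp.adducts[0]
    theo = adduct_mz(monoisotopic_mass(comp.formula), adduct)
    queries.append((f"feat{k:02d}", theo * (1 + 2e-6), ADDUCTS[adduct][1]))  # +2 ppm

matches = match_library(queries, library, tol_ppm=10.0)
print("feature -> compound (adduct, theoretical m/z, error):")
for m in matches[:4]:
    print(f"  {m.feature_id} -> {m.compound.name}  [{m.adduct}]  "
          f"{m.theoretical_mz:.5f} Th  {m.ppm_error:+.1f} ppm")
print(f"annotated {sum(m.annotated for m in matches)}/{len(matches)} features")

members: dict[str, set] = {}
for comp in library:
    for pname in comp.pathway_names:
        members.setdefault(pname, set()).add(comp.kegg_id)
db = [PathwayDef(name, name, mem) for name, mem in sorted(members.items())]
universe = len({c.kegg_id for c in library})
results = pathway_summary(matches, db, universe_size=universe)
print("\npathways by hits (p is the hypergeometric upper tail):")
for r in sorted(results, key=lambda r: -r.n_hits)[:4]:
    print(f"  {r.name}: hits={r.n_hits}  p={r.p_value:.3f}  impact={r.impact:.2f}")
# With every library member annotated the enrichment p-values are flat (the
# selection equals the universe); hit counts show primary bile acid
# biosynthesis carrying the most identified metabolites (4).
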