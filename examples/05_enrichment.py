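"""Hypergeometric over-representation of a DE gene list.

Builds a toy term annotation and asks whether the query list is enriched
for a testis-development term: p = P[X >= k] for X hypergeometric.
"""

from crossprio import TermAnnotation, hypergeom_enrich

universe = frozenset(f"Gene{i:03d}" for i in range(200))
annotation = TermAnnotation(
    terms={
        "testis_development": frozenset(f"Gene{i:03d}" for i in range(12)),
        "cilium_assembly": frozenset(f"Gene{i:03d}" for i in range(100, 140)),
    },
    universe=universe,
)
# a 20-gene query that contains 6 of the 12 testis-development genes
query = {f"Gene{i:03d}" for i in range(6)} | {f"Gene{i:03d}" for i in range(150, 164)}

result = hypergeom_enrich(query, annotation, correction="bh")
print(result.round(6).to_string())
print()
print("overlap is k of the term's K genes found among the n query genes in an")
print("N-gene universe; p is the chance of an overlap at least that large.")
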