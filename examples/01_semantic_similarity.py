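"""Disease semantic similarity from a small MeSH-style DAG.

Builds a four-node "diamond" ontology (one root A, two intermediate terms
B and C, one leaf disease D reachable through both) and evaluates the
ancestor-contribution scheme: each term contributes rho^(generations above
the disease), the semantic value is the sum of contributions, and the
similarity of two diseases is the contribution mass of their shared
ancestors relative to their combined semantic values.
"""

from hcfmda import DiseaseDAG, SemanticParams, semantic_contributions, \
    semantic_similarity, semantic_value

params = SemanticParams(rho=0.5)
dag = DiseaseDAG.from_edges([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")])

contrib = semantic_contributions(dag, "D", params)
print("ancestor contributions to D:", dict(sorted(contrib.items())))
print("semantic value DSV(D):", semantic_value(dag, "D", params))
# B and C are siblings one step under the root: they share only A, whose
# contribution to each is 0.5, so their similarity is (0.5+0.5)/(1.5+1.5)
sd = semantic_similarity(dag, ["B", "C"], params)
print(f"similarity(B, C) = {sd.S[0, 1]:.4f}  (shared root A only)")
sd_full = semantic_similarity(dag, ["B", "D"], params)
print(f"similarity(B, D) = {sd_full.S[0, 1]:.4f}  (D lies below B)")
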