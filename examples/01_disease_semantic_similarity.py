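"""Disease semantic similarity from a small disease-term DAG.

Builds a toy ontology fragment (two cancers under a shared parent, one of
them also under a second parent), computes the decaying-contribution
semantic similarity with Delta = 0.5, and prints the matrix.
"""

from rcmf import DiseaseDAG, SemanticConfig, semantic_similarity, semantic_value

dag = DiseaseDAG(
    terms=frozenset({
        "gastric cancer", "esophageal cancer", "digestive cancer",
        "thoracic cancer", "cancer",
    }),
    edges=frozenset({
        ("gastric cancer", "digestive cancer"),
        ("esophageal cancer", "digestive cancer"),
        ("esophageal cancer", "thoracic cancer"),
        ("digestive cancer", "cancer"),
        ("thoracic cancer", "cancer"),
    }),
)

cfg = SemanticConfig(delta=0.5)
for term in ("gastric cancer", "esophageal cancer"):
    print(f"semantic value DV({term!r}) = {semantic_value(dag, term, cfg):.3f}")

S = semantic_similarity(dag, cfg, terms=["gastric cancer", "esophageal cancer"])
print("\npairwise semantic similarity:")
print(f"  S(gastric, esophageal) = {S.values[0, 1]:.4f}")
print("""
The two cancers share the ancestors 'digestive cancer' and 'cancer';
esophageal cancer has the larger DAG (an extra parent), so the shared part
is a smaller fraction of its semantic value, keeping the score below 1.
""")
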