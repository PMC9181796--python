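"""Hypergeometric term enrichment of a DEG list.

A term annotating K of N background genes that overlaps a gene set of size
n in k genes gets p = P(X >= k) under sampling without replacement; BH FDR
<= 0.05 calls it enriched. The direction score (up - down)/total shows
whether a term's DEGs lean up- or down-regulated.
"""

from splitrootseq import direction_score, hypergeom_enrich, top_terms
from splitrootseq.enrich import TermAnnotation

background = {f"g{i}" for i in range(1000)}
gene_set = {f"g{i}" for i in range(50)}  # pretend these are deficiency DEGs

annotations = [
    TermAnnotation("GO:amino_acid", "cellular amino acid metabolic process", "BP",
                   frozenset({f"g{i}" for i in range(30)} | {"g500", "g501"})),
    TermAnnotation("GO:calcium", "calcium-mediated signalling", "BP",
                   frozenset({f"g{i}" for i in range(45, 60)})),
    TermAnnotation("GO:ribosome", "cytosolic ribosome", "CC",
                   frozenset({f"g{i}" for i in range(400, 480)})),
]

res = hypergeom_enrich(gene_set, background, annotations)
print(top_terms(res, 3)[["term_id", "k", "K", "n", "N", "p", "fdr", "enriched"]]
      .to_string(index=False))
print("-> GO:amino_acid: 30/32 annotated genes hit a 50-gene set from a "
      "1000-gene background; p is astronomically small")

print("\ndirection score if 40 of those DEGs were up and 10 down:",
      direction_score(40, 10, 50))
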