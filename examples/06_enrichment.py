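"""Gene-set over-representation of a module.

A module's gene list is tested against a GMT collection with the
one-sided hypergeometric tail; Benjamini-Hochberg q-values correct for
the number of sets; hits need overlap >= 2 and q < 0.05.  Here the GMT
is built in memory with one set planted inside a module and one random
decoy, so only the planted set should survive the filters.
"""

import numpy as np

from coexdiff import default_paper_like_scenario, simulate_two_condition
from coexdiff.enrichment import GeneSetCollection, enrichment_frame, hypergeometric_enrichment

cfg = default_paper_like_scenario(seed=1)
expr_ref, _, _, truth = simulate_two_condition(cfg)
background = set(expr_ref.index)

module_genes = set(truth.module_of.index[truth.module_of == 1])
rng = np.random.default_rng(0)

collection = GeneSetCollection(
    sets={
        "planted_pathway": set(list(module_genes)[:15]) | {"not_measured_1"},
        "decoy_pathway": set(rng.choice(sorted(background), size=16, replace=False)),
    },
    descriptions={
        "planted_pathway": "15 genes drawn from module 1",
        "decoy_pathway": "random background draw",
    },
)

results = hypergeometric_enrichment(
    module_genes, background, collection, min_overlap=2, q_cut=0.05
)
print(enrichment_frame(results).to_string(index=False))
print("\nonly the planted set should pass q < 0.05 with overlap >= 2;")
print("genes absent from the background (e.g. unmeasured ids) are ignored.")
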