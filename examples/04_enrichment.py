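"""Over-representation analysis of a responder gene list.

Builds a small GMT annotation in which one term is seeded with planted
LPS-up genes (an 'inflammation-like' module) and others are random, then
tests the pipeline's LPSup GO-input list against it. The seeded term should
dominate the ranking.
"""

import numpy as np

import sustaindeg as sd

cm, truth = sd.simulate_experiment(sd.SimConfig(seed=7))
result = sd.run_pipeline(cm)

rng = np.random.default_rng(7)
universe = list(truth["gene_id"])
lps_up = list(truth.loc[truth["label"] == "lps_up", "gene_id"])
annotations = [
    sd.GeneSet("M1", "seeded module: planted LPS-up genes + noise",
               frozenset(lps_up[:40] + list(rng.choice(universe, 20, replace=False)))),
]
for i in range(2, 6):
    annotations.append(
        sd.GeneSet(f"M{i}", f"random module {i}",
                   frozenset(rng.choice(universe, 60, replace=False)))
    )

sd.run_ora(result, annotations, sd.PipelineConfig())
table = sd.top_terms(result.ora_tables["LPSup"], k=5)
cols = ["term_id", "k", "K", "n", "N", "gene_ratio", "p", "padj", "significant"]
print("ORA of the LPSup list (top terms):")
print(table[cols].to_string(index=False, float_format=lambda x: f"{x:.3g}"))

# k/K/n/N: query hits in the term / term size / query size / universe size;
# gene_ratio = k/n. The seeded module M1 should be the only significant term.
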