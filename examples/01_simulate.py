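"""Generate a synthetic stimulation experiment and inspect its ground truth.

Draws NB counts for the six-condition design (control/LPS/IL-4 x 12/24 h,
five replicates) with planted responder programs, then prints the planted
class composition and a look at one gene per program type.
"""

import sustaindeg as sd

cm, truth = sd.simulate_experiment(sd.SimConfig(seed=7))

print(f"count matrix: {cm.n_genes} genes x {cm.n_samples} samples")
print("\nplanted class composition:")
print(truth["label"].value_counts().to_string())

print("\none example gene per planted program (true log2FC per condition):")
cols = ["gene_id", "label", "baseline_mean", "lfc_lps_12", "lfc_lps_24", "lfc_il4_12", "lfc_il4_24"]
examples = truth[truth["label"] != "none"].groupby("label").head(1)
print(examples[cols].round(1).to_string(index=False))

# The lfc_* columns are what the DE stage should estimate: e.g. a
# 'common_up' gene carries +2 under both stimuli at both timepoints, while
# a 'flip_lps' gene switches sign between 12 h and 24 h and must end up
# excluded from every sustained set.
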