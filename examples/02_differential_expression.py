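"""Run the NB Wald stage on simulated counts and check one planted gene.

Size factors (median-of-ratios), gene-wise Cox-Reid dispersions, then the
LPS-vs-control contrast at 12 h; DEGs are |log2FC| > 1 with padj < 0.05.
"""

import sustaindeg as sd
from sustaindeg.containers import Contrast

cm, truth = sd.simulate_experiment(sd.SimConfig(seed=7))

sf = sd.estimate_size_factors(cm)
print("size factors (first 6):")
print(sf.head(6).round(3).to_string())

disp = sd.estimate_dispersions(cm, sf)
print(f"\nmedian dispersion: {disp['alpha'].median():.3f} "
      f"({int(disp['excluded'].sum())} all-zero genes excluded)")

res = sd.wald_test(cm, sf, disp, Contrast("LPS", 12))
calls = sd.call_degs(res)
n_up = (calls["direction"] == "up").sum()
n_down = (calls["direction"] == "down").sum()
print(f"\nLPS 12 h vs control 12 h: {n_up} up, {n_down} down")

# a planted LPS-up gene should come back near its true log2FC of +2
gene = truth.loc[truth["label"] == "lps_up", "gene_id"].iloc[0]
row = calls.loc[gene]
print(f"\nplanted lps_up gene {gene}: "
      f"log2FC = {row['log2fc']:.2f} +- {row['se']:.2f}, "
      f"padj = {row['padj']:.2e}, call = {row['direction']}")
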