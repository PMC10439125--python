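"""Directional enrichment of variant effects among alpha-granule proteins.

The published cross-classification of megakaryocyte-expressed proteins
(40 of 44 granule proteins vs 101 of 171 others with negative allelic
effects) is tested directly; a simulated protein table then shows the
expression-adjusted regression recovering an injected granule shift.
"""

import numpy as np

from flowgwas import enrichment
from flowgwas.synthdata import simulate_protein_table

table = np.array([[40, 4], [101, 70]])
p = enrichment.fisher_exact(table)
print(f"published 2x2 table {table.tolist()}: Fisher two-sided p = {p:.2e}")

prot = simulate_protein_table(1456, 260, delta=0.038, seed=13)
tab = enrichment.build_table(prot)
reg = enrichment.localisation_regression(prot.loc[prot["log2_fpkm"] > 1])
print(f"simulated table (p<1e-3, log2FPKM>1): {tab.tolist()}, "
      f"Fisher p = {enrichment.fisher_exact(tab):.2e}")
print(f"granule shift estimate {reg['coef']:+.4f} SD (se {reg['se']:.4f}, p = {reg['p']:.1e}); "
      "injected -0.038")
# negative effects concentrate among granule proteins far beyond chance,
# and the regression recovers the injected shift after adjusting for
# megakaryocyte expression
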