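"""Alpha/beta diversity and permutation tests across hosts.

Builds the four-group coastal dataset (one HMA host, two LMA hosts,
seawater), computes Shannon diversity per group, and asks whether host
identity structures the communities (ANOSIM / PERMANOVA / MRPP on
Bray-Curtis distances).
"""

import numpy as np
import pandas as pd

from spongenet import (
    AsvTable,
    alpha_diversity,
    anosim,
    bray_curtis,
    generate_experiment,
    mrpp,
    permanova,
    upgma,
)

exp = generate_experiment("coastal", seed=1)

for host, table in exp.tables.items():
    shannon = np.mean([alpha_diversity(c, "shannon") for c in table.counts.T])
    print(f"{host:>15}: mean Shannon H = {shannon:.2f}")

merged = pd.concat([t.data for t in exp.tables.values()], axis=1)
merged = AsvTable(merged.fillna(0).astype(int).groupby(level=0).sum())
dm = bray_curtis(merged)
hosts = [str(exp.metadata.table.loc[s, "host"]) for s in dm.ids]

for res in (anosim(dm, hosts, seed=1), permanova(dm, hosts, seed=1),
            mrpp(dm, hosts, seed=1)):
    print(f"{res.name}: {res.statistic:.3f}  (p = {res.p_value:.3f})")

print()
print(
    "Seawater is the most diverse community and the HMA host out-"
    "diversifies the LMA hosts.  ANOSIM R near 1 with p at the "
    "permutation floor means host identity separates the communities "
    "almost perfectly.  The UPGMA dendrogram of the same distances:"
)
print(upgma(dm)[:120] + "...")
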