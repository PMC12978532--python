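"""Detect gene flow with the ABBA-BABA D statistic and estimate the
admixture fraction with the f4-ratio.

P2 receives 30% of its ancestry from the P3 side; D should be positive
with |Z| > 3, and the f4-ratio should estimate the 30% fraction.
"""

import numpy as np
import pandas as pd

from evopot import GenotypeTable, d_statistic, f4_ratio

rng = np.random.default_rng(11)
n_sites = 8_000
p_anc = rng.uniform(0.1, 0.9, n_sites)
F = 0.3
a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
f1, f2, f3 = rng.beta(a, b), rng.beta(a, b), rng.beta(a, b)
frac = 0.3
f2_admixed = (1 - frac) * f2 + frac * f3

cols = [rng.binomial(2, f[:, None], (n_sites, 6))
        for f in (f1, f2_admixed, f3)]
cols.append(np.zeros((n_sites, 1), dtype=int))
sites = pd.DataFrame({"chrom": "1", "pos": np.arange(1, n_sites + 1) * 500,
                      "ref": "A", "alt": "T"})
names = [f"p1_{i}" for i in range(6)] + [f"p2_{i}" for i in range(6)] \
    + [f"p3_{i}" for i in range(6)] + ["og"]
table = GenotypeTable(sites, names, np.hstack(cols).astype(np.int8))

pops = dict(p1=names[:6], p2=names[6:12], p3=names[12:18], og=["og"])
res = d_statistic(table, pops["p1"], pops["p2"], pops["p3"], pops["og"])
print(f"D = {res.d:.3f}, Z = {res.z:.1f} over {res.n_blocks} jackknife blocks")
# Positive D with |Z| > 3: excess ABBA sharing between P2 and P3 = gene flow.
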