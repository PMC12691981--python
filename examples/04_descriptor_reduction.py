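"""Identify and keep the descriptors that dominate the principal components.

Builds a panel in which four named descriptors ride two strong latent
factors while the rest are independent noise. The loadings analysis names
the descriptors with the largest |loading| per component; the retention
rule keeps every descriptor whose max |loading| over the scanned components
passes the cutoff, and the reduced table can be re-analyzed from scratch.
"""

import numpy as np
import pandas as pd

from molsim import DescriptorTable, RetentionRule, fit_pca, reduce_descriptors, scale, top_loadings

rng = np.random.default_rng(0)
f1, f2 = rng.normal(size=(2, 80))
strong = np.column_stack([
    f1 + 0.05 * rng.normal(size=80),
    f1 + 0.05 * rng.normal(size=80),
    f2 + 0.05 * rng.normal(size=80),
    f2 + 0.05 * rng.normal(size=80),
])
noise = rng.normal(size=(80, 10))
names = ["MW", "aromatic_rings", "BBB", "docking_score"] + [f"noise{j}" for j in range(10)]
df = pd.DataFrame(np.column_stack([strong, noise]),
                  index=[f"M{i:02d}" for i in range(80)], columns=names)
table = DescriptorTable(df, pd.Series("OTHER", index=df.columns, dtype=object))

pca = fit_pca(scale(table))
print("top |loading| per component:")
for j, (winners, mag) in enumerate(top_loadings(pca, 3), start=1):
    print(f"  PC{j}: {', '.join(winners)} ({mag:.2f})")

retained, sub = reduce_descriptors(pca, RetentionRule(n_components=2, cutoff=0.45))
print(f"\nretained descriptors (|loading| >= 0.45 over the 2 factor-bearing PCs): {retained}")
refit = fit_pca(scale(sub))
print(f"re-fit loadings table for the reduced panel "
      f"({refit.loadings.shape[0]} descriptors x 3 PCs):")
print(refit.loadings.iloc[:, :3].round(2).to_string())
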