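"""Choose the cluster count k by the elbow method and by PCA explained variance.

The elbow scan runs K-means for each k and looks for the knee of the
WSS-vs-k curve (maximum second difference); on a panel with five
well-separated planted classes the knee sits at k = 5. The PCA route counts
the principal components that explain 95% of the variance — it reads the
*spectrum*, so it is demonstrated on a panel whose correlation structure has
rank 5 (five latent factors); on a noisy blob panel the isotropic noise
floor legitimately inflates that count.
"""

import numpy as np
import pandas as pd

from molsim import (
    BlobSpec,
    DescriptorTable,
    KMeansConfig,
    elbow_scan,
    fit_pca,
    k_from_variance,
    make_blob_table,
    scale,
)

table = make_blob_table(BlobSpec(separation=10.0, seed=3))
scaled = scale(table)

res = elbow_scan(scaled.values, range(1, 10), KMeansConfig(k=2, seed=0, metric="ased"))
print("k :", "  ".join(f"{k}" for k in res.ks))
print("WSS:", " ".join(f"{w:7.1f}" for w in res.wss_values))
print(f"elbow suggestion: k = {res.suggested_k}  (five planted classes)")

# a panel whose 25 descriptors are mixtures of 5 latent factors
rng = np.random.default_rng(0)
factors = rng.normal(size=(40, 5))
cols = np.column_stack([
    factors[:, f] * rng.uniform(0.8, 1.2) + 0.05 * rng.normal(size=40)
    for f in range(5) for _ in range(5)
])
df = pd.DataFrame(cols, index=[f"M{i:02d}" for i in range(40)],
                  columns=[f"x{j}" for j in range(25)])
pca = fit_pca(scale(DescriptorTable(df, pd.Series("OTHER", index=df.columns, dtype=object))))
cum = np.cumsum(pca.explained_variance_ratio)
print(f"\nfactor panel, cumulative explained variance (first 7 PCs): "
      f"{np.round(cum[:7], 3).tolist()}")
print(f"components needed for 95% of the variance: k = {k_from_variance(pca, 0.95)}")
print("(five latent factors -> five dominant components -> k = 5)")
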