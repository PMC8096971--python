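"""PCA of binding matrices: a dominant temporal axis and a weaker
cell-type axis, mirroring the sample geometry of a differentiation
time course."""

import pandas as pd
from scipy import stats

from _common import SEED, save
from fatebind.differential import binding_pca
from fatebind.normalization import normalize_matrix
from fatebind.synth import GeneratorConfig, generate_two_factor_binding

m = generate_two_factor_binding(GeneratorConfig(seed=SEED))
pca = binding_pca(normalize_matrix(m, "depth"))

time_rank = m.samples["timepoint"].map({"t0": 0, "t1": 1, "t2": 2})
rho_time = stats.spearmanr(pca.coordinates["PC1"], time_rank).statistic
pc2 = pca.coordinates["PC2"]
sep = (pc2[m.samples["condition"] == "A"].min()
       - pc2[m.samples["condition"] == "B"].max())

table = pd.DataFrame({
    "statistic": ["pc1_variance_fraction", "pc2_variance_fraction",
                  "pc1_time_spearman_abs", "pc2_celltype_gap"],
    "value": [round(float(pca.variance_fraction[0]), 4),
              round(float(pca.variance_fraction[1]), 4),
              round(abs(float(rho_time)), 4), round(float(abs(sep)), 2)],
})
print(table.to_string(index=False))
coords = pca.coordinates.copy()
coords.insert(0, "sample_id", coords.index)
save(coords.reset_index(drop=True), "06_pca_coordinates.tsv")
save(table, "06_pca_summary.tsv")
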