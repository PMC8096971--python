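"""Differential binding between the two mature fates and the full site
taxonomy (specificity, progenitor-specific calls, lineage/housekeeping
deconvolution, promoter/distal annotation), scored against the planted
truth.
"""

import pandas as pd

from _common import get_workspace, save
from fatebind.differential import differential_test
from fatebind.genomic_io import nearest_tss
from fatebind.normalization import normalize_matrix
from fatebind.taxonomy import airway_low_subset, deconvolve_common

ws = get_workspace()
truth = ws.truth.set_index("site_id")
m = normalize_matrix(ws.binding, "depth")

res = differential_test(
    m, m.sample_ids(condition="A", timepoint="t2"),
    m.sample_ids(condition="B", timepoint="t2"),
).set_index("site_id")
spec = res["label"].copy()

# progenitor-specific: common sites that lose binding toward BOTH fates
lost = {}
for fate in ("A", "B"):
    pm = differential_test(
        m, m.sample_ids(timepoint="t0"), m.sample_ids(condition=fate, timepoint="t2")
    ).set_index("site_id")
    lost[fate] = pm["label"] == "A_specific"
common = spec.index[spec == "common"]
spec.loc[[s for s in common if lost["A"][s] and lost["B"][s]]] = "progenitor_specific"

common = list(spec.index[spec == "common"])
sub = deconvolve_common(common, ws.accessibility)
lineage = list(sub.index[sub == "lineage"])
airway_low = airway_low_subset(lineage, ws.accessibility)
ann = nearest_tss(ws.peaks, ws.genes).set_index("site_id")

summary = pd.DataFrame({
    "metric": [
        "specificity_recovery", "subclass_recovery", "airway_low_fraction",
        "n_A_specific", "n_B_specific", "n_common", "n_progenitor_specific",
        "n_lineage", "n_housekeeping",
    ],
    "value": [
        round(float((spec == truth["specificity"]).mean()), 4),
        round(float((sub == truth.loc[common, "common_subclass"]).mean()), 4),
        round(len(airway_low) / max(len(lineage), 1), 4),
        int((spec == "A_specific").sum()), int((spec == "B_specific").sum()),
        len(common), int((spec == "progenitor_specific").sum()),
        len(lineage), int((sub == "housekeeping").sum()),
    ],
})
print(summary.to_string(index=False))
save(summary, "02_taxonomy_summary.tsv")

from _common import SCRATCH

table = pd.DataFrame({"specificity": spec})
table.loc[sub.index, "common_subclass"] = sub
table["locale"] = ann["locale"]
SCRATCH.mkdir(exist_ok=True)
table.reset_index().to_csv(SCRATCH / "02_site_taxonomy.tsv", sep="\t", index=False)
print(f"  wrote {SCRATCH / '02_site_taxonomy.tsv'} (full per-site table)")
print(f"\nRecovered {summary.loc[0, 'value']:.1%}-scale specificity agreement "
      "against the planted labels; lineage/housekeeping deconvolution "
      f"agreement {summary.loc[1, 'value']:.4f}.")
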