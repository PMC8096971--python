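"""Nearest-gene module scores along pseudotime.

Three analyses: (1) the binding/expression dissociation — acquired and
retained cell-type-specific gene sets share the same expression
kinetics although only retained sites are progenitor-bound; (2) the
partner-loss perturbation — gene sets of the most decreased/increased
binding sites trend down/up along the merged trajectory; (3) the
TF-loss perturbation — opposite-fate accessibility gains without
expression change.
"""

import pandas as pd

from _common import get_workspace, save
from fatebind.differential import differential_test, rank_by_change
from fatebind.genomic_io import PeakSet, nearest_tss
from fatebind.modulescore import (
    compute_module_score,
    sites_to_gene_set,
    trend_along_pseudotime,
)
from fatebind.normalization import normalize_matrix
from fatebind.taxonomy import opposite_fate_gain

rows = []

ws = get_workspace()
truth = ws.truth.set_index("site_id")
ann = nearest_tss(ws.peaks, ws.genes)
obs = ws.expression.obs
m = normalize_matrix(ws.binding, "depth")
for kin in ("acquired", "retained"):
    ids = list(truth.index[(truth["specificity"] == "A_specific")
                           & (truth["kinetics"] == kin)])
    prog_signal = float(m.values.loc[ids, m.sample_ids(timepoint="t0")].to_numpy().mean())
    track = compute_module_score(ws.expression, sites_to_gene_set(ids, ann), seed=0)
    for branch in ("A", "B"):
        cells = obs.index[obs["branch"] == branch]
        _, rho = trend_along_pseudotime(track.scores.loc[cells], obs["pseudotime"])
        rows.append(("dissociation", f"A_{kin}", branch, round(rho, 4),
                     round(prog_signal, 1)))

wsp = get_workspace(perturbation="partner_loss")
annp = nearest_tss(wsp.peaks, wsp.genes)
pm = wsp.perturbation_binding
res = differential_test(pm, pm.sample_ids(condition="mutant"),
                        pm.sample_ids(condition="control"))
for direction in ("decreased", "increased"):
    ids = rank_by_change(res, direction, 0.20)
    track = compute_module_score(wsp.expression, sites_to_gene_set(ids, annp), seed=0)
    _, rho = trend_along_pseudotime(track.scores, wsp.expression.obs["pseudotime"])
    rows.append(("partner_loss", direction, "merged", round(rho, 4), None))

wst = get_workspace(perturbation="tf_loss")
tr = wst.truth.set_index("site_id")
own = PeakSet(tr.loc[tr["specificity"] == "A_specific",
                     ["chrom", "start", "end"]].reset_index())
opp = PeakSet(tr.loc[tr["specificity"] == "B_specific",
                     ["chrom", "start", "end"]].reset_index())
labels, fractions = opposite_fate_gain(wst.gains, own, opp)
gained = list(labels.index[labels == "opposite_bound"])
anng = nearest_tss(wst.gains, wst.genes)
track = compute_module_score(wst.expression, sites_to_gene_set(gained, anng), seed=0)
_, rho = trend_along_pseudotime(track.scores, wst.expression.obs["pseudotime"])
rows.append(("tf_loss", "opposite_fate_gains", "merged", round(rho, 4),
             round(fractions["opposite_bound"], 4)))

table = pd.DataFrame(rows, columns=["analysis", "gene_set", "branch",
                                    "spearman_rho", "aux"])
print(table.to_string(index=False))
save(table, "05_module_score_trends.tsv")
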