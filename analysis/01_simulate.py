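"""Generate the default synthetic workspace and record what was planted.

Writes the full plain-text workspace (genome, peaks, signal matrices,
accessibility, expression, truth tables) under scratch/workspace and a
site-class census under results/.
"""

import pandas as pd

from _common import SCRATCH, get_workspace, save
from fatebind.synth import write_workspace

ws = get_workspace()
write_workspace(ws, SCRATCH / "workspace")
print(f"workspace written to {SCRATCH / 'workspace'}")

census = (
    ws.truth.groupby(["class", "specificity", "kinetics", "common_subclass"])
    .size().rename("n_sites").reset_index()
)
print(census.to_string(index=False))
save(census, "01_planted_site_census.tsv")

print(f"\n{len(ws.peaks)} sites on {len(ws.genome)} chromosomes; "
      f"{ws.binding.values.shape[1]} ChIP-like samples; "
      f"{ws.expression.n_obs} cells x {ws.expression.n_vars} genes.")
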