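"""Control-matched gene-set module scores and their pseudotime trends.

The module score of a gene set in a cell is the mean expression of the
set minus the mean expression of a pooled control set drawn, with
replacement, from expression-matched bins — the averaging approach used
for cell-cycle and signature scoring in single-cell toolkits. Matching
controls by baseline expression removes the trivial dependence of a raw
set mean on how highly expressed its genes happen to be.

Expression is carried in an :class:`anndata.AnnData` whose ``obs`` holds
per-cell ``pseudotime``, ``branch`` and ``sample`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ModuleScoreTrack:
    """Per-cell control-subtracted scores for one gene set."""

    gene_set_id: str
    scores: pd.Series  # indexed by cell id
    genes_used: list[str]
    n_missing: int


def sites_to_gene_set(site_ids: Sequence[str], annotation: pd.DataFrame) -> list[str]:
    """Deduplicated nearest genes of the given sites.

    ``annotation`` is the nearest-TSS table (site_id, gene_id, ...);
    unannotated sites are dropped. Raises when nothing remains.
    """
    ann = annotation.set_index("site_id")
    known = [s for s in site_ids if s in ann.index]
    genes = ann.loc[known, "gene_id"].dropna()
    out = sorted(set(genes))
    if not out:
        raise ValueError("no annotated genes for the given sites")
    return out


def compute_module_score(
    expr: ad.AnnData,
    gene_set: Iterable[str],
    gene_set_id: str = "module",
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreTrack:
    """Expression-bin-matched module score per cell.

    Genes are ranked by mean expression across cells and split into
    ``n_bins`` equal-count bins; each set gene contributes ``n_ctrl``
    control genes drawn with replacement (seeded) from its own bin. The
    score is mean(set) - mean(pooled controls) per cell; deterministic
    given the seed and invariant to gene order and in-set duplicates.
    """
    genes = sorted(set(gene_set))
    present = [g for g in genes if g in expr.var_names]
    n_missing = len(genes) - len(present)
    if not present:
        raise ValueError(f"gene set disjoint from expression matrix: {genes[:10]}...")
    if expr.n_vars < max(2, n_bins):
        raise ValueError("too few genes to build expression bins")
    X = np.asarray(expr.X)
    gene_means = pd.Series(X.mean(axis=0), index=expr.var_names)
    ranks = gene_means.rank(method="first")
    bins = pd.cut(ranks, bins=n_bins, labels=False)
    rng = np.random.default_rng(seed)
    by_bin = {b: np.asarray(idx) for b, idx in pd.Series(
        np.arange(expr.n_vars), index=bins.to_numpy()).groupby(level=0)}
    control_idx = []
    gene_pos = {g: i for i, g in enumerate(expr.var_names)}
    for g in present:
        pool = by_bin[int(bins.iloc[gene_pos[g]])]
        control_idx.append(pool[rng.integers(0, len(pool), size=n_ctrl)])
    control_idx = np.concatenate(control_idx)
    set_idx = np.array([gene_pos[g] for g in present])
    scores = X[:, set_idx].mean(axis=1) - X[:, control_idx].mean(axis=1)
    return ModuleScoreTrack(
        gene_set_id=gene_set_id,
        scores=pd.Series(scores, index=expr.obs_names, name=gene_set_id),
        genes_used=present,
        n_missing=n_missing,
    )


def align_branch_endpoints(pt_a: pd.Series, pt_b: pd.Series) -> pd.Series:
    """Rescale branch B pseudotime so both branches share the same endpoint.

    Multiplies ``pt_b`` by max(pt_a) / max(pt_b); a positive scaling, so
    the within-branch cell order is preserved.
    """
    mb = float(pt_b.max())
    if mb <= 0:
        raise ValueError("branch B pseudotime has no positive endpoint")
    return pt_b * (float(pt_a.max()) / mb)


def trend_along_pseudotime(
    scores: pd.Series, pseudotime: pd.Series, n_ptbins: int = 20
) -> tuple[pd.DataFrame, float]:
    """Equal-width pseudotime bins of a score plus its Spearman trend.

    Returns (per-bin DataFrame with bin_mid, mean, sd, count over
    nonempty bins; Spearman rho of score vs pseudotime over cells).
    """
    pt = pseudotime.loc[scores.index].astype(float)
    if float(pt.max()) == float(pt.min()):
        raise ValueError("all cells share one pseudotime; no trend to compute")
    edges = np.linspace(pt.min(), pt.max(), n_ptbins + 1)
    which = np.clip(np.digitize(pt, edges[1:-1]), 0, n_ptbins - 1)
    rows = []
    for b in range(n_ptbins):
        mask = which == b
        if not mask.any():
            continue
        vals = scores.to_numpy()[mask]
        rows.append(
            ((edges[b] + edges[b + 1]) / 2, float(vals.mean()),
             float(vals.std(ddof=1)) if mask.sum() > 1 else 0.0, int(mask.sum()))
        )
    binned = pd.DataFrame(rows, columns=["bin_mid", "mean", "sd", "count"])
    if len(binned) < 2:
        raise ValueError("need >= 2 nonempty pseudotime bins")
    rho = float(stats.spearmanr(scores.to_numpy(), pt.to_numpy()).statistic)
    return binned, rho


def read_expression(values_path, meta_path) -> ad.AnnData:
    """Read a cells x genes tab table plus a cell-metadata sheet
    (cell_id, pseudotime, branch, sample)."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta = meta.loc[values.index]
    return ad.AnnData(X=values.to_numpy(), obs=meta.copy(),
                      var=pd.DataFrame(index=values.columns))


def write_expression(expr: ad.AnnData, values_path, meta_path) -> None:
    pd.DataFrame(np.asarray(expr.X), index=expr.obs_names, columns=expr.var_names).to_csv(
        values_path, sep="\t", index_label="cell_id", float_format="%.4f"
    )
    expr.obs.to_csv(meta_path, sep="\t", index_label="cell_id")
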