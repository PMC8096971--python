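"""Consensus peakset construction, differential binding, and binding PCA.

The differential test is a moderated two-sample t on log2(normalized
signal + 1): per-site pooled variances are shrunk 50% toward their
global mean, the standard small-replicate stabilization. Because log
counts with two or three replicates are visibly non-normal, p-values
come from the pooled group-relabeling null of the same statistic rather
than from a t reference — calibrated without distributional assumptions
and still deterministic (relabelings are enumerated). Benjamini-
Hochberg q-values are computed over all sites.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .genomic_io import PeakSet
from .normalization import SignalMatrix, normalize_matrix

#: default significance and effect-size thresholds for specificity calls
Q_THRESHOLD = 0.05
LFC_THRESHOLD = 1.0
PSEUDOCOUNT = 1.0


def consensus_peakset(
    peaksets: list[PeakSet], min_support: int = 1, width: int = 500
) -> PeakSet:
    """Merge peak calls from several samples into a fixed-width site universe.

    Overlapping peaks (>= 1 bp, single linkage) across all sets form
    clusters; clusters supported by >= min_support distinct sets are kept
    and recentered to ``width`` around the center of their maximum-score
    member. Fresh stable site_ids are assigned in coordinate order.
    """
    if not peaksets:
        raise ValueError("need at least one peakset")
    if min_support > len(peaksets):
        raise ValueError("min_support exceeds number of peaksets")
    frames = []
    for src, ps in enumerate(peaksets):
        df = ps.df.copy()
        df["_src"] = src
        df["_center"] = ps.centers
        frames.append(df)
    allp = pd.concat(frames, ignore_index=True)
    if not len(allp):
        return PeakSet()
    allp = allp.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    # single-linkage clustering by sweeping sorted intervals per chromosome
    cluster = np.zeros(len(allp), dtype=np.int64)
    cid = -1
    prev_chrom, prev_end = None, -1
    for i, r in enumerate(allp.itertuples()):
        if r.chrom != prev_chrom or r.start >= prev_end:
            cid += 1
            prev_chrom, prev_end = r.chrom, r.end
        else:
            prev_end = max(prev_end, r.end)
        cluster[i] = cid
    allp["_cluster"] = cluster
    rows = []
    for _, sub in allp.groupby("_cluster", sort=True):
        if sub["_src"].nunique() < min_support:
            continue
        score = sub["score"].to_numpy(dtype=float)
        score = np.where(np.isnan(score), -np.inf, score)
        best = sub.iloc[int(np.argmax(score))]  # argmax takes first on ties
        c = int(best["_center"])
        start = max(c - width // 2, 0)
        rows.append((best["chrom"], start, start + width, float(best["score"]), c - start))
    if not rows:
        return PeakSet()
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "summit"])
    out = out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    ndig = max(5, len(str(len(out))))
    out["site_id"] = [f"site_{i + 1:0{ndig}d}" for i in range(len(out))]
    out["strand"] = "."
    return PeakSet(out)


def _moderated_t(L: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray):
    """Moderated two-sample t: per-site pooled variance shrunk 50% toward
    the global mean variance. Returns (log2fc, t)."""
    A, B = L[:, idx_a], L[:, idx_b]
    na, nb = len(idx_a), len(idx_b)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    ss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + ((B - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / (na + nb - 2)
    s2_mod = 0.5 * s2 + 0.5 * s2.mean()
    lfc = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
        fallback = np.where(lfc == 0, 0.0, np.inf * np.sign(lfc))
    t = np.where(np.isfinite(t), t, fallback)
    return lfc, t


#: enumerate every group relabeling when their number is at most this;
#: beyond it a deterministic subsample of relabelings is used.
MAX_ENUMERATED_SPLITS = 400


def _null_splits(n: int, na: int, observed: frozenset) -> list[tuple[list[int], list[int]]]:
    all_splits = []
    complement = frozenset(range(n)) - observed
    for comb in itertools.combinations(range(n), na):
        s = frozenset(comb)
        if s == observed or s == complement:
            continue
        all_splits.append((list(comb), [j for j in range(n) if j not in s]))
    if len(all_splits) > MAX_ENUMERATED_SPLITS:
        rng = np.random.default_rng(0)
        keep = rng.choice(len(all_splits), size=MAX_ENUMERATED_SPLITS, replace=False)
        all_splits = [all_splits[i] for i in sorted(keep)]
    return all_splits


def differential_test(
    m: SignalMatrix,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Moderated t-test of group A vs B signal per site, with p-values
    from the pooled group-relabeling null.

    ``m`` may be raw (depth-normalized internally) or already normalized.
    The statistic is the moderated t on log2(normalized + pseudocount);
    its null distribution is taken from the same statistic recomputed
    under every relabeling of samples into groups of the same sizes,
    pooled across sites — calibrated without distributional assumptions
    on the counts, and deterministic given the inputs. Returns a
    DataFrame (site_id, log2fc, stat, pvalue, qvalue, label) where
    log2fc is the A-over-B difference of group means; labels use the
    default thresholds (re-labelable with :func:`classify_specificity`).
    """
    na, nb = len(group_a), len(group_b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 replicates for a variance estimate")
    if m.norm is None:
        m = normalize_matrix(m, "depth")
    cols = list(group_a) + list(group_b)
    L = np.log2(m.values[cols].to_numpy() + pseudocount)
    idx_a, idx_b = np.arange(na), np.arange(na, na + nb)
    lfc, t = _moderated_t(L, idx_a, idx_b)
    null = np.sort(
        np.concatenate(
            [
                np.abs(_moderated_t(L, np.asarray(ia), np.asarray(ib))[1])
                for ia, ib in _null_splits(na + nb, na, frozenset(range(na)))
            ]
        )
    )
    n_null = len(null)
    exceed = n_null - np.searchsorted(null, np.abs(t), side="left")
    p = (1.0 + exceed) / (1.0 + n_null)
    q = multipletests(p, method="fdr_bh")[1]
    res = pd.DataFrame(
        {"site_id": m.values.index, "log2fc": lfc, "stat": t, "pvalue": p, "qvalue": q}
    ).reset_index(drop=True)
    return classify_specificity(res)


def classify_specificity(
    results: pd.DataFrame,
    q_threshold: float = Q_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
) -> pd.DataFrame:
    """Label each site A_specific / B_specific / common.

    A_specific iff q < q_threshold and log2fc >= lfc_threshold;
    B_specific symmetric (boundary inclusive on |log2fc|); else common.
    """
    res = results.copy()
    sig = res["qvalue"] < q_threshold
    res["label"] = "common"
    res.loc[sig & (res["log2fc"] >= lfc_threshold), "label"] = "A_specific"
    res.loc[sig & (res["log2fc"] <= -lfc_threshold), "label"] = "B_specific"
    res.attrs["q_threshold"] = q_threshold
    res.attrs["lfc_threshold"] = lfc_threshold
    return res


def rank_by_change(
    results: pd.DataFrame, direction: str, top_fraction: float = 0.20
) -> list[str]:
    """The ceil(top_fraction * n) most decreased or increased sites by log2fc.

    Ties broken by smaller p-value, then site_id.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must lie in (0, 1]")
    if direction not in {"decreased", "increased"}:
        raise ValueError(f"direction must be 'decreased' or 'increased', got {direction!r}")
    k = math.ceil(top_fraction * len(results))
    asc = direction == "decreased"
    ordered = results.sort_values(
        ["log2fc", "pvalue", "site_id"],
        ascending=[asc, True, True],
        kind="mergesort",
    )
    return list(ordered["site_id"].iloc[:k])


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray

    def __post_init__(self):
        vf = np.asarray(self.variance_fraction, dtype=float)
        if np.any(np.diff(vf) > 1e-12) or vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must be nonincreasing and sum <= 1")


def binding_pca(m: SignalMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples in log2(signal + 1) site space.

    Sites are features, samples observations; features are mean-centered.
    Component signs are fixed by making the first sample's coordinate
    nonnegative on every component.
    """
    if m.values.shape[1] < 3:
        raise ValueError("PCA needs >= 3 samples")
    X = np.log2(m.values.to_numpy().T + 1.0)
    if np.allclose(X.var(axis=0).sum(), 0):
        raise ValueError("constant matrix has no variance to decompose")
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    flip = np.where(coords[0] < 0, -1.0, 1.0)
    coords = coords * flip
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=m.values.columns, columns=cols),
        variance_fraction=pca.explained_variance_ratio_,
    )
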