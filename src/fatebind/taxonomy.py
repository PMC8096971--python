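"""Site taxonomy: lineage/housekeeping deconvolution, acquired/retained
kinetics, promoter/distal annotation, and opposite-fate cross-referencing.

The taxonomy of a lineage factor's binding sites has three axes:

* specificity — bound in cell type A only, B only, common to both, or
  only in the progenitor;
* common subclass — common sites accessible only in the tissue's own
  lineage ("lineage" sites) versus accessible in all lineages
  ("housekeeping" sites), decided from multi-lineage pseudo-bulk
  accessibility;
* kinetics — cell-type-specific sites that are absent from progenitors
  and gained during differentiation ("acquired") versus already bound
  in progenitors and kept in one fate ("retained").
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import PeakSet, _merged_intervals, _overlaps_any
from .normalization import SignalMatrix

LINEAGES = ["epithelial", "endothelial", "immune", "mesenchymal"]
NON_TARGET_LINEAGES = ["endothelial", "immune", "mesenchymal"]
PSEUDOCOUNT = 1.0


def deconvolve_common(
    common_sites: Sequence[str],
    acc: pd.DataFrame,
    lfc_threshold: float = 1.0,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.Series:
    """Split common sites into lineage vs housekeeping by accessibility.

    A site is "lineage" iff its epithelial accessibility exceeds EVERY
    other lineage by log2 fold change >= lfc_threshold (pseudocounted);
    otherwise "housekeeping". ``acc`` is indexed by site_id with one
    column per lineage.
    """
    missing_cols = [c for c in LINEAGES if c not in acc.columns]
    if missing_cols:
        raise ValueError(f"accessibility table missing lineage columns: {missing_cols}")
    missing = [s for s in common_sites if s not in acc.index]
    if missing:
        raise ValueError(f"{len(missing)} common sites lack accessibility values")
    sub = acc.loc[list(common_sites)]
    epi = sub["epithelial"].to_numpy(dtype=float) + pseudocount
    is_lineage = np.ones(len(sub), dtype=bool)
    for other in NON_TARGET_LINEAGES:
        ratio = np.log2(epi / (sub[other].to_numpy(dtype=float) + pseudocount))
        is_lineage &= ratio >= lfc_threshold
    return pd.Series(
        np.where(is_lineage, "lineage", "housekeeping"), index=sub.index, name="common_subclass"
    )


def airway_low_subset(
    lineage_sites: Sequence[str],
    acc: pd.DataFrame,
    lfc_threshold: float = 1.0,
    pseudocount: float = PSEUDOCOUNT,
) -> list[str]:
    """Lineage sites with lower accessibility in airway cells than in the
    alveolar epithelium (log2 ratio >= lfc_threshold)."""
    if "airway" not in acc.columns:
        raise ValueError("accessibility table has no 'airway' column")
    sub = acc.loc[list(lineage_sites)]
    ratio = np.log2(
        (sub["epithelial"].to_numpy(dtype=float) + pseudocount)
        / (sub["airway"].to_numpy(dtype=float) + pseudocount)
    )
    return list(sub.index[ratio >= lfc_threshold])


def kinetic_classes(
    mature_vs_progenitor: pd.DataFrame, fraction: float = 0.20
) -> pd.Series:
    """Split one cell type's specific sites into acquired / retained /
    intermediate by their progenitor-to-mature binding change.

    ``mature_vs_progenitor`` needs columns site_id and log2fc where
    log2fc is mature-over-progenitor. The top ceil(fraction * n) sites
    (largest gain) are "acquired", the bottom ceil(fraction * n)
    (least change / most progenitor presence) "retained", the rest
    "intermediate". At fraction = 0.5 the split is an exhaustive
    bipartition (odd n: the median site joins the acquired window).
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must lie in (0, 0.5]; windows may not overlap")
    df = mature_vs_progenitor.sort_values(
        ["log2fc", "site_id"], ascending=[False, True], kind="mergesort"
    )
    n = len(df)
    k = math.ceil(fraction * n)
    labels = pd.Series("intermediate", index=df["site_id"], name="kinetics")
    labels.iloc[:k] = "acquired"
    labels.iloc[n - min(k, n - k):] = "retained"
    return labels.loc[mature_vs_progenitor["site_id"]]


def ranking_agreement(
    mature_vs_progenitor: pd.DataFrame, progenitor_signal: pd.Series
) -> float:
    """Spearman agreement between the fold-change ranking and the
    low-progenitor-presence ranking (diagnostic for the two phrasings of
    the acquired/retained sort)."""
    merged = mature_vs_progenitor.set_index("site_id")["log2fc"]
    rho = stats.spearmanr(merged, -progenitor_signal.loc[merged.index]).statistic
    return float(rho)


def kinetic_profiles(
    m: SignalMatrix,
    classes: pd.Series,
    timepoints: Sequence[str],
    condition: str | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-class, per-timepoint mean signal and log2 fold change vs the
    first timepoint.

    Samples may be restricted to one condition; progenitor-only
    timepoints (no sample of that condition) fall back to all samples at
    that timepoint. Adds a per-class monotonicity diagnostic.
    """
    if len(timepoints) < 2:
        raise ValueError("need >= 2 timepoints")
    rows = []
    for cls in sorted(classes.unique()):
        sites = classes.index[classes == cls]
        base = None
        for tp in timepoints:
            ids = m.sample_ids(timepoint=tp, condition=condition) if condition else []
            if not ids:
                ids = m.sample_ids(timepoint=tp)
            if not ids:
                raise ValueError(f"no samples at timepoint {tp!r}")
            mean = float(m.values.loc[sites, ids].to_numpy().mean())
            if base is None:
                base = mean
            rows.append(
                (cls, tp, mean, math.log2((mean + pseudocount) / (base + pseudocount)))
            )
    prof = pd.DataFrame(rows, columns=["kinetics", "timepoint", "mean_signal", "log2fc_vs_t0"])
    mono = (
        prof.groupby("kinetics")["mean_signal"]
        .apply(lambda s: bool(np.all(np.diff(s.to_numpy()) >= 0)))
        .rename("nondecreasing")
    )
    return prof.merge(mono, on="kinetics")


def opposite_fate_gain(
    increased_sites: PeakSet,
    binding_own: PeakSet,
    binding_opposite: PeakSet,
) -> tuple[pd.Series, dict[str, float]]:
    """Label mutant accessibility-gain sites by overlap with control binding.

    A gained site overlapping (>= 1 bp) the opposite fate's binding
    peakset is "opposite_bound"; else if it overlaps the mutant's own
    fate's peakset, "same_bound"; else "unbound". Returns per-site labels
    and the summary fractions.
    """
    labels = pd.Series("unbound", index=increased_sites.df["site_id"], name="gain_class")
    if len(increased_sites):
        if len(binding_opposite):
            opp = _overlaps_any(increased_sites.df, _merged_intervals(binding_opposite.df))
        else:
            opp = np.zeros(len(increased_sites), dtype=bool)
        if len(binding_own):
            own = _overlaps_any(increased_sites.df, _merged_intervals(binding_own.df))
        else:
            own = np.zeros(len(increased_sites), dtype=bool)
        labels.iloc[np.flatnonzero(own & ~opp)] = "same_bound"
        labels.iloc[np.flatnonzero(opp)] = "opposite_bound"
    n = max(len(labels), 1)
    fractions = {
        cls: float((labels == cls).sum()) / n
        for cls in ["opposite_bound", "same_bound", "unbound"]
    }
    return labels, fractions


def assemble_taxonomy(
    specificity: pd.Series,
    common_subclass: pd.Series | None = None,
    kinetics: pd.Series | None = None,
    locale: pd.Series | None = None,
) -> pd.DataFrame:
    """Combine per-axis labels into one taxonomy table.

    Sites absent from an axis get the neutral value for that axis
    ("none" subclass, "not_applicable" kinetics, "unannotated" locale).
    Common subclasses may only be attached to common sites.
    """
    tax = pd.DataFrame({"specificity": specificity})
    tax["common_subclass"] = "none"
    if common_subclass is not None:
        bad = [
            s for s in common_subclass.index
            if tax.loc[s, "specificity"] != "common"
        ]
        if bad:
            raise ValueError(f"subclass assigned to non-common sites, e.g. {bad[0]!r}")
        tax.loc[common_subclass.index, "common_subclass"] = common_subclass
    tax["kinetics"] = "not_applicable"
    if kinetics is not None:
        tax.loc[kinetics.index, "kinetics"] = kinetics
    tax["locale"] = "unannotated"
    if locale is not None:
        tax.loc[locale.index, "locale"] = locale
    tax.index.name = "site_id"
    return tax
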