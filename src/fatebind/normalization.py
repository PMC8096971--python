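"""Depth and foreground (FRiP-based) normalization of site x sample signal.

Foreground normalization divides each sample by FRiP x library depth —
the estimated number of in-peak reads — so that peak heights are
comparable across samples with different signal-to-background ratios.
The per-sample factors are rescaled by their geometric mean to keep the
output near the raw count scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genomic_io import PeakSet

SAMPLE_COLUMNS = ["sample_id", "condition", "timepoint", "replicate", "depth", "frip"]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    condition: str
    timepoint: str
    replicate: int
    depth: float
    frip: Optional[float] = None

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.frip is not None and not (0.0 <= self.frip <= 1.0):
            raise ValueError(f"frip must lie in [0, 1], got {self.frip}")


@dataclass
class SignalMatrix:
    """Nonnegative sites x samples signal with per-sample metadata.

    ``values``: DataFrame indexed by site_id with sample_id columns.
    ``samples``: DataFrame indexed by sample_id with columns condition,
    timepoint, replicate, depth, frip. ``norm`` tags applied normalization
    (None, "depth" or "foreground") and guards against double application.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    sites: Optional[PeakSet] = None
    norm: Optional[str] = None

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signal values must be nonnegative")
        if self.values.isna().to_numpy().any():
            raise ValueError("signal matrix has missing entries")
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing metadata: {missing}")
        self.samples = self.samples.loc[list(self.values.columns)]
        if (self.samples["depth"] <= 0).any():
            raise ValueError("depths must be positive")

    def sample_ids(self, **filters) -> list[str]:
        """Sample ids matching metadata equality filters, e.g. condition='A'."""
        mask = np.ones(len(self.samples), dtype=bool)
        for key, val in filters.items():
            mask &= (self.samples[key] == val).to_numpy()
        return list(self.samples.index[mask])


def compute_frip(reads_in_peaks: float, total_reads: float) -> float:
    """Fraction of reads in peaks."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not (0 <= reads_in_peaks <= total_reads):
        raise ValueError("reads_in_peaks must lie in [0, total_reads]")
    return reads_in_peaks / total_reads


def foreground_scale_factor(meta: SampleMeta) -> float:
    """FRiP x post-filtering library depth: the per-sample foreground size."""
    if meta.frip is None:
        raise ValueError(
            f"sample {meta.sample_id!r} has no FRiP; run compute_frip first"
        )
    return meta.frip * meta.depth


def normalize_matrix(m: SignalMatrix, mode: str = "depth") -> SignalMatrix:
    """Return a normalized copy of ``m``.

    depth: counts-per-million on library depth. foreground: divide by
    FRiP x depth, scale to counts-per-million, and multiply by the
    geometric mean of the FRiPs, so foreground-matched values stay on a
    CPM-like scale and the whole map is invariant to jointly rescaling
    raw values and depths.
    """
    if m.norm is not None:
        raise ValueError(f"matrix already normalized ({m.norm}); refusing to re-normalize")
    if mode == "depth":
        factors = m.samples["depth"].to_numpy(dtype=float)
        scaled = m.values / factors * 1e6
    elif mode == "foreground":
        frip = m.samples["frip"].to_numpy(dtype=float)
        if np.isnan(frip).any():
            bad = list(m.samples.index[np.isnan(frip)])
            raise ValueError(f"foreground mode needs FRiP for every sample; missing: {bad}")
        factors = frip * m.samples["depth"].to_numpy(dtype=float)
        if (factors <= 0).any():
            bad = list(m.samples.index[factors <= 0])
            raise ValueError(f"zero foreground scale factor for samples {bad}")
        # rescale by the geometric-mean FRiP so the output sits on the
        # counts-per-million scale and is invariant to a joint rescaling
        # of raw values and depths
        gm_frip = float(np.exp(np.mean(np.log(frip))))
        scaled = m.values / factors * 1e6 * gm_frip
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SignalMatrix(values=scaled, samples=m.samples.copy(), sites=m.sites, norm=mode)


def read_signal_matrix(values_path, samples_path) -> SignalMatrix:
    """Read a tab-delimited site_id x sample table plus a sample sheet."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return SignalMatrix(values=values, samples=samples)


def write_signal_matrix(m: SignalMatrix, values_path, samples_path) -> None:
    m.values.to_csv(values_path, sep="\t", index_label="site_id")
    m.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def write_bedgraph(peaks: PeakSet, values: pd.Series, path) -> None:
    """Emit one scaled value per site as a bedGraph track."""
    df = peaks.df
    with open(path, "w") as fh:
        for r in df.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{float(values[r.site_id]):g}\n")
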