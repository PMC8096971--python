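"""Seeded synthetic-data generator with planted ground truth.

Emulates the statistical structure of a lineage-factor binding study on
a toy genome: a six-way site taxonomy (cell-type-specific acquired and
retained sites for two fates, lineage and housekeeping common sites,
progenitor-specific sites), negative-binomial ChIP-like count matrices
whose means follow the planted binding kinetics across a progenitor ->
mature time course, multi-lineage pseudo-bulk accessibility, partner
motifs planted with controlled pairwise spacing, and bifurcating-
pseudotime expression coupled (or deliberately decoupled) to the
binding classes. Every emitted object is deterministic per seed; all
randomness flows from the top-level seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd

from .genomic_io import GeneModel, PeakSet, write_genes, write_peaks
from .motifs import MotifModel, load_bundled_motifs, reverse_complement
from .normalization import SignalMatrix, write_signal_matrix

SITE_CLASSES = [
    "A_specific_acquired",
    "A_specific_retained",
    "B_specific_acquired",
    "B_specific_retained",
    "lineage",
    "housekeeping",
    "progenitor_specific",
]

_SPECIFICITY = {
    "A_specific_acquired": "A_specific",
    "A_specific_retained": "A_specific",
    "B_specific_acquired": "B_specific",
    "B_specific_retained": "B_specific",
    "lineage": "common",
    "housekeeping": "common",
    "progenitor_specific": "progenitor_specific",
}
_KINETICS = {
    "A_specific_acquired": "acquired",
    "A_specific_retained": "retained",
    "B_specific_acquired": "acquired",
    "B_specific_retained": "retained",
}

# named RNG substreams hanging off the top-level seed
_STREAMS = {"sites": 1, "genome": 2, "binding": 3, "accessibility": 4,
            "motifs": 5, "expression": 6, "gains": 7}


@dataclass
class MotifPlan:
    """Which motifs are planted in which site classes, and pair spacing.

    ``fractions`` maps site class -> motif_id -> fraction of sites of
    that class receiving a planted instance (exact counts, random
    membership). When both motifs of ``pair`` land in one site their
    center-to-center distance is drawn from Normal(pair_mean, pair_sd),
    truncated to stay inside the site. ``degenerate`` samples instances
    from the PPM instead of writing the consensus.
    """

    fractions: dict = field(default_factory=lambda: {
        "A_specific_acquired": {"nkx": 0.55, "tead": 0.73},
        "A_specific_retained": {"nkx": 0.55, "tead": 0.73},
        "B_specific_acquired": {"nkx": 0.55, "tead": 0.23},
        "B_specific_retained": {"nkx": 0.55, "tead": 0.23},
        "lineage": {"nkx": 0.55, "tead": 0.35},
        "housekeeping": {"nkx": 0.55, "tead": 0.35, "ctcf": 0.30},
        "progenitor_specific": {"nkx": 0.55, "tead": 0.35},
    })
    pair: tuple = ("tead", "nkx")
    pair_mean: float = 52.0
    pair_sd: float = 5.0
    degenerate: bool = False


@dataclass
class GeneratorConfig:
    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000})
    n_sites: dict = field(default_factory=lambda: {
        "A_specific_acquired": 600, "A_specific_retained": 600,
        "B_specific_acquired": 600, "B_specific_retained": 600,
        "lineage": 300, "housekeeping": 300, "progenitor_specific": 300,
    })
    site_width: int = 500
    slot_width: int = 1200  # per-site territory: site + designated nearest gene
    effect_size: float = 3.0  # log2 bound/unbound separation
    nb_dispersion: float = 0.1
    baseline_log2_mean: float = 5.5
    baseline_log2_sd: float = 0.5
    sample_log2_sd: float = 0.15  # per-sample efficiency wobble
    timepoints: tuple = ("t0", "t1", "t2")
    n_replicates: int = 3
    acc_dispersion: float = 0.05
    airway_low_fraction: float = 0.3
    n_cells_per_branch: int = 300
    n_background_genes: int = 4000  # unlinked genes so control bins stay clean
    expression_amp: float = 2.0  # log2 dynamic range of fate programs
    expression_base_log2_mean: float = 4.0
    expression_base_log2_sd: float = 0.5
    expression_dispersion: float = 0.3
    # opposing fate programs occupy distinct absolute-expression ranges so
    # expression-matched control bins stay dominated by uncoupled genes
    program_base_offset_log2: float = 0.8
    program_base_sd_log2: float = 0.3
    pseudotime_max: float = 10.0
    motif_plan: MotifPlan = field(default_factory=MotifPlan)
    perturbation: str = "none"  # none | partner_loss | tf_loss
    n_gain_sites: int = 1500
    gain_opposite_fraction: float = 0.12
    gain_same_fraction: float = 0.05
    gain_width: int = 300

    def __post_init__(self):
        if any(v < 0 for v in self.n_sites.values()):
            raise ValueError("site counts must be >= 0")
        if self.nb_dispersion <= 0 or self.effect_size < 0:
            raise ValueError("dispersion must be > 0 and effect_size >= 0")
        if self.perturbation not in {"none", "partner_loss", "tf_loss"}:
            raise ValueError(f"unknown perturbation {self.perturbation!r}")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def plan_sites(cfg: GeneratorConfig) -> pd.DataFrame:
    """Deterministic site layout: coordinates, classes, designated genes.

    Sites occupy disjoint slots along the toy genome; each slot also
    carries the site's designated nearest gene a few hundred bp away, so
    nearest-TSS annotation recovers the planted linkage exactly.
    """
    n_total = sum(cfg.n_sites.values())
    capacity = sum(L // cfg.slot_width for L in cfg.chrom_lengths.values())
    if n_total > capacity:
        raise ValueError(
            f"genome too small for {n_total} sites: need >= "
            f"{n_total * cfg.slot_width} bp, have "
            f"{sum(cfg.chrom_lengths.values())} bp"
        )
    rng = cfg.rng("sites")
    per_class = [[c] * cfg.n_sites[c] for c in SITE_CLASSES if cfg.n_sites[c]]
    classes = np.concatenate(per_class) if per_class else np.array([], dtype=object)
    if len(classes):
        classes = classes[rng.permutation(len(classes))]
    rows = []
    slot_iter = (
        (chrom, s * cfg.slot_width)
        for chrom, L in cfg.chrom_lengths.items()
        for s in range(L // cfg.slot_width)
    )
    for i, cls in enumerate(classes):
        chrom, slot0 = next(slot_iter)
        start = slot0 + 100
        end = start + cfg.site_width
        # TSS 50-250 bp past the site: own-gene distance (300-500 bp from
        # the site center) always beats the neighboring slot's gene (>700)
        tss = end + int(rng.integers(50, 250))
        rows.append((f"site_{i + 1:05d}", cls, chrom, start, end, slot0,
                     f"gene_{i + 1:05d}", tss))
    truth = pd.DataFrame(
        rows, columns=["site_id", "class", "chrom", "start", "end", "slot0",
                       "gene_id", "tss"],
    )
    truth["specificity"] = truth["class"].map(_SPECIFICITY)
    truth["kinetics"] = truth["class"].map(_KINETICS).fillna("not_applicable")
    truth["common_subclass"] = np.where(
        truth["class"].isin(["lineage", "housekeeping"]), truth["class"], "none"
    )
    is_lineage = (truth["class"] == "lineage").to_numpy()
    airway_low = np.zeros(len(truth), dtype=bool)
    lineage_idx = np.flatnonzero(is_lineage)
    k = int(round(cfg.airway_low_fraction * len(lineage_idx)))
    airway_low[rng.permutation(lineage_idx)[:k]] = True
    truth["airway_low"] = airway_low
    return truth


def truth_peakset(truth: pd.DataFrame, cfg: GeneratorConfig) -> PeakSet:
    df = truth[["chrom", "start", "end", "site_id"]].copy()
    df["score"] = 10.0
    df["strand"] = "."
    df["summit"] = float(cfg.site_width // 2)
    return PeakSet(df)


def truth_genes(truth: pd.DataFrame) -> list[GeneModel]:
    return [GeneModel(r.gene_id, r.chrom, int(r.tss), "+") for r in truth.itertuples()]


def generate_genome_and_genes(cfg: GeneratorConfig):
    """Random toy genome plus the planted gene models.

    Returns (genome: chrom -> uint8 ASCII array, genes, peaks, truth);
    byte-identical across runs with the same config.
    """
    truth = plan_sites(cfg)
    rng = cfg.rng("genome")
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {
        chrom: alphabet[rng.integers(0, 4, size=L)]
        for chrom, L in cfg.chrom_lengths.items()
    }
    return genome, truth_genes(truth), truth_peakset(truth, cfg), truth


def genome_to_strings(genome: dict) -> dict[str, str]:
    return {c: seq.tobytes().decode() for c, seq in genome.items()}


def site_sequences(genome: dict, peaks: PeakSet) -> dict[str, str]:
    """Extract per-site sequences keyed by site_id."""
    seqs = {}
    for r in peaks.df.itertuples():
        seqs[r.site_id] = genome[r.chrom][r.start:r.end].tobytes().decode()
    return seqs


def _bound_indicator(cls: str, condition: str, tau: float) -> float:
    """Planted binding occupancy in [0, 1.5] for a site class in a sample.

    tau is the normalized time (0 = progenitor-stage, 1 = mature).
    Acquired sites ramp up in the target fate only; retained sites start
    bound and ramp down in the alternative fate; lineage/housekeeping
    sites are bound everywhere; progenitor-specific sites decay in both.
    """
    target = cls[0] if cls[0] in "AB" else None
    if cls in ("lineage", "housekeeping"):
        return 1.0
    if cls == "progenitor_specific":
        return 1.0 - tau
    acquired = cls.endswith("acquired")
    if condition == "progenitor":
        return 0.0 if acquired else 1.0
    if acquired:
        return tau if condition == target else 0.0
    return 1.0 if condition == target else 1.0 - tau


# whole-tissue occupancy used for the perturbation contrast: mature
# specific sites are bound in half the cells of an unsorted sample.
_CONTROL_IND = {"A_specific": 0.5, "B_specific": 0.5, "common": 1.0,
                "progenitor_specific": 0.0}
_PARTNER_LOSS_IND = {"A_specific": 0.0, "B_specific": 1.0, "common": 1.0,
                     "progenitor_specific": 0.0}


def generate_binding_signal(cfg: GeneratorConfig):
    """Per-site x per-sample NB binding counts over the time course.

    Returns (SignalMatrix of raw counts, PeakSet, truth). In
    ``partner_loss`` mode a second contrast matrix (whole-tissue control
    vs partner-factor mutant, 3 + 3 replicates) is attached as
    ``matrix.attrs['perturbation']``-style extra return via
    :func:`generate_perturbation_signal`.
    """
    truth = plan_sites(cfg)
    rng = cfg.rng("binding")
    baseline = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=len(truth))
    taus = np.linspace(0.0, 1.0, len(cfg.timepoints))
    samples = []
    for ti, tp in enumerate(cfg.timepoints):
        conds = ["progenitor"] if ti == 0 else ["A", "B"]
        for cond in conds:
            for rep in range(1, cfg.n_replicates + 1):
                samples.append((f"{cond}_{tp}_r{rep}", cond, tp, rep, taus[ti]))
    values = np.empty((len(truth), len(samples)))
    cls_arr = truth["class"].to_numpy()
    for j, (sid, cond, tp, rep, tau) in enumerate(samples):
        eff = 2.0 ** rng.normal(0.0, cfg.sample_log2_sd)
        b = np.array([_bound_indicator(c, cond, tau) for c in cls_arr])
        mu = baseline * (2.0 ** (cfg.effect_size * b)) * eff
        values[:, j] = _nb_draw(rng, mu, cfg.nb_dispersion)
    frips = rng.uniform(0.3, 0.6, size=len(samples))
    colsums = values.sum(axis=0)
    meta = pd.DataFrame(
        {
            "condition": [s[1] for s in samples],
            "timepoint": [s[2] for s in samples],
            "replicate": [s[3] for s in samples],
            "depth": np.maximum(colsums / frips, 1.0),
            "frip": frips,
        },
        index=pd.Index([s[0] for s in samples], name="sample_id"),
    )
    vdf = pd.DataFrame(values, index=truth["site_id"], columns=meta.index)
    peaks = truth_peakset(truth, cfg)
    return SignalMatrix(values=vdf, samples=meta, sites=peaks), peaks, truth


def generate_perturbation_signal(cfg: GeneratorConfig, truth: pd.DataFrame) -> SignalMatrix:
    """Control vs partner-loss-mutant binding counts (3 + 3 replicates).

    Cell-type-A-specific sites lose binding in the mutant, B-specific
    sites gain it; common sites are unaffected — the planted analogue of
    the partner-factor knockout contrast.
    """
    rng = np.random.default_rng([cfg.seed, _STREAMS["binding"], 99])
    baseline = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=len(truth))
    spec = truth["specificity"].to_numpy()
    samples, cols = [], []
    for cond, ind_map in (("control", _CONTROL_IND), ("mutant", _PARTNER_LOSS_IND)):
        b = np.array([ind_map[s] for s in spec])
        for rep in range(1, cfg.n_replicates + 1):
            eff = 2.0 ** rng.normal(0.0, cfg.sample_log2_sd)
            mu = baseline * (2.0 ** (cfg.effect_size * b)) * eff
            cols.append(_nb_draw(rng, mu, cfg.nb_dispersion))
            samples.append((f"{cond}_mut_r{rep}", cond, "mut", rep))
    values = np.column_stack(cols)
    frips = rng.uniform(0.3, 0.6, size=len(samples))
    meta = pd.DataFrame(
        {
            "condition": [s[1] for s in samples],
            "timepoint": [s[2] for s in samples],
            "replicate": [s[3] for s in samples],
            "depth": np.maximum(values.sum(axis=0) / frips, 1.0),
            "frip": frips,
        },
        index=pd.Index([s[0] for s in samples], name="sample_id"),
    )
    vdf = pd.DataFrame(values, index=truth["site_id"], columns=meta.index)
    return SignalMatrix(values=vdf, samples=meta)


def generate_two_factor_binding(
    cfg: GeneratorConfig,
    n_sites: int = 2000,
    temporal_lfc: float = 2.0,
    celltype_lfc: float = 1.0,
    temporal_fraction: float = 0.5,
    celltype_fraction: float = 0.25,
) -> SignalMatrix:
    """Binding counts with a dominant temporal factor plus a weaker
    cell-type factor — the planted structure behind a binding-matrix PCA.

    A ``temporal_fraction`` of sites gains ``temporal_lfc`` log2 units
    uniformly over the time course in both cell types; a disjoint-drawn
    ``celltype_fraction`` differs by ``celltype_lfc`` between the two
    cell types at every timepoint. Samples: 2 cell types x timepoints x
    replicates.
    """
    rng = np.random.default_rng([cfg.seed, _STREAMS["binding"], 7])
    baseline = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n_sites)
    t_load = (rng.random(n_sites) < temporal_fraction) * temporal_lfc
    c_load = (rng.random(n_sites) < celltype_fraction) * celltype_lfc
    taus = np.linspace(0.0, 1.0, len(cfg.timepoints))
    samples, cols = [], []
    for ti, tp in enumerate(cfg.timepoints):
        for cond, csign in (("A", +0.5), ("B", -0.5)):
            for rep in range(1, cfg.n_replicates + 1):
                eff = 2.0 ** rng.normal(0.0, cfg.sample_log2_sd)
                mu = baseline * 2.0 ** (t_load * taus[ti] + c_load * csign) * eff
                cols.append(_nb_draw(rng, mu, cfg.nb_dispersion))
                samples.append((f"{cond}_{tp}_r{rep}", cond, tp, rep))
    values = np.column_stack(cols)
    meta = pd.DataFrame(
        {
            "condition": [s[1] for s in samples],
            "timepoint": [s[2] for s in samples],
            "replicate": [s[3] for s in samples],
            "depth": np.maximum(values.sum(axis=0), 1.0),
            "frip": 0.5,
        },
        index=pd.Index([s[0] for s in samples], name="sample_id"),
    )
    vdf = pd.DataFrame(
        values, index=[f"site_{i + 1:05d}" for i in range(n_sites)], columns=meta.index
    )
    return SignalMatrix(values=vdf, samples=meta)


def generate_lineage_accessibility(cfg: GeneratorConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-site pseudo-bulk accessibility for the four tissue lineages
    plus an airway column.

    Lineage sites (and the factor's epithelial binding sites generally)
    are accessible 2^effect_size above baseline in the epithelial
    lineage only; housekeeping sites are equally accessible in all four.
    A planted fraction of lineage sites is additionally low in airway
    cells.
    """
    rng = cfg.rng("accessibility")
    n = len(truth)
    base = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
    hi = base * 2.0 ** cfg.effect_size
    cls = truth["class"].to_numpy()
    is_hk = cls == "housekeeping"
    cols = {}
    for lin in ("epithelial", "endothelial", "immune", "mesenchymal"):
        mean = hi if lin == "epithelial" else np.where(is_hk, hi, base)
        cols[lin] = _nb_draw(rng, mean, cfg.acc_dispersion)
    airway_mean = np.where(truth["airway_low"].to_numpy(), base, hi)
    cols["airway"] = _nb_draw(rng, airway_mean, cfg.acc_dispersion)
    return pd.DataFrame(cols, index=pd.Index(truth["site_id"], name="site_id"))


def _exact_fraction_mask(rng, n: int, fraction: float) -> np.ndarray:
    k = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:k]] = True
    return mask


def _instance(motif: MotifModel, degenerate: bool, rng) -> str:
    if not degenerate:
        return motif.consensus
    cols = [rng.choice(4, p=motif.ppm[:, j]) for j in range(motif.length)]
    return "".join("ACGT"[c] for c in cols)


def plant_motifs(cfg: GeneratorConfig, genome: dict, truth: pd.DataFrame):
    """Write motif instances into site sequences per the motif plan.

    Returns (genome with planted instances, placement truth table with
    site_id, motif_id, offset within the site, strand, center). Paired
    motifs get center-to-center spacing ~ Normal(pair_mean, pair_sd).
    """
    rng = cfg.rng("motifs")
    motifs = load_bundled_motifs()
    plan = cfg.motif_plan
    width = cfg.site_width
    pair_a, pair_b = plan.pair
    max_L = max(m.length for m in motifs.values())
    if width < 2 * (plan.pair_mean + 6 * plan.pair_sd) and width < 200:
        raise ValueError("site too short for the requested pair spacing")
    genome = {c: seq.copy() for c, seq in genome.items()}
    placements = []

    def _write(site_row, motif: MotifModel, center: int):
        L = motif.length
        offset = int(center) - L // 2
        strand = "+" if rng.random() < 0.5 else "-"
        inst = _instance(motif, plan.degenerate, rng)
        if strand == "-":
            inst = reverse_complement(inst)
        pos = site_row.start + offset
        genome[site_row.chrom][pos:pos + L] = np.frombuffer(inst.encode(), dtype=np.uint8)
        placements.append((site_row.site_id, motif.motif_id, offset, strand, offset + L // 2))

    lo, hi_c = max_L // 2 + 1, width - max_L // 2 - 2
    for cls, sub in truth.groupby("class", sort=True):
        fracs = plan.fractions.get(cls, {})
        masks = {
            mid: _exact_fraction_mask(rng, len(sub), f) for mid, f in sorted(fracs.items())
        }
        for i, row in enumerate(sub.itertuples()):
            present = [mid for mid, mask in masks.items() if mask[i]]
            paired = pair_a in present and pair_b in present
            if paired:
                c1 = int(rng.integers(90, width - 90))
                d = float(np.clip(rng.normal(plan.pair_mean, plan.pair_sd), 12, 80))
                sign = 1 if rng.random() < 0.5 else -1
                c2 = int(round(c1 + sign * d))
                if not (lo <= c2 <= hi_c):
                    c2 = int(round(c1 - sign * d))
                _write(row, motifs[pair_b], c1)
                _write(row, motifs[pair_a], c2)
            for mid in present:
                if paired and mid in (pair_a, pair_b):
                    continue
                _write(row, motifs[mid], int(rng.integers(lo, hi_c + 1)))
    placement_df = pd.DataFrame(
        placements, columns=["site_id", "motif_id", "offset", "strand", "center"]
    )
    return genome, placement_df


def _expression_program(cfg: GeneratorConfig, truth: pd.DataFrame,
                        gain_opposite_genes: set[str] | None = None):
    """Per-gene (group, base mean) for the expression generator."""
    rng = cfg.rng("expression")
    gene_ids = list(truth["gene_id"]) + [
        f"gene_bg_{i + 1:05d}" for i in range(cfg.n_background_genes)
    ]
    group = {}
    for r in truth.itertuples():
        if gain_opposite_genes and r.gene_id in gain_opposite_genes:
            group[r.gene_id] = "gain_flat"
        elif r.specificity == "A_specific":
            group[r.gene_id] = "A_program"
        elif r.specificity == "B_specific":
            group[r.gene_id] = "B_program"
        elif r.common_subclass == "lineage":
            group[r.gene_id] = "lineage_high"
        else:
            group[r.gene_id] = "flat"
    groups = np.array([group.get(g, "flat") for g in gene_ids])
    mean_log2 = np.full(len(gene_ids), cfg.expression_base_log2_mean)
    sd_log2 = np.full(len(gene_ids), cfg.expression_base_log2_sd)
    mean_log2[groups == "A_program"] += cfg.program_base_offset_log2
    mean_log2[groups == "B_program"] -= cfg.program_base_offset_log2
    prog = np.isin(groups, ["A_program", "B_program"])
    sd_log2[prog] = cfg.program_base_sd_log2
    base = 2.0 ** rng.normal(mean_log2, sd_log2)
    return rng, gene_ids, base, groups


def generate_expression(cfg: GeneratorConfig, truth: pd.DataFrame,
                        gain_truth: pd.DataFrame | None = None) -> ad.AnnData:
    """Cells x genes expression coupled to the planted binding classes.

    Default: a bifurcating trajectory — branches A and B from a shared
    progenitor state, pseudotime in [0, T]. Genes linked to A-specific
    sites (acquired and retained alike) follow a low -> high program
    along branch A only, so progenitor cells score low on retained-site
    gene sets even though those sites are planted as progenitor-bound:
    the binding/expression dissociation is built in.

    partner_loss: one merged trajectory (fate A -> exaggerated fate B);
    A-linked genes fall and B-linked genes rise along it.

    tf_loss: one merged trajectory in which genes of opposite-fate
    accessibility-gain sites stay flat (accessibility without
    expression); requires ``gain_truth`` from
    :func:`generate_opposite_fate_gains`.

    X is log1p-normalized; raw counts sit in ``layers['counts']``.
    """
    gain_genes = None
    if cfg.perturbation == "tf_loss":
        if gain_truth is None:
            raise ValueError("tf_loss mode needs the opposite-fate gain truth table")
        src = gain_truth.loc[gain_truth["gain_class"] == "opposite_bound", "source_site_id"]
        gain_genes = set(truth.set_index("site_id").loc[src, "gene_id"])
    rng, gene_ids, base, groups = _expression_program(cfg, truth, gain_genes)
    T = cfg.pseudotime_max
    if cfg.perturbation == "none":
        n = cfg.n_cells_per_branch
        branches = np.array(["A"] * n + ["B"] * n)
        pt = rng.uniform(0, T, size=2 * n)
    else:
        n = 2 * cfg.n_cells_per_branch
        branches = np.array(["merged"] * n)
        pt = rng.uniform(0, T, size=n)
    ramp = np.clip(pt / T, 0, 1)
    amp = cfg.expression_amp
    log2_shift = np.zeros((len(pt), len(gene_ids)))
    if cfg.perturbation == "none":
        onA = (branches == "A").astype(float)
        onB = (branches == "B").astype(float)
        log2_shift[:, groups == "A_program"] = (amp * ramp * onA)[:, None]
        log2_shift[:, groups == "B_program"] = (amp * ramp * onB)[:, None]
    elif cfg.perturbation == "partner_loss":
        log2_shift[:, groups == "A_program"] = (amp * (1 - ramp))[:, None]
        log2_shift[:, groups == "B_program"] = (amp * ramp)[:, None]
    else:  # tf_loss: own-fate program decays; gain_flat genes stay flat
        log2_shift[:, groups == "A_program"] = (amp * (1 - ramp))[:, None]
    log2_shift[:, groups == "lineage_high"] = amp * 0.5
    mu = base[None, :] * 2.0 ** log2_shift
    counts = _nb_draw(rng, mu, cfg.expression_dispersion)
    # no per-cell depth is planted, so X is log1p of the raw counts; a
    # per-cell rescaling would only inject compositional artifacts
    X = np.log1p(counts)
    tercile = np.minimum((ramp * 3).astype(int), 2)
    obs = pd.DataFrame(
        {
            "pseudotime": pt,
            "branch": branches,
            "sample": np.array(["early", "mid", "late"])[tercile],
        },
        index=pd.Index([f"cell_{i + 1:05d}" for i in range(len(pt))], name="cell_id"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")))
    adata.layers["counts"] = counts
    return adata


def generate_opposite_fate_gains(cfg: GeneratorConfig, truth: pd.DataFrame):
    """Mutant accessibility-gain sites for the tf_loss cross-reference.

    The mutant's own fate is A; a planted fraction of gains falls on
    B-specific (opposite-fate) binding sites, a smaller fraction on
    A-specific sites, the rest on unbound territory. Returns
    (PeakSet of gains, truth with gain_class and source_site_id).
    """
    rng = cfg.rng("gains")
    n = cfg.n_gain_sites
    n_opp = int(round(cfg.gain_opposite_fraction * n))
    n_same = int(round(cfg.gain_same_fraction * n))
    tr = truth.set_index("site_id")
    b_sites = tr.index[tr["specificity"] == "B_specific"].to_numpy()
    a_sites = tr.index[tr["specificity"] == "A_specific"].to_numpy()
    rows, labels = [], []

    def _from_source(source_ids, label):
        for sid in source_ids:
            r = tr.loc[sid]
            shift = int(rng.integers(-100, 101))
            start = max(int(r["start"]) + shift, 0)
            rows.append((r["chrom"], start, start + cfg.site_width, sid))
            labels.append(label)

    _from_source(rng.choice(b_sites, size=n_opp, replace=False), "opposite_bound")
    _from_source(rng.choice(a_sites, size=n_same, replace=False), "same_bound")
    free_slots = tr.iloc[rng.choice(len(tr), size=n - n_opp - n_same, replace=False)]
    for _, r in free_slots.iterrows():
        start = int(r["slot0"]) + 650 + int(rng.integers(0, 200))
        rows.append((r["chrom"], start, start + cfg.gain_width, None))
        labels.append("unbound")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "source_site_id"])
    df["site_id"] = [f"gain_{i + 1:05d}" for i in range(len(df))]
    gains = PeakSet(df[["chrom", "start", "end", "site_id"]].assign(strand=".", score=np.nan))
    gain_truth = df[["site_id", "source_site_id"]].copy()
    gain_truth["gain_class"] = labels
    return gains, gain_truth.set_index("site_id").loc[gains.df["site_id"]].reset_index()


@dataclass
class SyntheticWorkspace:
    """Everything the pipeline consumes, plus planted truth."""

    cfg: GeneratorConfig
    genome: dict
    genes: list
    peaks: PeakSet
    truth: pd.DataFrame
    binding: SignalMatrix
    accessibility: pd.DataFrame
    motif_truth: pd.DataFrame
    expression: ad.AnnData
    perturbation_binding: Optional[SignalMatrix] = None
    gains: Optional[PeakSet] = None
    gain_truth: Optional[pd.DataFrame] = None

    @property
    def sequences(self) -> dict[str, str]:
        return site_sequences(self.genome, self.peaks)


def generate_workspace(cfg: GeneratorConfig, outdir: str | Path | None = None) -> SyntheticWorkspace:
    """Generate every pipeline input (and truth) for one config; optionally
    write the standard file layout under ``outdir``."""
    genome, genes, peaks, truth = generate_genome_and_genes(cfg)
    binding, _, _ = generate_binding_signal(cfg)
    acc = generate_lineage_accessibility(cfg, truth)
    genome, motif_truth = plant_motifs(cfg, genome, truth)
    gains = gain_truth = perturbation = None
    if cfg.perturbation == "partner_loss":
        perturbation = generate_perturbation_signal(cfg, truth)
    if cfg.perturbation == "tf_loss":
        gains, gain_truth = generate_opposite_fate_gains(cfg, truth)
    expression = generate_expression(cfg, truth, gain_truth)
    ws = SyntheticWorkspace(
        cfg=cfg, genome=genome, genes=genes, peaks=peaks, truth=truth,
        binding=binding, accessibility=acc, motif_truth=motif_truth,
        expression=expression, perturbation_binding=perturbation,
        gains=gains, gain_truth=gain_truth,
    )
    if outdir is not None:
        write_workspace(ws, Path(outdir))
    return ws


def write_workspace(ws: SyntheticWorkspace, outdir: Path) -> None:
    """Write the workspace in the plain-text layout the pipeline reads."""
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in genome_to_strings(ws.genome).items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_genes(ws.genes, outdir / "genes.tsv")
    write_peaks(ws.peaks, outdir / "peaks.narrowPeak", format="narrowPeak")
    write_signal_matrix(ws.binding, outdir / "binding.tsv", outdir / "binding_samples.tsv")
    ws.accessibility.to_csv(outdir / "accessibility.tsv", sep="\t")
    ws.motif_truth.to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)
    ws.truth.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    from .modulescore import write_expression

    write_expression(ws.expression, outdir / "expression.tsv", outdir / "cells.tsv")
    if ws.perturbation_binding is not None:
        write_signal_matrix(
            ws.perturbation_binding,
            outdir / "perturbation_binding.tsv",
            outdir / "perturbation_samples.tsv",
        )
    if ws.gains is not None:
        write_peaks(ws.gains, outdir / "gains.bed", format="bed")
        ws.gain_truth.to_csv(outdir / "truth_gains.tsv", sep="\t", index=False)
    def _plain(obj):
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    cfg_echo = {k: _plain(v) for k, v in vars(ws.cfg).items() if k != "motif_plan"}
    cfg_echo["motif_plan"] = _plain(vars(replace(ws.cfg.motif_plan)))
    import yaml

    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(cfg_echo, fh, default_flow_style=False)
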