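"""End-to-end orchestration: io -> normalize -> differential -> classify
-> kinetics -> motif -> module_score -> crossref.

Consumes a plain-text workspace (the layout written by
:func:`fatebind.synth.write_workspace`, equally producible from real
data), writes tab-delimited stage outputs plus a Markdown report with
per-stage parameters, counts and output checksums. A rerun with the
same config and seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential as diffmod
from . import genomic_io as gio
from . import modulescore as ms
from . import motifs as mot
from . import taxonomy as tax
from .normalization import SignalMatrix, normalize_matrix, read_signal_matrix

logger = logging.getLogger(__name__)

ALL_STAGES = ("io", "normalize", "differential", "classify", "kinetics",
              "motif", "module_score", "crossref")

#: stage dependencies, used to auto-enable prerequisites
_REQUIRES = {
    "normalize": ("io",),
    "differential": ("io", "normalize"),
    "classify": ("io", "normalize", "differential"),
    "kinetics": ("io", "normalize", "differential", "classify"),
    "motif": ("io",),
    "module_score": ("io", "normalize", "differential", "classify", "kinetics"),
    "crossref": ("io", "normalize", "differential", "classify"),
}


@dataclass
class PipelineConfig:
    workspace: Path
    out_dir: Path
    seed: int = 0
    q_threshold: float = 0.05
    lfc_threshold: float = 1.0
    kinetics_fraction: float = 0.20
    distal_bp: int = 2000
    motif_rel_threshold: float = 0.8
    stages: tuple = ALL_STAGES
    n_score_bins: int = 24
    n_ctrl: int = 100

    def __post_init__(self):
        self.workspace = Path(self.workspace)
        self.out_dir = Path(self.out_dir)
        wanted = set(self.stages)
        for st in self.stages:
            wanted.update(_REQUIRES.get(st, ()))
        self.stages = tuple(s for s in ALL_STAGES if s in wanted)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return a list of problems; empty iff run_pipeline can start."""
    problems = []
    ws = cfg.workspace
    needed = ["peaks.narrowPeak", "genes.tsv", "binding.tsv", "binding_samples.tsv"]
    if "classify" in cfg.stages:
        needed.append("accessibility.tsv")
    if "motif" in cfg.stages:
        needed.append("genome.fa")
    if "module_score" in cfg.stages:
        needed += ["expression.tsv", "cells.tsv"]
    for name in needed:
        if not (ws / name).exists():
            problems.append(f"missing input file: {ws / name}")
    if not (0 < cfg.q_threshold < 1):
        problems.append(f"q_threshold {cfg.q_threshold} outside (0, 1)")
    if cfg.lfc_threshold < 0:
        problems.append(f"lfc_threshold {cfg.lfc_threshold} must be >= 0")
    if not (0 < cfg.kinetics_fraction <= 0.5):
        problems.append(
            f"kinetics_fraction {cfg.kinetics_fraction} outside (0, 0.5]"
        )
    if cfg.distal_bp <= 0:
        problems.append(f"distal_bp {cfg.distal_bp} must be positive")
    if not (0 < cfg.motif_rel_threshold <= 1):
        problems.append(f"motif_rel_threshold {cfg.motif_rel_threshold} outside (0, 1]")
    unknown = [s for s in cfg.stages if s not in ALL_STAGES]
    if unknown:
        problems.append(f"unknown stages: {unknown}")
    return problems


def _read_fasta(path) -> dict[str, np.ndarray]:
    from Bio import SeqIO

    return {
        rec.id: np.frombuffer(str(rec.seq).upper().encode(), dtype=np.uint8)
        for rec in SeqIO.parse(str(path), "fasta")
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)

    def record(self, stage: str, **info):
        self.stages[stage] = info

    def to_json(self, path: Path):
        with open(path, "w") as fh:
            json.dump(
                {"stages": self.stages, "counts": self.counts, "checksums": self.checksums},
                fh, indent=2, default=str,
            )

    def to_markdown(self, path: Path):
        lines = ["# Pipeline run report", ""]
        if self.counts:
            lines += ["## Site counts", ""]
            for key, val in self.counts.items():
                lines.append(f"- {key}: {val}")
            lines.append("")
        for stage, info in self.stages.items():
            lines += [f"## Stage: {stage}", ""]
            for key, val in info.items():
                lines.append(f"- {key}: {val}")
            lines.append("")
        lines += ["## Output checksums", ""]
        for name, digest in sorted(self.checksums.items()):
            lines.append(f"- {name}: {digest}")
        path.write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the configured stages in dependency order."""
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid pipeline config:\n" + "\n".join(problems))
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    state: dict = {}
    written: list[Path] = []

    def _write_df(df: pd.DataFrame, name: str, index=False, **kw):
        path = cfg.out_dir / name
        df.to_csv(path, sep="\t", index=index, **kw)
        written.append(path)

    for stage in cfg.stages:
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](cfg, state, report, _write_df)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.1fs", stage, time.time() - t0)
    for path in written:
        report.checksums[path.name] = _sha256(path)
    report.to_json(cfg.out_dir / "run_report.json")
    report.to_markdown(cfg.out_dir / "report.md")
    return report


def _stage_io(cfg, state, report, _write_df):
    ws = cfg.workspace
    state["peaks"] = gio.read_peaks(ws / "peaks.narrowPeak", format="narrowPeak")
    state["genes"] = gio.read_genes(ws / "genes.tsv")
    state["binding"] = read_signal_matrix(ws / "binding.tsv", ws / "binding_samples.tsv")
    if (ws / "accessibility.tsv").exists():
        state["accessibility"] = pd.read_csv(ws / "accessibility.tsv", sep="\t", index_col=0)
    if (ws / "genome.fa").exists() and "motif" in cfg.stages:
        state["genome"] = _read_fasta(ws / "genome.fa")
    if (ws / "expression.tsv").exists() and "module_score" in cfg.stages:
        state["expression"] = ms.read_expression(ws / "expression.tsv", ws / "cells.tsv")
    if (ws / "perturbation_binding.tsv").exists():
        state["perturbation"] = read_signal_matrix(
            ws / "perturbation_binding.tsv", ws / "perturbation_samples.tsv"
        )
    if (ws / "gains.bed").exists():
        state["gains"] = gio.read_peaks(ws / "gains.bed", format="bed")
    report.record(
        "io", n_peaks=len(state["peaks"]), n_genes=len(state["genes"]),
        n_samples=state["binding"].values.shape[1],
    )


def _stage_normalize(cfg, state, report, _write_df):
    state["normalized"] = normalize_matrix(state["binding"], "depth")
    report.record("normalize", mode="depth")


def _stage_differential(cfg, state, report, _write_df):
    m = state["normalized"]
    tps = list(dict.fromkeys(m.samples["timepoint"]))
    last = tps[-1]
    group_a = m.sample_ids(condition="A", timepoint=last)
    group_b = m.sample_ids(condition="B", timepoint=last)
    res = diffmod.differential_test(m, group_a, group_b)
    res = diffmod.classify_specificity(res, cfg.q_threshold, cfg.lfc_threshold)
    state["diff_ab"] = res
    state["timepoints"] = tps
    _write_df(res, "differential_A_vs_B.tsv")
    report.record(
        "differential", contrast=f"A vs B at {last}", q_threshold=cfg.q_threshold,
        lfc_threshold=cfg.lfc_threshold,
        n_A_specific=int((res["label"] == "A_specific").sum()),
        n_B_specific=int((res["label"] == "B_specific").sum()),
        n_common=int((res["label"] == "common").sum()),
    )


def _stage_classify(cfg, state, report, _write_df):
    m = state["normalized"]
    res = state["diff_ab"].set_index("site_id")
    tps = state["timepoints"]
    spec = res["label"].copy().rename("specificity")
    # progenitor-specific: common sites losing binding from t0 to maturity
    # in BOTH fates (tested per fate so within-group variance stays clean)
    prog = m.sample_ids(timepoint=tps[0])
    lost = {}
    for fate in ("A", "B"):
        mature = m.sample_ids(condition=fate, timepoint=tps[-1])
        pm = diffmod.differential_test(m, prog, mature)
        pm = diffmod.classify_specificity(pm, cfg.q_threshold, cfg.lfc_threshold)
        lost[fate] = pm.set_index("site_id")["label"] == "A_specific"
    common_ids = spec.index[spec == "common"]
    prog_specific = [s for s in common_ids if lost["A"][s] and lost["B"][s]]
    spec.loc[prog_specific] = "progenitor_specific"
    common_ids = spec.index[spec == "common"]
    subclass = tax.deconvolve_common(
        list(common_ids), state["accessibility"], cfg.lfc_threshold
    )
    lineage_ids = list(subclass.index[subclass == "lineage"])
    airway_low = (
        tax.airway_low_subset(lineage_ids, state["accessibility"], cfg.lfc_threshold)
        if "airway" in state["accessibility"].columns and lineage_ids else []
    )
    ann = gio.nearest_tss(state["peaks"], state["genes"])
    state["annotation"] = ann
    locale = ann.set_index("site_id")["locale"]
    taxonomy = tax.assemble_taxonomy(spec, subclass, locale=locale)
    taxonomy["airway_low"] = taxonomy.index.isin(airway_low)
    state["taxonomy"] = taxonomy
    _write_df(taxonomy.reset_index(), "taxonomy.tsv")
    counts = taxonomy["specificity"].value_counts().to_dict()
    counts.update({f"common_{k}": v for k, v in
                   taxonomy["common_subclass"].value_counts().to_dict().items()
                   if k != "none"})
    counts["airway_low"] = int(taxonomy["airway_low"].sum())
    report.counts.update(counts)
    report.record("classify", thresholds=dict(q=cfg.q_threshold, lfc=cfg.lfc_threshold),
                  n_prog_specific=len(prog_specific))


def _stage_kinetics(cfg, state, report, _write_df):
    m = state["normalized"]
    taxonomy = state["taxonomy"]
    tps = state["timepoints"]
    prog = m.sample_ids(timepoint=tps[0])
    kin_all = {}
    for fate in ("A", "B"):
        ids = taxonomy.index[taxonomy["specificity"] == f"{fate}_specific"]
        if len(ids) < 4:
            continue
        mature = m.sample_ids(condition=fate, timepoint=tps[-1])
        res = diffmod.differential_test(
            SignalMatrix(m.values.loc[ids], m.samples, norm=m.norm), mature, prog
        )
        kin_all[fate] = tax.kinetic_classes(res, cfg.kinetics_fraction)
    kinetics = pd.concat(kin_all.values()) if kin_all else pd.Series(dtype=object)
    taxonomy["kinetics"] = "not_applicable"
    taxonomy.loc[kinetics.index, "kinetics"] = kinetics
    _write_df(taxonomy.reset_index(), "taxonomy.tsv")
    profiles = []
    for fate, kin in kin_all.items():
        prof = tax.kinetic_profiles(m, kin, tps, condition=fate)
        prof.insert(0, "fate", fate)
        profiles.append(prof)
    if profiles:
        _write_df(pd.concat(profiles, ignore_index=True), "kinetic_profiles.tsv")
    report.record("kinetics", fraction=cfg.kinetics_fraction,
                  n_acquired=int((taxonomy["kinetics"] == "acquired").sum()),
                  n_retained=int((taxonomy["kinetics"] == "retained").sum()))


def _stage_motif(cfg, state, report, _write_df):
    from .synth import site_sequences

    seqs = site_sequences(state["genome"], state["peaks"])
    motifs = mot.load_bundled_motifs(cfg.motif_rel_threshold)
    hits = mot.scan_sites(seqs, [motifs["nkx"], motifs["tead"], motifs["ctcf"]])
    state["hits"] = hits
    _write_df(hits, "motif_hits.tsv")
    taxonomy = state.get("taxonomy")
    if taxonomy is not None:
        sets = {
            name: list(taxonomy.index[taxonomy["specificity"] == name])
            for name in ("A_specific", "B_specific", "common")
        }
        sets = {k: v for k, v in sets.items() if v}
        cooc = mot.cooccurrence_fraction(sets, hits, "tead")
        _write_df(cooc.rename_axis("site_set").reset_index(), "tead_cooccurrence.tsv")
        report.record("motif", rel_threshold=cfg.motif_rel_threshold,
                      tead_cooccurrence=cooc.round(4).to_dict())
    _, mean_sp, n_sp = mot.motif_spacing(hits, "tead", "nkx")
    report.stages.setdefault("motif", {})["tead_nkx_spacing_bp"] = (
        None if np.isnan(mean_sp) else round(mean_sp, 2)
    )
    report.stages["motif"]["n_spacing_sites"] = n_sp


def _stage_module_score(cfg, state, report, _write_df):
    expr = state["expression"]
    taxonomy = state["taxonomy"]
    ann = state["annotation"]
    rows = []
    tracks = {}
    for fate in ("A", "B"):
        for kin in ("acquired", "retained"):
            ids = taxonomy.index[
                (taxonomy["specificity"] == f"{fate}_specific")
                & (taxonomy["kinetics"] == kin)
            ]
            if not len(ids):
                continue
            genes = ms.sites_to_gene_set(list(ids), ann)
            track = ms.compute_module_score(
                expr, genes, gene_set_id=f"{fate}_{kin}",
                n_bins=cfg.n_score_bins, n_ctrl=cfg.n_ctrl, seed=cfg.seed,
            )
            tracks[track.gene_set_id] = track
            for branch in expr.obs["branch"].unique():
                cells = expr.obs_names[expr.obs["branch"] == branch]
                _, rho = ms.trend_along_pseudotime(
                    track.scores.loc[cells], expr.obs["pseudotime"]
                )
                rows.append((track.gene_set_id, branch, len(genes), rho))
    state["score_tracks"] = tracks
    trends = pd.DataFrame(rows, columns=["gene_set", "branch", "n_genes", "spearman_rho"])
    _write_df(trends, "module_score_trends.tsv")
    scores = pd.DataFrame({k: t.scores for k, t in tracks.items()})
    _write_df(scores.rename_axis("cell_id").reset_index(), "module_scores.tsv")
    report.record("module_score", seed=cfg.seed, n_bins=cfg.n_score_bins,
                  n_ctrl=cfg.n_ctrl,
                  trends={f"{r.gene_set}/{r.branch}": round(r.spearman_rho, 3)
                          for r in trends.itertuples()})


def _stage_crossref(cfg, state, report, _write_df):
    gains = state.get("gains")
    if gains is None:
        report.record("crossref", skipped="no gains.bed in workspace")
        return
    taxonomy = state["taxonomy"]
    peaks = state["peaks"]
    own = peaks.df[peaks.df["site_id"].isin(
        taxonomy.index[taxonomy["specificity"] == "A_specific"])]
    opp = peaks.df[peaks.df["site_id"].isin(
        taxonomy.index[taxonomy["specificity"] == "B_specific"])]
    labels, fractions = tax.opposite_fate_gain(
        gains, gio.PeakSet(own.copy()), gio.PeakSet(opp.copy())
    )
    _write_df(labels.rename_axis("site_id").reset_index(), "opposite_fate_gains.tsv")
    report.record("crossref", own_fate="A", **{f"fraction_{k}": round(v, 4)
                                               for k, v in fractions.items()})


_STAGE_FUNCS = {
    "io": _stage_io,
    "normalize": _stage_normalize,
    "differential": _stage_differential,
    "classify": _stage_classify,
    "kinetics": _stage_kinetics,
    "motif": _stage_motif,
    "module_score": _stage_module_score,
    "crossref": _stage_crossref,
}
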