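"""Known-motif scanning and motif statistics over binding-site sequences.

A motif is a position-probability matrix (PPM); scanning scores every
offset of a sequence on both strands with the log2 odds of the PPM
against a background base composition and keeps offsets at or above the
motif's score threshold (by default 80% of the maximum attainable
score). Enrichment of a motif in a target set over a background set is
tested with an upper-tail binomial; co-occurrence and spacing statistics
summarize partner-motif geometry within sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)} | {"N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BUNDLED_MOTIFS = ("nkx", "tead", "cebp", "ctcf", "foxa")

#: fraction of the maximum attainable log-odds score used as the default
#: hit threshold; relative so it adapts across motif lengths.
DEFAULT_REL_THRESHOLD = 0.8


@dataclass
class MotifModel:
    """A position-probability matrix with background and hit threshold."""

    motif_id: str
    ppm: np.ndarray  # 4 x L, rows A, C, G, T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    score_threshold: float | None = None  # log-odds bits; None -> 80% of max

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.ppm.shape[0] != 4 or self.ppm.shape[1] < 4:
            raise ValueError("ppm must be 4 x L with L >= 4")
        if not np.allclose(self.ppm.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("ppm columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        if self.score_threshold is None:
            self.score_threshold = DEFAULT_REL_THRESHOLD * self.max_score

    @property
    def length(self) -> int:
        return self.ppm.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.ppm / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.ppm.argmax(axis=0))


def load_motif(path, motif_id: str | None = None, rel_threshold: float = DEFAULT_REL_THRESHOLD) -> MotifModel:
    """Read a PPM in the minimal tabular format: an optional ``>name``
    header then four tab-separated rows A, C, G, T of probabilities."""
    rows = {}
    name = motif_id
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = name or line[1:].strip()
                continue
            parts = line.replace(":", "\t").split()
            rows[parts[0].upper()] = [float(x) for x in parts[1:]]
    missing = [b for b in BASES if b not in rows]
    if missing:
        raise ValueError(f"{path}: missing rows for bases {missing}")
    ppm = np.array([rows[b] for b in BASES])
    model = MotifModel(name or "motif", ppm)
    model.score_threshold = rel_threshold * model.max_score
    return model


def save_motif(motif: MotifModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{motif.motif_id}\n")
        for i, b in enumerate(BASES):
            fh.write(b + "\t" + "\t".join(f"{p:.4f}" for p in motif.ppm[i]) + "\n")


def load_bundled_motifs(rel_threshold: float = DEFAULT_REL_THRESHOLD) -> dict[str, MotifModel]:
    """The package's fixture PPMs (NKX, TEAD, CEBP, CTCF, FOXA)."""
    out = {}
    for name in BUNDLED_MOTIFS:
        ref = resources.files("fatebind.data.motifs") / f"{name}.ppm"
        with resources.as_file(ref) as path:
            out[name] = load_motif(path, motif_id=name, rel_threshold=rel_threshold)
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(128, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    codes = lut[arr]
    if (codes == 4).any() and not set(seq.upper()) <= set("ACGTN"):
        bad = sorted(set(seq.upper()) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    return codes


_HIT_COLUMNS = ["site_id", "motif_id", "offset", "strand", "score", "center"]


def _hit_rows(codes: np.ndarray, motif: MotifModel, site_id: str) -> list[tuple]:
    """Hit tuples for one integer-encoded sequence, ordered (offset, strand)."""
    L = motif.length
    if len(codes) < L:
        return []
    lom = np.vstack([motif.log_odds, np.full((1, L), -np.inf)])  # row 4: N
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    fwd = lom[windows, np.arange(L)].sum(axis=1)
    # '-' strand: score the reverse complement of each window
    lom_rc = lom[[3, 2, 1, 0, 4], :][:, ::-1]
    rev = lom_rc[windows, np.arange(L)].sum(axis=1)
    rows = []
    for offset in np.flatnonzero(
        (fwd >= motif.score_threshold) | (rev >= motif.score_threshold)
    ):
        for strand, score in (("+", fwd[offset]), ("-", rev[offset])):
            if score >= motif.score_threshold:
                rows.append(
                    (site_id, motif.motif_id, int(offset), strand, float(score),
                     int(offset) + L // 2)
                )
    return rows


def scan_pwm(seq: str, motif: MotifModel, site_id: str = "") -> pd.DataFrame:
    """All hits of ``motif`` in ``seq`` on both strands.

    Returns a DataFrame (site_id, motif_id, offset, strand, score,
    center) ordered by (offset, strand); offsets are 0-based window
    starts on the forward sequence, center = offset + L // 2. Positions
    containing N score -inf and can never reach the threshold.
    """
    return pd.DataFrame(_hit_rows(_encode(seq), motif, site_id), columns=_HIT_COLUMNS)


def scan_sites(
    sequences: Mapping[str, str], motifs: Iterable[MotifModel]
) -> pd.DataFrame:
    """Scan every site sequence with every motif; concatenated hit table."""
    rows = []
    encoded = {sid: _encode(seq) for sid, seq in sequences.items()}
    for motif in motifs:
        for site_id, codes in encoded.items():
            rows.extend(_hit_rows(codes, motif, site_id))
    return pd.DataFrame(rows, columns=_HIT_COLUMNS)


@dataclass
class EnrichmentStat:
    motif_id: str
    target_fraction: float
    background_fraction: float
    fold: float
    pvalue: float
    n_target: int
    n_background: int


def fold_enrichment(target_fraction: float, background_fraction: float) -> float:
    """Ratio of target to background with-motif fractions (inf at 0 background)."""
    if background_fraction == 0:
        return float("inf")
    return target_fraction / background_fraction


def enrichment_from_counts(
    motif_id: str, k_target: int, n_target: int, k_background: int, n_background: int
) -> EnrichmentStat:
    """Binomial enrichment of with-motif site counts, target over background.

    The p-value is the upper binomial tail of >= k_target successes in
    n_target trials at the background fraction. A zero background
    fraction is floored at 1 / (2 * n_background) for the test.
    """
    if n_target < 1 or n_background < 1:
        raise ValueError("both site sets must be non-empty")
    tf = k_target / n_target
    bf = k_background / n_background
    p0 = bf if bf > 0 else 1.0 / (2 * n_background)
    pvalue = float(stats.binom.sf(k_target - 1, n_target, p0))
    return EnrichmentStat(
        motif_id=motif_id,
        target_fraction=tf,
        background_fraction=bf,
        fold=fold_enrichment(tf, bf),
        pvalue=max(pvalue, np.finfo(float).tiny),
        n_target=n_target,
        n_background=n_background,
    )


def _sites_with_hit(sequences: Mapping[str, str], motif: MotifModel) -> int:
    return sum(1 for sid, seq in sequences.items() if len(scan_pwm(seq, motif, sid)))


def motif_enrichment(
    target_sites: Mapping[str, str],
    background_sites: Mapping[str, str],
    motif: MotifModel,
) -> EnrichmentStat:
    """Fraction-with-motif enrichment of target over background sequences."""
    if not target_sites or not background_sites:
        raise ValueError("both site sets must be non-empty")
    return enrichment_from_counts(
        motif.motif_id,
        _sites_with_hit(target_sites, motif),
        len(target_sites),
        _sites_with_hit(background_sites, motif),
        len(background_sites),
    )


def cooccurrence_fraction(
    site_sets: Mapping[str, Sequence[str]], hits: pd.DataFrame, motif_id: str
) -> pd.Series:
    """Per named set: fraction of sites carrying >= 1 hit of ``motif_id``."""
    with_hit = set(hits.loc[hits["motif_id"] == motif_id, "site_id"])
    out = {}
    for name, ids in site_sets.items():
        if len(ids) == 0:
            raise ValueError(f"site set {name!r} is empty")
        out[name] = sum(1 for s in ids if s in with_hit) / len(ids)
    return pd.Series(out, name=f"fraction_with_{motif_id}")


def motif_spacing(
    hits: pd.DataFrame, motif_a: str, motif_b: str
) -> tuple[pd.Series, float, int]:
    """Center-to-center spacing between two motifs within each site.

    Only sites with >= 1 hit of both motifs contribute; per site the
    minimum |center_a - center_b| over hit pairs is taken. Returns
    (per-site distances, mean distance, n contributing sites); the mean
    is NaN when no site carries both motifs.
    """
    ha = hits[hits["motif_id"] == motif_a]
    hb = hits[hits["motif_id"] == motif_b]
    shared = sorted(set(ha["site_id"]) & set(hb["site_id"]))
    dists = {}
    for sid in shared:
        ca = ha.loc[ha["site_id"] == sid, "center"].to_numpy()
        cb = hb.loc[hb["site_id"] == sid, "center"].to_numpy()
        dists[sid] = float(np.abs(ca[:, None] - cb[None, :]).min())
    per_site = pd.Series(dists, name=f"spacing_{motif_a}_{motif_b}", dtype=float)
    mean = float(per_site.mean()) if len(per_site) else float("nan")
    return per_site, mean, len(per_site)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts
    (Altschul-Erickson Eulerian-path shuffle)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq[:-1], seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = list(edges)
    for _ in range(10_000):
        last_exit = {
            v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != last
        }
        # the chosen last-exit edges must lead every vertex to the last one
        ok = True
        for v in last_exit:
            seen, cur = {v}, v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely for DNA alphabets
        raise RuntimeError("dinucleotide shuffle failed to find an Eulerian ordering")
    pools = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_exit:
            rest.remove(last_exit[v])
        rng.shuffle(rest)
        if v in last_exit:
            rest.append(last_exit[v])
        pools[v] = rest
    out = [first]
    cur = first
    for _ in range(len(seq) - 1):
        nxt = pools[cur].pop(0)
        out.append(nxt)
        cur = nxt
    return "".join(out)
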