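# fatebind

Resolving the cell-type-specific function of a lineage transcription
factor from epigenomic data.

A lineage transcription factor — the motivating case is NKX2-1, which
drives both of the opposing alveolar type 1 (AT1) and type 2 (AT2) fates
in the lung epithelium — is expressed in every cell type of its lineage,
so its cell-type-specific output must come from *where* it binds, not
*whether* it is present. `fatebind` implements the analysis framework for
dissecting that question from ChIP-seq-style site × sample signal,
multi-lineage pseudo-bulk accessibility, site sequences, and single-cell
expression with pseudotime:

1. **Site taxonomy.** Differential binding between two mature cell types
   (A vs B) partitions a fixed-width consensus peakset into A-specific,
   B-specific and common sites (moderated t on log₂ normalized signal,
   BH-corrected; default call: q < 0.05 and |log₂FC| ≥ 1). Common sites
   are deconvolved into *lineage* sites (accessible only in the tissue's
   own lineage: log₂ epithelial/other ≥ 1 against each other lineage)
   versus *housekeeping* sites (accessible in all four lineages), and
   sites losing binding from progenitor to both mature fates are called
   progenitor-specific. Sites > 2 kb from the nearest TSS are distal.
2. **Acquired vs retained kinetics.** Within each fate's specific sites,
   ranking by mature-over-progenitor change splits the top 20% (gained
   de novo during differentiation: *acquired*) from the bottom 20%
   (already progenitor-bound and kept in one fate: *retained*).
3. **Partner-motif statistics.** Known-PWM scanning (log-odds ≥ 80% of
   each motif's maximum score, both strands) yields per-set
   fraction-with-motif, binomial enrichment over a background set
   (fold = target/background fraction), and center-to-center spacing
   between partner motifs within a site.
4. **Module scores along pseudotime.** Each site set maps to its
   nearest-gene set; the per-cell module score is the set's mean
   expression minus that of expression-bin-matched control genes, and
   its trend along (supplied) pseudotime is summarized by Spearman ρ.
5. **Binding PCA** of samples in log₂ site space.

Everything runs on a seeded synthetic-data generator
(`fatebind.synth`) that plants a full ground truth — the six-way site
taxonomy, negative-binomial count noise, motif placements with
controlled spacing, and fate-coupled (or deliberately decoupled)
expression programs — so the whole pipeline is testable without any
external download.

## Worked example

```python
from fatebind.motifs import enrichment_from_counts

stat = enrichment_from_counts("ctcf", k_target=600, n_target=1000,
                              k_background=17, n_background=1000)
print(f"{stat.target_fraction:.0%} over {stat.background_fraction:.1%} "
      f"-> {stat.fold:.1f}-fold, p = {stat.pvalue:.2g}")
```

prints

```
60% over 1.7% -> 35.3-fold, p = 2.2e-308
```

— a site set in which 60% of sites carry a motif against a 1.7%
background is a ≈35-fold (printed as "36-fold" when computed from
unrounded fractions) enrichment, with an upper-tail binomial p-value
that underflows double precision.

Running the numbered drivers reproduces the synthetic study end to end
(`python analysis/01_simulate.py` … `06_binding_pca.py`; outputs land in
`results/`). On the default conditions (3300 sites, 3 replicates, NB
dispersion 0.1, effect size 3 log₂ units, seed 1) the taxonomy stage
prints a specificity-label agreement of 0.991 with the planted truth and
perfect lineage/housekeeping deconvolution; the motif stage recovers the
planted TEAD co-occurrence gradient 73.1%/34.9%/23.1% and a TEAD–NKX
mean spacing of 52.3 bp; the module-score stage shows the
binding–expression dissociation (acquired and retained gene sets both at
Spearman ρ ≈ 0.98 along the target branch, |ρ| < 0.08 on the alternative
branch, despite an 8-fold progenitor-binding difference).

There is also a CLI (`fatebind simulate | run | diff | classify |
kinetics | motif | modulescore | crossref | pca`) that drives the same
library over a plain-text workspace directory.

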