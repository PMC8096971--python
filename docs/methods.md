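# Methods

This note documents the models, statistics and design choices behind
`fatebind`, in the order the pipeline runs them.

## Coordinates and peak geometry

All intervals are 0-based half-open (BED convention); a narrowPeak
summit is an offset from the interval start. The *center* of a peak is
`start + summit` when a summit is known and the integer midpoint
otherwise — summit preference matches peak-caller practice, and both
centerings are supported because consensus intervals from merged peak
calls may lack summits. Consensus peaksets merge overlapping calls
(single linkage, ≥ 1 bp) across samples, keep clusters supported by at
least `min_support` input sets, and recenter each cluster to a fixed
width (default 500 bp) on its maximum-score member's center. Windows
clipped at a chromosome's left edge keep their right edge and are
flagged. Nearest-TSS distances are strand-agnostic and signed
(center − TSS); ties go to the lexicographically smaller gene id so
annotation is deterministic; the promoter/distal boundary is
|distance| > 2000 bp.

## Normalization

Depth mode is counts-per-million on post-filtering library depth.
Foreground mode divides each sample by FRiP × depth — the estimated
number of in-peak reads, which matches samples on foreground rather
than total sequencing — then scales to CPM and multiplies by the
geometric mean of the FRiPs. The rescaling constant is deliberately a
function of FRiPs alone (dimensionless), so the map is exactly
invariant under jointly multiplying raw values and depths by any
constant; a constant involving depth would break that invariance while
changing nothing about between-sample comparability. Matrices carry a
normalization tag and refuse re-normalization. FRiP is computed per
assay/antibody peak universe; the API takes the universe explicitly.

## Differential binding

The test statistic per site is a moderated two-sample t on
log₂(normalized + 1): the pooled per-site variance is shrunk 50% toward
the global mean variance, the usual stabilization when each group has
only 2–3 replicates. Pseudocount 1 keeps zeros finite and is
conventional.

P-values do **not** come from a t reference. With three replicates of
log negative-binomial counts the statistic's null distribution is
visibly non-t: on null simulations (2000 sites, NB dispersion 0.1,
3 vs 3, 20 seeds) a t reference with residual df was anticonservative
in every seed and one with doubled df was rejected for non-uniformity
in half of them. Instead the same moderated statistic is recomputed
under every relabeling of the samples into two groups of the original
sizes; the |t| values pooled across sites and relabelings form the null
(a classic permutation-null design for moderated statistics), and
p = (1 + #{null ≥ |t|}) / (1 + N). Relabelings are fully enumerated
when there are at most 400 (3 vs 3 gives 18 informative ones) and
deterministically subsampled beyond that, so results are reproducible
without a seed. Under the same null simulations this yields uniform
p-values (KS α = 0.01 non-rejected in 19/20 seeds), a q < 0.05 fraction
of ~0, and full power on an 8-fold planted shift. Benjamini–Hochberg
q-values are computed over all sites. The granularity floor of a
permutation p (≈ 1/(18·n_sites) here) is far below any decision
threshold at the matrix sizes this package targets.

Specificity calls use q < 0.05 and |log₂FC| ≥ 1 by default (boundary
inclusive); both thresholds are configurable because source analyses of
this kind rarely print them. Top-fraction selection for
most-changed-site sets uses `ceil(fraction · n)` with ties broken by
p-value then site id.

## Site taxonomy

*Progenitor-specific* calls: among sites common to the two mature
fates, a site is progenitor-specific when the progenitor-vs-mature test
is significant with progenitor-ward fold change **in both fates**,
tested per fate. Testing each fate separately keeps within-group
variance clean — a pooled "all mature samples" group mixes A- and
B-specific signal and loses most power.

*Lineage vs housekeeping*: a common site is a lineage site iff
log₂((epithelial + 1)/(other + 1)) ≥ 1 against **each** of the three
non-epithelial lineages (the strictest reading of "higher accessibility
in the epithelial lineage"; deterministic and conservative).
Housekeeping is the complement, so the partition is exhaustive. The
airway-low subset applies the same ratio rule to an airway
accessibility column.

*Kinetics*: each fate's specific sites are ranked by
log₂(mature/progenitor) on normalized signal; the top `fraction`
(default 0.20) are acquired, the bottom `fraction` retained, the middle
intermediate; `fraction` = 0.5 gives the exhaustive bipartition. The
alternative phrasing — least/most *present* in progenitors — produces
rankings whose half-splits agree with the fold-change split ≥ 95% on
synthetic data, although global Spearman agreement is only ≈ 0.83
because within-class ordering is noise in both rankings; the package
exposes `ranking_agreement` as a diagnostic.

*Opposite-fate gains* label mutant accessibility-gain sites by ≥ 1 bp
overlap with the opposite fate's binding peakset first, then the own
fate's, else unbound, and report fractions rather than enforcing any
threshold (the observed fraction is a result, not a parameter).

## Motif analysis

Motifs are position-probability matrices in a minimal tabular format;
five fixture PPMs (NKX, TEAD, CEBP, CTCF, FOXA) ship with the package.
These fixtures are **synthetic** motif models — sharp 10–14-column
matrices (dominant base 0.85) chosen so that consensus instances score
at the maximum and the default threshold tolerates no mismatch — not
database-derived profiles; de novo discovery is out of scope, and every
statistic of interest (fraction-with-motif, fold, spacing) only needs a
deterministic scanner. Scanning scores log₂(p/background) summed over
columns at every offset on both strands; N scores −∞. The default
threshold is 80% of each motif's maximum score — relative, so it adapts
across motif lengths. Enrichment is an upper-tail binomial on the
number of target sites with ≥ 1 hit at the background
fraction-with-hit; a zero background fraction is floored at
1/(2·background-set size). Spacing is the per-site minimum
center-to-center distance (center = offset + L//2) over hit pairs,
averaged over sites carrying both motifs; center-to-center and
per-site-minimum are declared conventions, since this distance is
rarely defined precisely in published analyses. Dinucleotide-preserving
background shuffles use the Altschul–Erickson Eulerian-path method.

## Module scores and pseudotime trends

The module score of a gene set in a cell is mean(set expression) −
mean(pooled control expression), with controls drawn per set gene
(n_ctrl = 100, with replacement, seeded) from the gene's
average-expression bin (n_bins = 24, equal-count by rank) — the
bin-matched averaging used by the major single-cell toolkits, with
parameters made explicit; agreement with scanpy's implementation is
checked in the test suite. Scores are deterministic per seed and
invariant to gene order and in-set duplicates. Branch endpoints are
aligned by multiplying one branch's pseudotime by max(pt_A)/max(pt_B)
(a positive scaling, so within-branch order is preserved). Trends use
equal-width pseudotime bins (default 20) and report per-bin mean/SD/n
plus the cell-level Spearman ρ.

## The synthetic-data generator

The generator is first-class, tested code; its defaults *are* the study
conditions. Per top-level seed, every stage draws from a named
substream, so each emitted object is byte-stable.

**Sites.** 3300 sites by default
(600/600/600/600 A/B × acquired/retained, 300 lineage, 300
housekeeping, 300 progenitor-specific), 500 bp wide, on a 2 × 2 Mb toy
genome. Sites occupy disjoint 1200-bp slots; each slot carries the
site's designated nearest gene with its TSS 50–250 bp past the site
end, so the planted site→gene linkage is exactly recoverable by
nearest-TSS annotation (own-gene distance ≤ 500 bp, nearest neighbor
gene > 700 bp).

**Binding counts.** Negative binomial with constant dispersion
(default 0.1; var = μ + φμ²), per-site lognormal baselines (log₂ mean
5.5, sd 0.5, i.e. ≈ 45 reads), a per-sample efficiency wobble (log₂ sd
0.15), and mean μ = baseline · 2^(effect · occupancy), effect 3 log₂
units. Occupancy encodes the planted kinetics over three timepoints
(progenitor → intermediate → mature, 3 replicates each; A and B
sampled separately after the progenitor stage): acquired sites ramp
0 → ½ → 1 in the target fate only; retained start at 1 and ramp down
in the alternative fate; lineage/housekeeping are constitutive;
progenitor-specific decay in both. Sample FRiPs are drawn uniform
(0.3, 0.6) and depths derived so FRiP × depth equals the in-peak count
sum.

**Accessibility.** One pseudo-bulk value per site per lineage
(NB, dispersion 0.05): epithelial is 2^effect above baseline
everywhere; the other three lineages are elevated only at housekeeping
sites; a planted 30% of lineage sites is additionally low in the
airway column.

**Motifs.** Planted as consensus instances (threshold-robust; a
`degenerate` toggle samples instances from the PPM for harder tests) at
exact per-class fractions: TEAD in 73% of A-specific, 35% of
common/progenitor, 23% of B-specific sites; NKX in 55% everywhere;
CTCF in 30% of housekeeping sites. When TEAD and NKX co-occupy a site
their center spacing is Normal(52, 5) clipped to [12, 80] bp (the clip
keeps instances inside the site and non-overlapping; it moves the mean
by < 10⁻⁶ bp).

**Expression.** 300 cells per branch on a bifurcating trajectory
(pseudotime uniform on [0, 10]), genes = one per site plus 4000
unlinked background genes, NB dispersion 0.3, X = log1p(counts). Genes
linked to A-specific sites — acquired and retained alike — follow a
low→high program (amplitude 2 log₂ units) along branch A only;
symmetric for B; lineage genes are constitutively elevated; everything
else is flat. Two deliberate design points make the control-matched
score clean: the two fate programs occupy distinct absolute-expression
ranges (baseline log₂ mean ± 0.8, sd 0.3), so expression-matched
control bins for one program contain almost none of the other
program's genes; and no per-cell library rescaling is applied, because
the generator plants no per-cell depth variation and a CPM transform
would only inject compositional artifacts into every flat gene. This
construction embodies the central dissociation: retained-site genes
are low in progenitor cells although their sites are
progenitor-bound.

**Perturbations.** `partner_loss` adds a control-vs-mutant binding
contrast (whole-tissue control occupancy ½ at specific sites; mutant 0
at A-specific, 1 at B-specific) and replaces the bifurcation with one
merged trajectory along which A-linked genes fall and B-linked genes
rise. `tf_loss` emits 1500 accessibility-gain sites — 12% overlapping
B-specific (opposite-fate) binding sites, 5% A-specific, the rest on
unbound territory — and an expression matrix in which the
opposite-fate gain genes stay flat: accessibility without expression.

**What the generator does not emulate:** read-level artifacts
(GC/fragment-length bias, duplicates), peak-calling uncertainty,
batch effects, cell-level dropout structure beyond NB noise, doublets,
ambient RNA, or real trajectory inference (pseudotime is planted).
Passing tests therefore demonstrate the correctness and calibration of
the analysis logic under the declared noise model, not robustness to
every artifact of real data.

## Problem sizes

Unit tests run on a scaled-down workspace (330 sites, 160 cells); the
acceptance checks use the full default conditions (3300 sites, 600
cells, 7300 genes), 20 null-calibration simulations of 2000 sites each,
and oracle comparisons at up to 1000 elements — sizes chosen so the
complete suite executes in a few minutes on one CPU while keeping every
recovery margin comfortably away from its threshold.

## Known limitations

- The permutation null needs ≥ 2 replicates per group and gains
  resolution from site pooling; single-replicate designs are rejected.
- Lineage deconvolution consumes pseudo-bulk accessibility values; no
  within-lineage variance is modeled, so no significance is attached to
  the log-ratio rule (matching its qualitative origin).
- Motif spacing conventions (center-to-center, per-site minimum) are
  declared, not validated against any external tool's convention.
- Module-score magnitudes depend on the binning/control parameters;
  only shapes and signs of trends are meaningful across datasets.
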