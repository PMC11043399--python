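# Methods

## The zero-expression LOY call

A cell is classified LOY iff its **raw** count is exactly zero for every
retained gene of the MSY panel (*RPS4Y1, ZFY, USP9Y, DDX3Y, KDM5D,
EIF1AY*), and non-LOY otherwise. The rule runs on raw counts because raw
zeros are invariant to per-cell normalization, so calling can precede —
and is never altered by — annotation or scoring. Panel genes missing
from a matrix are dropped with a warning (public matrices differ in
feature annotation) and the call uses the retained subset; a panel with
no retained gene is an error.

The rule's false-positive rate is governed by technical dropout: a
Y-bearing cell is miscalled LOY iff all six genes drop out
independently, i.e. with probability ∏₆ q_g for per-gene technical-zero
probabilities q_g. Donor sex is inferred from the same panel: a donor
with any MSY expression in any cell is male, otherwise female. Cells of
female donors are excluded from LOY calling (call = `unassigned`),
mirroring the removal of female patients from an LOY study.

Two cohort filters are provided as profiles: `zhang-like` removes
donor × tissue × cell-type groups with fewer than 15 called cells (the
small multi-tissue-cohort regime) and `atlas-like` removes groups below
50 cells plus cancer types with fewer than 4 donors (the pan-cancer
atlas regime). Both removals are strict ("lower than"), so a group of
exactly 15 (or 50) cells survives.

Group %LOY is reported two ways — pooled over cells
(100·Σn_loy/Σn_cells) and as the unweighted mean of per-donor
percentages — because the two statistics genuinely differ (e.g. 101 LOY
among 498 pooled Tregs is 20.3% pooled, while the mean over four donors
can be 22%); which one a figure shows should always be explicit.

## Treg/Th annotation

CD4⁺ cells (Tregs and helper T cells; CTLs are accepted from upstream
labels and never relabeled here) are normalized to log CP10K
(counts scaled to 10,000 per cell, then log(1+x)), embedded by PCA on
the 100 most variable genes after per-gene standardization, and
clustered (k-means, default k = 2; graph-based Leiden and a
pass-through mode for pre-computed labels are alternatives). A cluster
is labeled **Treg** iff its mean normalized expression of every retained
marker (*CTLA4*, *IL23R*) strictly exceeds the across-cluster median of
that marker; all other clusters are Th. The strict inequality makes the
degenerate single-cluster case label Th, the least-assumption default.
Cluster-then-label was chosen over per-cell thresholding to match the
recluster-then-categorize workflow; a per-cell rule can be emulated by
passing per-cell labels through the `none` clustering mode. The marker
rule is a stated stand-in: published marker tables for this step are not
fully specified, and *IL23R* in particular is often low in Tregs, so the
markers are configurable.

## Module scores

The score of gene set M in cell c is
mean_{g∈M} x_cg − mean_{g∈C} x_cg, where the control pool C is drawn to
match M's expression level: all genes are ranked by dataset-wide mean
expression and split into `n_bins` (default 24) equal-frequency bins;
each module gene contributes `n_ctrl` (default 100) genes drawn
uniformly **with replacement** from its bin. Controls exclude module
genes by default so that an additive shift δ on a module gene moves the
score by exactly δ; set `exclude_module_from_ctrl=False` for strict
emulation of implementations that do not exclude them. The defaults
24/100 follow the conventional single-cell scoring routine.

Determinism contract (what a reimplementation must reproduce): genes are
ordered by (mean, symbol) and split with `numpy.array_split`; module
genes are processed in sorted-symbol order; bin candidates are
symbol-sorted; draws come from
`numpy.random.default_rng(seed).choice(len(candidates), n_ctrl)`
sequentially. The test suite holds the implementation to this contract
against an independent loop-based scorer, exactly.

LOY vs non-LOY comparisons of per-cell scores use the two-sided rank-sum
test with the cell as the statistical unit; the output record carries an
explicit pseudoreplication caveat, since cells within a donor are not
independent. Correlation ranking against a target gene (e.g. *TIGIT* in
Tregs) uses the product-moment coefficient on normalized expression,
excluding zero-variance genes, with symbol-order tie-breaks; the choice
of Pearson here is this package's, as the upstream method is not pinned
down.

## ddPCR quantification

Each well partitions ~20,000 droplets and reads two channels: AMELX
(X chromosome, reference) and AMELY. With template copies Poisson
distributed across droplets, the positive fraction per channel inverts
to mean copies per droplet λ = −ln(1 − n⁺/N); a saturated channel
(n⁺ = N) is an error. Then

    %LOY = 100 · (1 − λ_Y / λ_X),

which is independent of the droplet volume (default 0.00085 µL, the
QX200 nominal — used only for the copies/µL concentrations). The
detection threshold is ≥ 5% (a value of exactly 5 counts as detectable,
consistent with how the bundled cohort table's detectable entries range
6–45 and non-detectable 0–4). Sampling noise can make the point estimate
negative when true LOY is near zero; such estimates are reported raw and
flagged rather than zeroed, while the bundled patient table follows the
assay's reporting convention of printing sub-threshold values as 0.

## Synthetic data generator

The generator emulates exactly the structure the analysis assumes, and
its defaults are the study conditions: four male donors; tumor, margin
and blood tissues; a Treg/Th/CTL/other mixture with Tregs at 25% of the
CD4 compartment (within the 10–50% range reported for tumor-infiltrating
Tregs); true LOY fractions per tissue and type (tumor: Treg 0.22,
Th 0.11, CTL 0.14; blood: Treg 0.17, Th/CTL 0.04; margin: ~0.04–0.05);
500 cells per donor and tissue; 200 filler genes.

Counts are negative binomial with dispersion θ = 2 (var = µ + µ²/θ, a
typical droplet-scRNA-seq overdispersion). MSY genes are structurally
zero in female-donor cells and truth-LOY cells. In Y-bearing cells each
MSY gene is a *zero-truncated* negative binomial (mean 2.0) mixed with
an independent technical-zero probability (default 0.1): a count is 0
with exactly probability q_g and positive otherwise. This
parameterization was chosen so that dropout *is* the per-gene zero
probability — the analytic false-positive rate of the zero-expression
rule is exactly ∏ q_g, and at q = 0 every Y-bearing cell is guaranteed
MSY-positive, making truth recovery exact rather than approximate.
Marker genes are elevated in their defining types (CTLA4/IL23R in Tregs,
CD4 in CD4⁺ types, CD8A in CTLs, additive mean +3), Tregs additionally
elevate the whole immunosuppressive panel (+1, reflecting the broad
effector-Treg program of CCR8, CCR4, ICOS, ENTPD1, IKZF2, …), and
truth-LOY Tregs receive configurable additive shifts on *PDCD1*,
*TIGIT* and *IKZF2* (+0.5 each) — the effect the scoring stage should
detect. Filler genes get log-normal mean rates (log-mean −1, σ = 1) so
the control bins of the module score are populated across the expression
range. Donor-level heterogeneity in LOY fractions is exposed as a
per-donor override knob without a claimed default, as no reliable
population value is available.

Randomness is one `SeedSequence` split into a gene-level stream plus one
stream per donor, so a fixed seed is bit-reproducible and adding donors
never perturbs existing donors' draws. Female donors cannot be assigned
nonzero LOY (a config error), and truth labels ride along in the cell
table.

What the generator does **not** model: doublets, ambient RNA, batch
effects, UMI saturation, donor-correlated library sizes, or realistic
gene–gene covariance beyond the planted Treg/LOY programs. Passing tests
therefore demonstrate correctness of the pipeline's logic and its
statistical calibration under the stated model, not robustness to every
artefact of real single-cell data.

The droplet simulator draws per-droplet X copies ~ Poisson(λ_g) and Y
copies ~ Poisson(λ_g(1 − f)) with f the true LOY fraction and
λ_g = 0.1 genomes/droplet by default (50 ng digested DNA in ~20,000
droplets is in this regime); a droplet is channel-positive iff it holds
at least one copy. This is the exact generative model the Poisson
correction inverts, so it serves as the estimator's Monte-Carlo oracle.

## Statistics

Rank-sum tests use the exact null distribution when min(n_a, n_b) ≤ 25
and the pooled sample is tie-free, matching conventional defaults, and
otherwise the normal approximation with tie and continuity corrections.
Bonferroni families are all pairwise comparisons within one grouping
call — never pooled across panels. Pearson's r is used for per-patient
%LOY correlations (the bundled cohort reproduces r = 0.71, p = 0.02 for
UM vs tumor in the primary-cancer arm under Pearson, which is the
deciding evidence for that choice); p-values come from the t transform
with n − 2 degrees of freedom. Both per-cell and per-patient comparison
modes are supported; which one is in use is visible in the group sizes
logged with every comparison table.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run on deliberately modest
sizes — cohorts of 2–4 donors × 3 tissues × 300–1000 cells, a
20,000-cell single-tissue cohort for false-positive calibration, 200
simulated wells of 20,000 droplets — which keep the whole suite in the
minutes range on one CPU while leaving Monte-Carlo standard errors well
inside the asserted tolerances. Ties in expression-bin boundaries and in
correlation rankings break deterministically by gene symbol; cluster
labels are stable under any monotone rescaling of marker means; %LOY
point estimates are clamped to [−100, 100] with the raw value retained
alongside.

## Known limitations

- The LOY caller is intentionally the plain zero-expression rule; a
  dropout-aware probabilistic caller is a documented extension point,
  not implemented.
- Treg/Th labeling quality depends on how well two markers separate the
  clusters; with default synthetic conditions per-cell accuracy is
  ≈ 0.95–0.96, not 1.0, and real data will differ.
- The per-cell score comparisons inherit pseudoreplication; donor-level
  aggregation is left to the caller (both pooled and per-donor summaries
  are emitted).
- No HDF5/loom input, no accession downloading; external datasets enter
  through the market-matrix triplet plus cell-table adapter, which
  assumes raw counts are available.
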