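# Methods

This note documents the statistical model, the numerical choices, and the
synthetic study design behind `mastqtl`, in the spirit of the methods
documentation of packages like statsmodels or msprime: what is computed,
under which assumptions, and what the tests do and do not demonstrate.

## Record preparation

A QTL record carries study id, population type/size, one of seven stress
labels (DS, HS, D+H, SS, WS, PHS, AS — "D+H" is a combined drought+heat
trial and expands to DS *and* HS only when stress classes are tallied), the
wheat chromosome (21 valid labels), flanking markers, and optionally peak,
95% CI, LOD and PVE. Invalid rows are never silently dropped: they go to a
rejects report with a reason, so the attrition from collected to analysable
records is fully accounted.

Imputation follows the conventions of the meta-QTL literature: missing
LOD → 3.0, missing PVE → 10 (percent), missing peak → midpoint of the
flanking markers on the study's own map. A missing 95% CI is estimated as

CI = k / (N · R²)

with R² the PVE as a proportion and k a population-specific constant from
the Darvasi–Soller lineage of approximations: 530 for F₂ and backcross, 287
for doubled haploids, 163 for RILs; populations typed "other" use the DH
constant. The constants are configuration (`CIEstimationConfig`), not
hard-coded, because different meta-analyses use slightly different variants
of these equations. Estimated CIs are centred on the peak and floored at
0 cM on the left; every imputation and estimation is flagged on the record.

## Consensus map

Published consensus builders solve an LP/weighted-least-squares problem. We
use a deterministic anchor-based surrogate whose behaviour is fully
specified and order-preserving, which is what the downstream biology
depends on:

1. per chromosome, the densest map is the *frame* and fixes marker order;
2. every other map is aligned to the frame piecewise-linearly through their
   shared markers (markers whose order conflicts with the frame are dropped
   from the alignment and flagged; maps sharing < 2 markers contribute
   nothing and their markers are reported *unanchored*);
3. each shared (anchor) marker's consensus coordinate is the weighted mean
   of its translation-aligned position across the maps containing it
   (weights default to per-chromosome marker counts). Positions, not
   inter-anchor gaps, are averaged: gap averaging lets per-map noise
   accumulate as a random walk along the chromosome, whereas position
   averaging keeps the error of every anchor at the per-map noise level.
   Frame order is restored afterwards by re-sorting the averaged values;
4. non-anchor markers are placed by fractional interpolation between their
   flanking anchors *in their own source map*; chromosomes are shifted to
   start at 0.

With equal weights the construction is symmetric in the input maps; with
a single input map it is the identity (up to the min-shift). QTL-flanking
markers enter the consensus simply by merging the per-study maps together
with the base map(s).

## Projection

A QTL is projected through a *context*: a pair of markers common to its
source map and the consensus that flank its peak. All flanking common pairs
are enumerated; pairs whose interval-length ratio (longer/shorter across the
two maps) exceeds `max_ratio` (default 5) are infeasible; among feasible
pairs the one minimizing |log(consensus length / source length)| wins, ties
to the tighter pair — this reproduces the "widen outward when the nearest
pair is inconsistent" behaviour of dynamic projection tools. Peak and CI map
through the linear transform of the context; CI endpoints falling outside
the context interval use the piecewise-linear map through all common
markers (extrapolating with the edge segments). A homogeneity check is
exposed as a heuristic p-value, 2(1 − Φ(|log s₁/s₂|)) on two interval scale
factors — exact published formulas for this test are not available, so the
ratio bound is the primary gate and the p-value a documented secondary one.
Projected QTLs with CI wider than `max_ci_cm` (default 50 cM) are rejected
as "large_CI"; every rejection reason is counted per chromosome, and
total = incomplete + projected + rejected always holds.

## Meta-analysis

Projected peaks x₁…x_n on a chromosome follow a K-component normal mixture
with known per-observation variances σᵢ² = (CI95ᵢ/3.92)², σ floored at
0.05 cM so degenerate zero-width CIs cannot produce infinite weights. EM
maximizes the likelihood for each K (quantile-spread initial means, jittered
seeded restarts — default 5, convergence at ΔlogL < 1e−8 or 2000
iterations); the M-step mean is the posterior-weighted inverse-variance
mean. Free parameters number d = 2K − 1 (variances are data, not
parameters), which matters because all five criteria penalize d:

- AIC = −2logL + 2d, AIC3 with penalty 3d, AICc with the small-sample
  correction (undefined and excluded from voting when n ≤ d + 1),
- BIC = −2logL + d·log n,
- AWE = −2logL_c + 2d(3/2 + log n) on the classification (hard-assignment)
  likelihood, per its literature definition.

K\* is the K winning at least 3 of the 5 criteria; failing that, the
BIC-minimal K (tie → smaller K), and the rule actually used is logged.

QTLs join their maximum-posterior component when that posterior is ≥ 0.5
(otherwise reported *unassigned*, not forced). One-member components are
*singletons*; components whose members share one study id are single-study
hotspots — both are excluded from true MQTLs but fully reported, so the
hotspot → MQTL attrition is auditable. MQTL position and CI come from
inverse-variance pooling (position ± 1.96/√Σσᵢ⁻²), which can only narrow,
never widen, relative to any member — the source of the CI fold-reduction
statistic. LOD and PVE are arithmetic means of the members
(posterior-weighted PVE available via `pve_weighting="posterior"`).
Names are MQTL<chromosome>.<rank> ascending in position.

## Physical anchoring and downstream stages

Genetic CI endpoints are anchored to the nearest consensus markers at or
outside each endpoint that have physical positions on the same chromosome;
a side with no outside marker falls back to the nearest resolvable marker
and is flagged `extended_*`; MQTLs with no resolvable markers are
*unanchored*. Coordinates are 1-based inclusive internally; BED export is
0-based half-open. The physical peak uses the printed formula
start + (Δbp/ΔcM)·CI95/2 with two documented guards the formula itself
lacks: clamping into [start, end] (a wide CI95 can overshoot) and the bp
midpoint when the genetic span is zero (zero-width CIs do occur in
published tables).

MTA validation uses closed-interval containment of the marker bp, with an
optional ± LD window (default 0); known-gene and gene-model overlap use
any-overlap semantics — boundary rules the literature leaves unstated, so
they are fixed and tested here. MAST MQTLs are those covering ≥ 5 stress
classes with ≥ 9 member QTLs (both configurable). DEG calling is the pure
fold-change rule: |log₂FC| ≥ 1 between condition and control means on log₂
TPM (raw TPM is log-transformed with pseudocount 0.01). The printed
criterion "FC ≥ 2 or FC ≤ −2" is not satisfiable by a fold change on a
linear scale; the only consistent reading on log₂ data is |log₂FC| ≥ 1,
i.e. a two-fold change either way, and that is what is implemented. Calls
are made per condition/timepoint, so a gene can be up at one timepoint and
down at another ("mixed"). Candidates are ranked by the number of datasets
with ≥ 1 call; ≥ 3 datasets ⇒ *promising*.

Promoters are the 1500 bp upstream of the ATG (reverse-complemented for −
strand genes), truncated with a flag at chromosome ends. CRE scanning is
exact IUPAC consensus matching on the sense strand only, all overlapping
occurrences reported, scored by matched length, against a bundled table of
literature consensus elements (ABRE, MBS, ARE, LTR, STRE, TC-rich repeats,
As-1, WUN-motif, WRE3, DRE, hormone- and growth-related elements, core
elements, and two uncharacterized ones). This is a deterministic offline
stand-in for matrix-based promoter scanners: adequate for categorical CRE
composition analyses, *not* a PWM scorer, and counts from matrix-based
tools will differ.

Ortho-MQTL detection joins mined wheat genes to a user-supplied orthologue
table and declares a (wheat MQTL, foreign MQTL) pair when ≥ `min_genes`
(default 1 — published analyses report conserved regions supported by
anywhere from one to hundreds of genes) orthologues overlap the foreign
interval.

## Synthetic study design

The default scenario emulates, at desk scale, the structure of a curated
literature collection: 3 chromosomes (150 cM, 2 Mb each — the cM scale is
realistic, the bp scale compressed ~100× so a full run takes seconds), 6
true loci (2/3/1 per chromosome, ≥ 35 cM apart), 8 studies (RIL/DH/F₂/BC,
N = 180–450, 25 QTLs each, 200 total). Study maps share ~70% of the 61
base-map markers as anchors plus private markers, with N(0, 0.5²) cM jitter
followed by order repair (re-sort, original order as tie-break). Each QTL
draws PVE ∈ (8, 25)%, gets the population's Darvasi–Soller CI, and scatters
its peak around its true locus with the CI-implied σ — exactly the
meta-analysis model, so parameter recovery measures the estimator, not a
model mismatch. Configurable fractions of records lose LOD (0.2), PVE
(0.2), CI (0.5) or peak (0.05) to exercise imputation.

Downstream truth: MTAs are planted within ±10 kb of each true locus (3 per
locus, background rate 0); a tandem cluster of two 6-kb candidate genes is
inserted *spanning* each true position (so any physical window that
contains the locus is guaranteed to mine them — placing planted genes at
tiling distance from the locus would make end-to-end recovery a coin flip
at the ~kb scale of the position error), and 11 of the 12 cluster genes
carry planted log₂FC = 2.5 effects in exactly 3 of the 4 expression
datasets, with 6 decoy genes perturbed in a single dataset; promoter motifs
(ABRE, MBS, ARE) are written into the genome upstream of each planted gene;
orthologues of the cluster genes at the first locus of each of the first
two chromosomes are placed inside one rice and one maize MQTL interval,
plus one orthologue planted outside every interval as a negative control.
Everything is deterministic under the scenario seed.

Because physical anchoring can only resolve an interval to one base-marker
spacing (2.5 cM ≈ 33 kb here), synthetic pipeline runs validate MTAs with a
50 kb LD window — the scale-consistent counterpart of the library's
window option, whose default remains 0 (exact containment).

What passing these tests shows: the estimator recovers the generating model
(projection transforms, K selection, position pooling, overlap and
filtering rules) under realistic noise. What it does not show: robustness
to real-data pathologies absent from the generator — non-normal peak
scatter, systematically misordered maps, reference-assembly disagreements,
LD structure in GWAS panels, or expression dispersion (the FC rule does no
statistical testing by design).

## Numerical and design choices

- σ floor 0.05 cM; EM tolerance 1e−8; 2000 iteration cap; 5 restarts.
- K_max = min(n, 10) per chromosome.
- The published density figure of a 100k-marker consensus map is internally
  inconsistent (global markers/cM vs mean of per-chromosome densities), so
  the summaries emit both definitions side by side.
- Percentages and densities are reported at 2 decimals, computed by
  round-half-even; a published table that prints 23.27 for 722/3102 is a
  truncation, ours prints 23.28.
- MQTL PVE is the plain member mean by default; posterior-weighted
  averaging is available because published tools are not explicit about
  their weighting and reported MQTL PVE ranges sometimes exceed what plain
  averaging yields.
- Reported runtimes: full test suite ≈ 1.5 min, acceptance script ≈ 1 min
  on one CPU at the default problem sizes (100 mixture-recovery replicates,
  one end-to-end default-scenario run).
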