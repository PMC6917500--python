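# Methods

## Competitive occupancy model (`occupancy`)

The model treats the enzyme as partitioning at equilibrium between the apo
state, the cofactor-bound state and one state per inhibitor species.  Its
assumptions, all inherited from the underlying biochemistry:

- **Free ≈ total concentration.**  Ligands are assumed to be in large
  excess over the enzyme, so the supplied concentrations are used as free
  concentrations with no depletion correction.  Tight-binding corrections
  are out of scope.
- **Km,SAM ≈ Kd,SAM.**  A single constant (`kd_sam`) serves both in the
  IC50 relation (where the Michaelis constant appears) and in the
  occupancy fractions (where the dissociation constant appears).
- **Units.**  All concentrations are µM internally; nM inputs must be
  converted at the boundary (the equations are consistent only in one
  unit).

`fit_sam_competition_line` is an unweighted OLS fit of IC50 on [SAM]; no
weighting scheme is assumed for the titration.  A non-positive intercept
or slope is flagged as non-physical rather than rejected, because noisy
low-affinity titrations can legitimately produce them and the caller
should see the numbers.

## LC-MS/MS quantification (`lcms`)

Calibration is a direct line of concentration ratio on peak-area ratio
(Y = pX + q), fitted with a free intercept — calibration blanks are not
forced through zero.  Back-computed ratios outside the calibrated range
are flagged (`in_range=False`) but returned; extrapolation policy is the
caller's decision.  The three-internal-standard weighted mean generalizes
to any k ≥ 1 standards with weights equal to the internal-standard peak
areas, which makes it invariant to uniform detector-gain rescaling.  The
intracellular conversion uses a 40 µL extract, a hemocytometer cell count
and a mean single-cell volume of 1.3·10⁻⁶ µL by default.

## Curve fitting (`curvefit`)

- `fit_ic50` is a four-parameter logistic in log10 dose with asymptotes
  free by default (`fix_floor=0` / `fix_ceiling=100` available); IC50 is
  the back-transformed inflection and its SE comes from the delta method.
- `fit_saturation_ec50` fits Inhibition% = Max%·[I]/([I]+EC50) by
  unweighted nonlinear least squares.
- Both fits expose residual degrees of freedom (`dof`) so confidence
  intervals can use the t quantile; with ~8-dose designs the asymptotic
  normal interval visibly undercovers.
- `fit_melting_curve` is a four-parameter Boltzmann sigmoid; the reported
  Tm is the fitted midpoint (50% relative signal).  Rising (dye
  fluorescence) and falling (soluble-fraction) melts are both handled via
  the sign of the slope; a midpoint outside the scanned temperature range
  warns and flags the fit.
- Percent inhibition from scintillation counts is returned unclipped so
  that noise outside [0, 100] remains visible.

## scRNA-seq preprocessing (`preprocess`)

Container: `AnnData`, raw counts in `layers["counts"]`, treatment origin
and QC metrics in `obs`.  Defaults follow the droplet-workflow standards:
cells kept with 1000–5000 detected genes (inclusive) and <20% (strict)
mitochondrial fraction; mito/ribo genes identified by configurable name
prefixes (`MT-`, `RPS`/`RPL`); depth normalization to 10,000 counts and
natural-log transform; variable genes by binned-dispersion z-score
(20 equal-width bins of log1p mean, z > 1, mean bounds 0.0125–8); per-gene
OLS regression on total UMI, mito and ribo fractions, then z-scoring
clipped at ±10; PCA (20 components, deterministic sign convention: the
largest-magnitude loading of each component is positive).

Clustering builds a kNN graph (k = 30), reweights edges by the Jaccard
overlap of neighbor sets (pruned below 1/15), and partitions by seeded
Leiden modularity with a resolution parameter.  The backend is pluggable
by design — downstream scoring consumes labels only, and no equivalence
to any published clustering implementation is claimed.  The 2-D layout is
seeded t-SNE (perplexity clamped to (n−1)/3 for small inputs).

**Cell-cycle scoring.**  Each marker set is scored per cell as the mean
marker expression minus the mean of bin-matched control genes: all genes
are ranked by average expression into 25 quantile bins, and each marker
draws 100 controls with replacement from its own bin (seeded).  Stage
rule: both scores ≤ 0 → G0/G1; otherwise the larger score wins, with S
taking ties (s = g2m > 0) and single-positive scores winning directly.
Default S (43-gene) and G2M (54-gene) human marker panels ship with the
package and are overridable; synthetic tests use their own planted panels
so nothing downstream depends on the shipped lists.

## Resolution scoring (`resolution`)

The entropy score uses natural logarithms throughout, with 0·ln 0 := 0,
and generalizes to any number of origins ≥ 2.  The denominator is the
global origin entropy −Σ_j f_j ln f_j — the score's value when all cells
occupy one cluster — which normalizes it to [0, 1].

The Monte-Carlo Fisher test downsamples to 150 cells, 100 repeats,
uniformly without replacement and unstratified.  Within a repeat, the
p-value is a permutation test: origin labels are shuffled 2000 times and a
permuted table counts as at least as extreme when its fixed-margins
multivariate-hypergeometric log-probability does not exceed the observed
one (the classical exact-test ordering); p = (1+extreme)/(B+1), so p is
never zero.  Degenerate subsamples (one cluster or one origin) score
p = 1, a deliberately conservative choice.  Mean and standard error over
repeats are reported.

Silhouette uses Euclidean distance on the 2-D embedding, with singleton
clusters contributing 0.  Selection: k\* = cluster count at maximal mean
silhouette (smallest on ties); within [k\*, 3k\*] the minimal mean Fisher
p wins, ties broken by lower entropy score then lower cluster count; an
empty window falls back to the global Fisher optimum with a recorded
warning.  Fisher is the primary criterion; silhouette bounds the window
from below so that under-clustered solutions cannot win on a p-value tie.

## Population shifts (`population`)

The five published category definitions overlap and leave gaps (e.g. one
ratio ≥ 1.2 with the other ≤ 0.8 matches both differential rules), so
they are evaluated in a fixed precedence — resistant, commonly emerging,
commonly depleted, differentially depleted, differentially emerging —
with anything unmatched (including |r_b − r_a| exactly at the separation
threshold) reported as `unclassified`.  Ratios default to per-origin
conditional cluster frequencies P(cluster | origin), which are robust to
unequal arm sizes; a `literal` mode reproduces the total-fraction ratio
d_(j,i),total/d_(vehicle,i),total exactly (the two agree when arms are
equal).  Clusters with no vehicle cells are flagged undefined.

## Signatures (`signatures`)

Cluster relatedness: mean expression profile per cluster over a gene set
(typically the variable genes), Euclidean distances, average-linkage
agglomeration, exportable as Newick.  Marker ranking: two-sided Wilcoxon
rank-sum per gene (asymptotic), BH adjustment across all tested genes,
fold change ln(mean(expm1 x_high)+1) − ln(mean(expm1 x_low)+1) with a
|logFC| > 0.25 cutoff.  Natural log is the default base (the convention
behind the `avg_logFC` field name); base 2 is available and the base used
is recorded in the output metadata.

## Synthetic data (`synthdata`)

The scRNA-seq generator emulates a three-arm perturbation study: three
origins (vehicle, control compound, probe), five subpopulations at
vehicle frequencies 0.30/0.25/0.20/0.17/0.08, with the rare 8%
subpopulation depleted to 0.2× frequency in the probe arm only
(≈80% depletion after renormalization, expected frequency ratio ≈0.214).
Stage marginals are 0.631/0.139/0.230 for G0/G1, S and G2/M.  Counts are
gamma–Poisson (negative binomial, shared dispersion 2) over a heavy-tailed
log-normal baseline, with log-normal library sizes (median 8000).
Subpopulation programs put a 3-fold effect on 40 disjoint genes each
(subtle structure); stage programs put an 8-fold effect on 40 marker
genes per stage — cycle markers behave near on/off between stages in real
droplet data, and cycle signatures are expected to dominate subpopulation
signatures, which is precisely why the pipeline stages cells first.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, gene–gene correlation beyond the program structure, zero
inflation beyond NB sampling, or UMI collisions.  Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not robustness to every artifact of real droplet data.

All generators are seed-deterministic and independent of mapping
insertion order (arms are drawn in sorted name order, so configurations
survive round-trips through sorted YAML).  The dose-response generator
offers both multiplicative (CV) and additive (SD) noise; coverage checks
of the fit intervals use additive noise, matching the unweighted
least-squares error model the intervals assume.

## Pipeline (`pipeline`, `cli`)

Stages are assigned first, then the entire clustering/scoring stack runs
independently within each stage subset.  Runs are bit-identical under a
fixed seed, and the resolved configuration written beside the results
re-runs to identical outputs.  Stage subsets below `min_stage_cells`
(default 50) are skipped with a warning rather than scored unreliably.

### Problem sizes used in the shipped checks

The test suite and acceptance checks run the simulation-based properties
at 400 cells per arm (1200 total, 1500 genes) for stage assignment and
cluster-number recovery, 200 multinomial replicates at the three-arm
sizes 4099/3583/3232 for the depletion classification, 500 samples for
the LC-MS/MS chain, and 100–200 replicates for the fit-calibration
checks — sizes at which the planted effects are comfortably identifiable
while the whole suite completes in about a minute.

## Known limitations

- The occupancy model has no kinetics; time courses are equilibrium
  snapshots at each time point.
- The MC Fisher p is a permutation approximation (network-algorithm exact
  enumeration is not attempted for r×c tables); its resolution is bounded
  by 1/(B+1).
- t-SNE coordinates, and hence silhouette values, are seed-dependent;
  selection results should be read together with the recorded seed.
- Wald/t intervals on nonlinear fits remain approximate near parameter
  bounds (e.g. very shallow melts).
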