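# Methods

## The synthetic experiment generator

The generator emulates a multi-site soil survey plus microcosm incubation:
54 alfalfa-system sites (one composite soil each) spanning uniform climate
gradients (MAT 0–20 °C, MAP 100–1600 mm yr⁻¹), incubated under an
environmental control and three stressors, giving 216 per-sample units by
default. It is an *effect model*, not an incubation simulator: treatments
are multiplicative suppressions of gene abundance, and no moisture or
temperature kinetics are represented.

**Climate → stoichiometry.** Soil totals are log-normal:
log(total) = log(mean) + b_MAP·z(MAP) + b_MAT·z(MAT) + ε. Defaults: total C
12 g kg⁻¹ (b_MAP 0.30, b_MAT −0.10, σ 0.25), total N 1.2 g kg⁻¹
(b_MAP 0.35, σ 0.20), total P 0.65 g kg⁻¹ (b_MAP 0.05, σ 0.25 —
near-independent of climate, as P derives mainly from parent material).
C/N, C/P and N/P are computed exactly from the totals, so the ratio
identities hold to machine precision.

**Stoichiometry → abundance.** log₁₀ copies g⁻¹ of each gene is
intercept + Σ slopeₚ·z(predictor) + ε with σ = 0.25 log₁₀ units (log-normal
noise: qPCR copy numbers are positive and right-skewed). The biomass
markers (16S ~10⁹·⁵, ITS ~10⁸ copies g⁻¹) are generated first and their
standardized log abundances feed the functional genes. The default sign
matrix encodes the reported correlation structure: total N, C/P and N/P
positive with all 16 functional genes; total C positive with the
amoA-b/nifH/narG/nirS/nosZ subset; total P negative with the P activators
phoD and pqqC; C/N negative with phoD/phoC/pqqC/nirK/fungcbhIR/GH74;
climate linked to only four genes (MAT with nirK and phoC, MAP with pqqC
and fungcbhIR); both biomass markers positive everywhere, with the
C-cycling decomposers loading more on ITS than 16S (they are largely
fungal), which induces the bacterial:fungal-ratio association for that
group. The base slope magnitude is 0.3 on the log₁₀ scale; within each
group the magnitudes of the three universally shared drivers (total N,
C/P, N/P) cycle through ×0.4/×1.0/×1.6, because genes within a group do
not respond with identical strength and it is exactly this within-group
contrast that compositional (Hellinger) ordination can see — a uniform
shared effect cancels in the row normalization.

**Disturbance.** Treated abundance = control × exp(−m) with
m = baseline(gene) + Σ slopeₚ·z(predictor) + ε clipped at zero
(suppression by default; the resistance index uses only |D₀|, so direction
is a readability convention). Stoichiometry predictors enter m on the
*log* scale: they are log-normal, and standardizing the logs keeps m — and
hence resistance — linearly related to the variables the path models use.
Per-gene baselines (natural-log units) encode the reported resistance
ordering: phoD 0.9 and phoC 0.7 for drying-wetting (most sensitive) with
nosZ 0.15 (most resistant); nosZ and GH51 0.8 for warming with amoA-a
0.15; the glycoside-hydrolase C genes 0.85 for N deposition with
amoA-b/nirS/narG/norB at 0.15; all others 0.4. Stressor-level drivers:
MAP buffers drying-wetting (slope −0.25), MAT buffers warming (−0.25),
and C/P (−0.20) with total C and N (−0.12 each) buffer N deposition.
Effect noise σ = 0.25 keeps site-level group-resistance R² in a realistic
0.7–0.9 band rather than near 1. None of these magnitudes are measured
quantities; they are free parameters fixed once at values that give the
qualitative structure described above.

**What passing tests show.** The generator reproduces the *dependency
structure* (signs, orderings, driver hierarchy) of a real survey, not its
marginal distributions, spatial autocorrelation, assay noise floor, or the
published effect sizes. Tests passing on synthetic data therefore validate
the estimators and the pipeline plumbing — they do not certify that the
published field-data values would be recovered, which requires the
deposited dataset.

## qPCR handling

Standard curves are OLS fits of Cq on log₁₀ copies; efficiency
E = 10^(−1/slope) − 1. The efficiency correction rescales each gene by
(2/(1+E))^Cq_ref with Cq_ref the gene's mean Cq equivalent under its
curve: the exact correction rule used in the original assays is not
specified anywhere we could follow, so this is a documented convention —
identity at E = 1, rank-preserving within a gene — and can be disabled.
Cq values outside the fitted range are extrapolated with a logged warning.
The synthetic dilution-series generator draws efficiencies in 0.85–1.05
and sizes its Cq noise (σ = 1.75 cycles on 6 points) so fitted R² values
concentrate in the 0.94–0.98 band typical of these assays.

## Resistance and group scores

RS = 1 − 2|D₀|/(C₀+|D₀|) is computed on raw copy numbers (the index as
printed; no log transform). C₀ ≤ 0 makes the index undefined — such
records are excluded and reported, not coerced to −1. Group-level
resistance defaults to the per-site arithmetic mean of member-gene RS; the
share-normalization alternative (applied to RS + 1 to enforce
nonnegativity) is exposed as `mode="eq2"` because RS can be negative while
share normalization presumes nonnegative inputs. The cross-stressor
comparison uses Kruskal–Wallis with Dunn post-hoc z tests and
Benjamini–Hochberg correction across genes — RS is bounded and skewed, so
rank tests are the safe default; a one-way ANOVA + Welch-t alternative
sits behind `method="anova"`.

## Variance partitioning

Gene abundances are log₁₀-transformed (they span orders of magnitude),
Hellinger-transformed (square root of row proportions), and regressed on
each predictor set by multivariate least squares; R² is the trace ratio
and the Ezekiel adjustment 1 − (1−R²)(n−1)/(n−p−1) is applied per set.
Fractions follow inclusion–exclusion over adjR²(M), adjR²(S), adjR²(M∪S);
negative adjusted fractions are reported as computed and flagged, never
truncated. Within-set rank deficiency is an error naming the dependent
columns; the M∪S union tolerates redundancy and uses the matrix rank as
its predictor count (two identical sets must yield zero unique fractions).
Significance of a unique fraction: the tested set is residualized on the
other set (with intercept), its rows are permuted and re-residualized, and
the statistic is the extra explained sum of squares of the residualized
response; p = (1+#{perm ≥ obs})/(1+n_perm), 999 permutations by default.

## Random-forest importance

The forest is a purpose-built CART implementation (numba-compiled):
bootstrap per tree, mtry = max(1, ⌊p/3⌋) candidate predictors per split,
variance-reduction splitting, minimum node size 5 — the regression-forest
conventions — with all randomness from an explicit splitmix64 stream so a
seed reproduces the forest bit for bit. It exists because the importance
statistic needed here is *per-tree out-of-bag permutation importance*:
for each tree, the OOB MSE increase when one predictor's OOB values are
shuffled. Per-tree increases are averaged over the 500 trees and expressed
as a percentage of the forest-level OOB MSE; normalizing per tree instead
would bias the null upward (a noisy small-sample denominator — Jensen's
inequality), which the null-calibration test would catch. Raw %IncMSE can
be negative; a clipped percent-of-total view is also emitted since
published MPI axis conventions vary. Significance refits the whole forest
to each row-permuted response (99 permutations by default); a
no-refit approximation that only re-scores OOB error is available behind
`refit=False` and labelled as such.

## Path models

Models are recursive (DAG) path models over observed variables — the
published diagrams contain no latent variables — so maximum likelihood
coincides with per-equation OLS on standardized data, which is what is
implemented (transparent and oracle-testable against plain regression).
Exogenous covariances are fixed at their observed values; residual
correlations are absent. The model-implied correlation matrix is assembled
in topological order with each endogenous residual variance chosen so
implied variances are exactly 1 (the standardized solution; clamped to a
tiny positive value if a regression explains numerically everything).
χ² = (n−1)·[ln|Σ| − ln|S| + tr(SΣ⁻¹) − p]; df = p(p+1)/2 − free
parameters; RMSEA = √(max(χ²−df,0)/(df(n−1))), defined as 0 with a
saturated flag at df = 0; AIC = χ² + 2·free parameters. Good fit requires
RMSEA < 0.05 and 0.05 < P(χ²) ≤ 1. Pruning removes the retained edge with
the largest p ≥ α (ties: smaller |β|, then lexicographic), refits, and
stops when all edges are significant; both the a-priori and optimal fits
are reported. The default a-priori model sends MAT and MAP to log total C,
log total N and log C/P and directly to resistance, with the compositional
path log total C → log C/P included a priori (the ratio contains total C;
omitting it forces a structurally false conditional independence and
inflates χ² for every model). At n = 54, RMSEA retains its well-known
small-sample upward bias, so pruned models can fail the RMSEA criterion
while passing the χ² one.

## Problem sizes and numerical choices

Simulation-based tests run at the sizes needed for their statistical
claims and no larger: sign recovery at n = 500 × 20 seeds; variance
partitioning reproduction over 100 seeded 54-site experiments; importance
rankings over 50; pruning behaviour over 20; both permutation-test
null calibrations over 500 simulations at n_perm = 99. Degenerate inputs
(zero rows, constant columns, all-zero genes, nonpositive controls,
singular predictor sets) raise typed errors naming the offending entity.
Ties in tree splits are resolved by first-best over the sampled feature
order; Hellinger rows must be strictly positive in total; permutation
p-values use the add-one convention and can never be 0.

## Known limitations

- The generator's sites are exchangeable: no spatial or province-level
  autocorrelation, no site-level replication structure.
- Treatment metadata (+4.5 °C, 25 kg N ha⁻¹ yr⁻¹, 50 % WHC, 4 × 2-day
  wet / 5-day dry cycles, 1-month incubation) is carried as annotations
  only; the disturbance model is phenomenological.
- Resistance is mildly nonlinear in the generator's effect index, so path
  models fitted to group resistance carry a small structural χ²
  contribution even at the generating graph.
- Only the resistance index is implemented; resilience/recovery indices
  from the same family are out of scope.
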