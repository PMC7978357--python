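# Methods

`auxintor` reimplements, as a tested pipeline on synthetic or tabulated
inputs, the quantitative analyses by which indole-3-acetic acid (IAA, auxin)
was identified as an ATP-competitive inhibitor of yeast TORC1: transposon
insertion-library fitness scoring, chemical-genetic z-score screening with set
overlaps, enzyme-kinetic mechanism discrimination, dose-response IC50
estimation, and a Cheng-Prusoff model of physiological inhibition.

## Transposon-library model and fitness scores

**Generator.** A library of `n_clones` independent transposon mutants is laid
down once: each clone carries a single insertion, placed in a uniformly chosen
gene at a uniform position within its body (or, with probability
`intergenic_fraction`, uniformly in intergenic space). Insertion maps of real
saturated libraries show dense, roughly uniform within-ORF coverage, which this
matches at the resolution the scoring uses (per-gene tallies). After `g`
generations of batch growth a clone with relative fitness `f` is represented by
`2^(g·f)` copies — exponential clonal expansion, the minimal model consistent
with generation/copy bookkeeping (12.7 generations → ≈7×10³ copies per
founder). Sequencing reads for each condition are one multinomial draw of the
requested library size over clone abundances, so read totals are conserved
exactly and identical seeds reproduce byte-identical tables.

`per_gene_fitness` encodes *drug-conditional* fitness: it weights the treated
expansion only, while the control culture expands neutrally. The alternative —
applying `f` during both expansions — would make a deleterious gene look
*enriched* whenever the control grows for more generations than the treated
culture (as in the screen modeled here: ≈5.5 control vs ≈4.2 treated
generations), which is not the depletion readout the analysis is built to
detect. Genes whose loss is unconditionally sick are out of scope of the
generator; the scoring handles them the same way either way (their effect
cancels in the ratio).

**Scoring.** Insertions are assigned to every gene whose 1-based inclusive
interval contains the position (strand-agnostic; overlapping genes each
count). Per gene the score is

    score = log2( ((t + pc)/T) / ((c + pc)/C) )

with per-gene counts `t`, `c` (reads by default, distinct insertion sites as
an alternative mode) and library totals `T`, `C`. The pseudocount (default 1)
bounds scores for zero-count genes; it makes the depth-invariance of the
score exact only in the limit `pc → 0`, which is how the property is tested.
Genes empty in both libraries score exactly 0. Percentile bands use
nearest-rank cutoffs (depleted ≤ 10th percentile, enriched ≥ 90th by
default); ties at a cutoff fall into the extreme band, and a degenerate
distribution (coincident cutoffs) yields all-neutral with a warning.

**Recovery benchmark.** With 1,000 genes of which 50 have `f = 0.5`, 100,000
clones, 5×10⁶ reads per library and the culture generations above, ≥90% of
the truly depleted genes fall in the bottom score decile (observed: 100% at
the default seed). These sizes run in a few seconds and were chosen to match
the modeled screen's per-gene read depth (~5,000 reads/gene).

## Chemical-genetic screen

Colony sizes are normalized by their plate median (removing per-plate pinning
and growth batch effects, which the generator injects as lognormal per-plate
scale factors), averaged over replicate spots (quadruplicate by default),
and expressed as the ratio r = drug/control per strain. Standardization is
robust: z = (median(r) − r) / (1.4826·MAD(r)), oriented so a growth deficit
gives positive z; strains with z ≥ 1.88 are called sensitive, the threshold
used by the screening platform the pipeline emulates. If MAD = 0 with all
ratios identical (e.g. drug table equals control) all z are 0; MAD = 0 with
differing ratios is a degenerate population and an error.

A robust z against a threshold is a rank-free call whose precision depends on
prevalence: neutral strains have approximately standard-normal z, so a ~1-3%
false-positive rate at 1.88 is intrinsic, and the MAD is inflated (hence the
effective threshold raised) as the sensitive fraction grows. The joint
precision/recall benchmark therefore uses 400 mutants with a 15% sensitive
fraction, where the operating point is informative (observed at the default
seed: recall 1.00, precision 0.97); at low prevalence the same caller should
be read as a screening filter, not a final classifier.

Set overlaps report Venn region counts (which always partition the union),
conditional percentages (e.g. 85 of 156 IAA-sensitive strains also
rapamycin-sensitive → 54.5%), and an exact hypergeometric upper-tail
enrichment p-value when a universe is supplied.

## Inhibition kinetics

Steady-state rate laws for mechanisms MM, competitive, noncompetitive,
uncompetitive and mixed (see `inhibition_kinetics` docstring for the five
formulas); all reduce to Michaelis-Menten at zero inhibitor, a property
tested to machine precision. Fits are *global*: one (Vmax, Km, Ki[, α])
shared across all inhibitor levels, which is how Ki is defined and maximizes
identifiability on small grids. Optimization is unweighted least squares
(1/v² weighting available) in log-parameter space — positivity without
constrained solvers — with multi-start initialization (Km at the substrate
grid's min/median/max, Ki at 0.1/1/10 × the median inhibitor level, Vmax at
1.1 × the maximum velocity); the best SSE wins and must not exceed any
start's.

Mechanisms are compared by AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1),
ascending, ties toward fewer parameters. The discrimination benchmark (100
seeded datasets per true mechanism, 5% CV, 8×3 grid ×3 replicates, ≥90%
accuracy) uses the panel {MM, competitive, noncompetitive, uncompetitive}.
The mixed model stays available for fitting but is not in the default
discrimination benchmark: it nests the others as α→1/∞ limits, so on data
truly generated by a nested mechanism it wins exactly when the chance SSE
improvement of one extra parameter beats the AICc penalty, a coin-flip-rate
event that says nothing about the data. Classical diagnostic signatures
(apparent Km rising linearly with I at constant Vmax under competition;
apparent Vmax falling at constant Km under noncompetition) are verified on
noiseless per-level MM fits.

Parameter uncertainty uses case-resampling bootstrap percentile intervals
(≥100 resamples; refits start at the point estimate; degenerate resamples are
skipped and counted; intervals are widened, if ever needed, to contain the
point estimate). Coverage of the true Km by nominal 95% intervals is ≥88%
over 200 simulated datasets in the test suite.

Dose-response curves use the 4-parameter logistic
`response = bottom + (top − bottom)/(1 + (d/IC50)^hill)` with bottom
constrained non-negative, top initialized at the zero-dose mean, and dose 0
mapping exactly to the top plateau. Requires ≥5 dose levels including 0; a
curve with no decrease from dose 0 to the top dose returns a fit-failure
result rather than silent parameters.

## Physiological inhibition model

For an ATP-competitive inhibitor the effective half-maximal concentration at
cellular ATP follows Cheng-Prusoff, `IC50 = Ki·(1 + [ATP]/Km_ATP)`, and
fractional inhibition is `% = 100·[I]/([I] + IC50)`. With Ki = 2.4 μM and
Km_ATP = 50.5 μM this gives 145 μM at exponential-phase ATP (3 mM) and 5.1 μM
at stationary-phase ATP (56 μM); at 10 μM intracellular IAA the predicted
inhibition is 66.2%. The 66.2% arises when the effective IC50 is rounded to
two significant figures (5.1 μM) before the inhibition step — `predict_state`
exposes this as `paper_rounding` and always reports the unrounded IC50
alongside (unrounded chaining gives 66.4%).

Intracellular concentrations convert pmol amounts through total cell volume
(1 pmol per 10⁶ fL = 1 mM; conversions centralized in `units` with their own
tests), using 4 fL per exponentially growing cell and 2 fL (50% reduced) for
stationary/G1-arrested cells. Isotope-dilution quantification back-calculates
`amount = ((area_ratio − intercept)/slope) × IS_amount` from an unweighted
OLS line through the 6-point analyte/IS ratio calibration; negative
back-calculations are clipped to 0 and flagged. Because the intercept error
of an unweighted calibration is additive (≈CV × the calibration's ratio
scale), relative accuracy of ~3×CV holds in the central calibration range but
degrades toward the bottom of the range — quantification near the lowest
calibrator should be treated as semi-quantitative. Growth bookkeeping is
`g = log2(N_end/N_start)`, copies per founder `2^g`.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the analyses consume:
multinomial read sampling at fixed library depth, fitness-dependent clonal
expansion, plate batch effects, CV-type (multiplicative, zero-truncated
Gaussian) noise on velocities, colony sizes, responses and peak areas, and a
linear isotope-dilution response. They do not emulate PCR amplification bias,
insertion-site sequence preferences, essential-gene margin effects (genes are
treated uniformly, as the within-ORF placement of real insertions is not
modeled below gene resolution), spatial plate edge effects, chromatographic
peak integration, or matrix effects in MS. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise models, not
robustness to these real-data artifacts.

## Numerical choices and degenerate inputs

- Seeds are mandatory for every stochastic routine; there is no hidden global
  RNG state, and equal seeds give byte-identical outputs.
- Exact-fit SSE is floored at 1e-300 inside AICc to keep log defined;
  noiseless data therefore give a very large negative AICc rather than NaN.
- Velocity fits use Levenberg-Marquardt with xtol/ftol 1e-12; the 4PL is fit
  on (log IC50, log hill, top, log bottom).
- Fewer than 10 genes triggers a warning for percentile banding; fewer than 3
  genes makes treatment correlations an error.
- Insertion-table parsing reports the 1-based line of the first malformed row
  (non-integer, position < 1, negative reads, invalid strand).

## Known limitations

- The z-score construction of the original screening platform is not public;
  the plate-median/robust-z construction here is a principled stand-in whose
  threshold semantics (z ≥ 1.88) are calibrated on the synthetic generator,
  so published screen hit counts are inputs, not recomputed outputs.
- Whether the published per-gene analysis used read counts or distinct
  insertion events is ambiguous in its source; both modes are computed and
  reported side by side, with reads as the default.
- No tight-binding (Morrison) correction: Ki estimates assume free inhibitor
  ≈ total inhibitor, valid here because Ki (μM) far exceeds the enzyme
  concentration (nM).
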