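# Methods

## The models

`rmeco` implements three deterministic resource-competition models of
bacteria–phage interaction in which bacterial populations differ only in the
set of restriction–modification (RM) systems they carry.  All three share a
chemostat-like nutrient equation

    dN/dt = S − Σ_i α_i (1 − c_i) B_i N

with `N` the nutrient concentration in cellular equivalents·ml⁻¹ (a fixed
per-cell quota is absorbed into the unit), `S` the supply rate, `α` the
nutrient-utilization rate (ml·cell⁻¹·day⁻¹) and `c_i` the defense cost of
host `i`.  Cost is strictly linear in the number of RM systems: with a
per-RM cost of 0.05, one RM costs 5% of utilization, two cost 10%, and a
total cost reaching 1 is rejected as a configuration error rather than
clamped.

Host and phage dynamics differ by interaction structure:

* **general** — a single phage infects every host.  Host `i`'s
  susceptibility is `γ_i = r_e^(−|b_i|)`: each RM system multiplies the
  infection rate by `1/r_e`, so protection is multiplicative across systems
  (two systems at `r_e = 100` give a 10,000-fold reduction).
* **parallel** — one phage per host, no cross-infection; the same `γ_i`
  applies to each private pair.
* **memory** — one phage type per host, all phages infect all hosts, and
  every burst from host `i` releases phage of type `i` carrying host `i`'s
  methylation pattern `p_i = b_i`.  The pairwise susceptibility is

      Γ_ij = r_e^(−(|b_i − p_j| + (1 − m_v)·|b_i ∩ p_j|))

  RM systems the incoming phage is not methylated against act at full
  strength; systems shared with the phage's methylome are discounted by the
  virion methylation `m_v ∈ [0, 1]`.  At `m_v = 0` the matrix column-reduces
  to the general model's `γ`; at `m_v = 1` a phage fully escapes the
  defenses of any host whose RM set its methylome covers.

RM identities are opaque labels in frozensets; only set difference and
intersection cardinalities enter the dynamics.  Phage loss in each model is
`δ_p P` for the phage being updated; the infection-rate constant φ carries
units ml·virus⁻¹·day⁻¹, which is what dimensional consistency of the
`φγB P` terms requires.

## Default parameters

The defaults (in `ModelParams`) were chosen once so that the two-host
sweep displays the three canonical regimes — low-supply competition
monoculture, mid-supply coexistence, high-supply defense dominance with
general-model exclusion versus parallel-model coexistence — at biologically
sensible abundances:

| parameter | default | units | rationale |
|---|---|---|---|
| α | 1e-7 | ml cell⁻¹ day⁻¹ | break-even nutrient ~1e6 C.E./ml at δ_b=0.1 |
| φ | 1e-6 | ml virus⁻¹ day⁻¹ | puts the 3-RM phage-persistence ceiling near 1e10 cells/ml at r_e=100 |
| r_e | 100 | fold | a moderate per-RM infection reduction of two orders of magnitude |
| m_v | 0.99 (pairwise) / 0.75 (multi-level) | – | near-perfect vs partial virion methylation |
| β | 50 | virus cell⁻¹ | typical lytic burst size |
| δ_b, δ_p | 0.1, 0.5 | day⁻¹ | host and virion turnover |
| per-RM cost | 0.05 | – | a few percent of utilization per system |

With these values the single-host viral-persistence threshold is
`S_crit = δ_b δ_p / (β φ γ)`; phage appear on a 1-RM host near S ≈ 1e5
C.E. ml⁻¹ day⁻¹ and host ceilings are `δ_p/(βφγ)` = 1e6, 1e8, 1e10 cells/ml
for 1, 2, 3 RM systems.  All defaults are overridable per experiment
(`ModelParams.with_`, YAML configs, per-host α and cost overrides).

## Numerical protocol

**Steady states.**  Populations are integrated in log abundance (nutrient
linear) with LSODA in geometrically growing time chunks.  Log coordinates
keep deep transient crashes — which pass many orders of magnitude below any
absolute solver tolerance — representable, so a population that would
rebound is not spuriously zeroed; a reflecting floor at 1e-30 cells/ml
holds dynamically extinct populations in place while leaving them able to
re-invade, mirroring the fact that a deterministic ODE never reaches exactly
zero.  Populations initialized at exactly zero are structurally frozen (the
true dynamics keep them at zero forever).

Convergence is declared when `max_i |dx_i/dt| / (|x_i| + ε) < 1e-6` with
ε = 1e-3 cells/ml.  ε here is an absolute abundance scale, not merely a
division guard: a doomed population decays at a constant *relative* rate
(its relative derivative never shrinks), so a purely relative criterion
could never fire while it dies out; any ε far below the 1 cell/ml
extinction threshold gives identical classifications.

**Oscillations and polishing.**  The parallel model at high supply (and
parts of the memory regime) has host–phage cycles whose damping rate is
numerically indistinguishable from zero: when one host pins the nutrient,
the other host–phage pair reduces to a neutrally stable predator–prey
oscillator.  Two complementary mechanisms handle this:

1. after a short transient, a Newton solve (`scipy.optimize.root`, log
   parametrization) attempts to land exactly on the fixed point the
   trajectory is circling; the root is accepted only if it lies within an
   order of magnitude of the current state, extinct populations cannot
   re-invade it, and it is not strongly dynamically unstable;
2. failing that, when the trajectory's time-average over successive long
   windows (≥1500 days) stops changing, the run returns that average as a
   non-converged summary.  For these bilinear systems the cycle average of
   each population equals its fixed-point abundance (the log-derivative of
   each population averages to zero over a cycle), so the average is the
   meaningful steady-state surrogate.

A deterministic solver-step budget (`max_steps`) bounds the cost of
fast-oscillating parameter corners in ensembles; on exhaustion the latest
window average is returned, non-converged.

**Sweeps.**  Supply grids are log-spaced (default 30 points across
1e3–1e9).  Each supply rate warm-starts from the previous steady state with
extinct populations reseeded at 1e-2 cells/ml so that invasion at higher
supply remains possible; a population is scored extinct below 1 cell/ml.
Both floors are protocol choices (the underlying continuous model has no
extinction), and both are configurable.

**Ensembles.**  Latin Hypercube sampling uses `scipy.stats.qmc`
(one draw per equal-probability stratum per dimension), with `r_e` and φ on
log-uniform scales since they span orders of magnitude.  One root seed
fixes the entire ensemble; results are bitwise reproducible from
(seed, config).  The reference ensemble size is 1,000 draws; the test suite
runs reduced ensembles (tens of draws, shorter grids) that exercise the
same code paths.

## RM-system calling

The annotation module consumes precomputed evidence tables (it never runs
the search tools): per-protein gene coordinates, profile (HMM) hits with
residue envelopes and E-values, and local-alignment hits against reference
enzymes.  Rules, in order:

1. **Profile competition** — while two retained hits on one protein share
   ≥75% of the shorter envelope's residues, the higher-E-value hit is
   discarded; ties break toward the longer envelope, then the
   lexicographically smaller profile id, making the result order-independent.
   The shorter-envelope denominator is a deliberate (strict, symmetric)
   reading of "75% of the same residues".
2. **Alignment acceptance** — ≥75% query coverage and E ≤ 1e-5, both
   inclusive.
3. **Role classification** — both activities on one peptide → fused system;
   methyltransferase-only and >750 aa → putative type IIG (size separates
   IIG enzymes from plain methyltransferases; 750 aa exactly is *not* IIG);
   ResIII-like endonuclease evidence accompanied by a known false-positive
   covariate domain on the same protein is discarded (those domains recur in
   helicases and transcriptional regulators).
4. **Completeness** — fused and putative-IIG proteins stand alone; remaining
   endonucleases pair greedily, nearest first and one-to-one, with a free
   methyltransferase on the same contig at a boundary-to-boundary gene gap
   ≤4,000 bp (inclusive; 0 for overlapping genes; strand ignored).  Orphans
   are not counted.

Distance semantics (boundary gap, same contig, one-to-one pairing) are
package decisions where the published rule is silent; the synthetic
fixtures pin each boundary (a 4,000-bp gap pairs, 4,001 does not, etc.).
Counts are reported with and without the putative type IIG calls; dropping
them can only lower a genome's count.

## RMPG statistics

Isolate tables aggregate to genus level by arithmetic mean (RMPG and genome
size) with isolate counts; genus-level summaries use mean, median and
5th/95th quantiles by linear interpolation of order statistics (the numpy
default — the published quantile values depend on this convention, so it is
fixed and documented).  Regressions of genus-mean RMPG on genus-mean genome
size use Mbp units:

* **linear** — ordinary least squares with R² and the two-sided slope test;
* **negative binomial** — log-link GLM with dispersion α profiled by
  maximum likelihood and fit quality as McFadden's pseudo-R²
  (1 − ll_fit/ll_null).  Genus means are not integers; by default they
  enter the NB likelihood through its gamma-function (continuous) form, with
  a `round_response` alternative for comparison.  On simulated tables the
  two modes agree to within a few percent of the slope.

The genome-expansion-to-gain-one-RM figure is the reciprocal slope for the
linear model (baseline-independent) and, for the NB model, the Δ solving
`exp(η + slope·Δ) = exp(η) + 1` at the chosen baseline (default 2 Mbp).

The two-group comparison is a two-sided Wilcoxon rank-sum test with midrank
ties: exact full-enumeration permutation of the rank-sum statistic for
combined n ≤ 20 (valid under ties), otherwise the tie-corrected normal
approximation with continuity correction.

## Synthetic data

`synth.gen_annotation_fixture` plants complete systems with safety margins
(pair gaps ≤3,900 bp, duplicate profiles overlapping ≥80%, intergenic
spacing 6,000 bp > the pairing reach) and decoys that each violate exactly
one rule at its boundary; configurations whose decoys could accidentally
satisfy a rule are rejected at construction.  `synth.gen_stats_tables`
draws isolate RM counts from a negative-binomial (or Gaussian-noise linear)
model on genome size, with an optional additive habitat shift for two-group
tests.  Both generators are deterministic in their seed and emit the same
table dialects the pipeline reads.

What the fixtures do not emulate: real domain architectures beyond what the
rules inspect, correlated evidence errors (e.g. systematically truncated
envelopes), phylogenetic correlation between genera, or overdispersion
varying with genome size.  Passing on these fixtures therefore shows the
decision logic and estimators are implemented correctly, not that the
published annotation of real genomes would be reproduced from raw searches.

## Known limitations

* The models are deterministic, well-mixed and non-evolving: no demographic
  noise, space, RM gain/loss within a run, or saturating infection
  kinetics.
* Near-neutral oscillatory regimes are summarized by their cycle mean; the
  amplitude of those cycles is not a reported quantity.
* The published numeric parameter table for the simulations is not
  redistributed here; the defaults above reproduce the qualitative regime
  structure, not specific published curves.
* The deposited genus-level survey table is likewise not bundled; the
  statistics on it can be recomputed by placing it at
  `data/genus_table_s1.csv`.
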