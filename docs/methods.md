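# Methods

## The kinetic model

Each transcript's abundance R(t) follows a linear birth–death equation

    dR/dt = v_eff(Tb(t)) − k_eff(Tb(t)) · R,   R(0) = v_sr / k_dr,

forced by a body-temperature trajectory Tb(t). Warm-state (37 °C)
parameters are sampled per transcript: the synthesis rate v_sr is
lognormal with log-mean `mu_syn` (default 0.033, i.e. a typical rate of
~1 mRNA/min) and log-sd `sigma_syn` (0.1); the half-life in hours is
lognormal with log-mean `mu_halflife` (default 2.5, ~12 h) and log-sd
`sigma_halflife` (0.3), converted to `k_dr = ln2 / halflife / 60` per
minute. The half-life log-sd is a calibration: with σ = 0.3 the
closed-form population mean E[k] = (ln2/60)·exp(−μ + σ²/2) reproduces
the documented average degradation rates at μ = 3.5 and μ = 7.5
(3.63·10⁻⁴ and 6.69·10⁻⁶ mRNAs/min) simultaneously; no single choice is
exactly consistent with both documented average *transcription* rates
(27.93 and 1.3967 mRNAs/min differ by ~0.5% from any one lognormal
σ), so σ_syn = 0.1 is retained and agreement is expected at the 1%
level.

Temperature enters through Q10 scaling, rate(Tb) =
rate(37)·Q10^((Tb−37)/10), with Q10 = 3.0 for synthesis and 2.0 for
degradation, and synthesis is set to zero below 18 °C (transcription
effectively ceases at low Tb). The differential Q10 makes the
steady-state ratio v/k fall with temperature: cooling favors
degradation. The degradation Q10 sits in the conventional physiological
2–3 range; 2.0 specifically is a calibration chosen so that the default
temperature-gated mechanism (below) yields a greater-than-twofold rise
of the protected subset's normalized abundance after ten days of torpor,
the regime the model is meant to exhibit. Both Q10 values and the arrest
temperature are configurable.

### Body-temperature profile

The default 12-day cycle is: 12 h warm interbout at 37 °C → 12 h linear
entrance ramp 37 → 4 °C → 10 days of torpor at 4 °C → 2 h arousal ramp
4 → 37 °C → 22 h warm remainder. Entrance is deliberately much slower
than arousal (cooling is passive; rewarming is driven by brown-fat
thermogenesis). Ramp durations and the torpid set-point are calibrated
choices, not measured values; an exponential transition shape is
available since real cooling is approximately exponential. The profile
is evaluated on a uniform grid (default 1 min) and treated as piecewise
constant per grid cell with the left-endpoint convention.

### Integration

Because Tb is constant within a grid cell the ODE is linear with
constant coefficients there, so the per-cell update

    R ← v/k + (R − v/k)·e^(−kΔt)      (k > 0;  R ← R + vΔt for k = 0)

is exact. There are no solver tolerances to tune; accuracy is limited
only by the grid's sampling of the ramps, and a 100×-finer RK4
integration agrees to better than 10⁻⁶ relative error. At 1-minute
resolution the full 1,450-transcript, 12-day run takes a few seconds.

### Normalization

"Normalized" abundance mimics library-size (tags-per-million)
normalization of sequencing data: transcript i's share of the population
total at time t, divided by its share at t = 0. Under this view a subset
whose decay is merely slowed *appears* to increase while the population
total falls. Folds are evaluated at the final minute of the torpor phase,
before the arousal ramp. Both the subset mean and median are reported by
the CLI; tests assert the mean.

### Protection mechanisms

1. **Elevated transcription** — the protected subset's synthesis
   log-mean is moved to `mu_shift` by a quantile-preserving
   multiplicative shift, with either the degradation rate raised to hold
   the warm steady state (`matched_degradation`) or the steady state
   allowed to grow (`steady_state`). Because synthesis is arrested in
   deep torpor, this mechanism cannot raise relative abundance at the
   end of torpor; with matched degradation it actively lowers it.
2. **Reduced degradation** — the half-life log-mean is shifted up, with
   synthesis lowered to hold steady state (`matched_transcription`) or
   steady state allowed to grow. The protected fold rises with the
   shift and saturates (once protected decay is negligible, the fold is
   set entirely by the bulk decline).
3. **Temperature-gated protection** — rates are sampled exactly as for
   bulk; at run time, whenever Tb is *strictly below* `threshold_tb`
   (default 10 °C; the boundary is exclusive), the protected subset's
   degradation is clamped to `protection_fraction` (default 0.03) of its
   warm value. Unprotected transcripts are never touched.

**Dose–response caveat.** The clamp protects only while
`protection_fraction` is below the Q10 cold-scaling factor
(2.0^((Tb−37)/10) ≈ 0.10 at 4 °C). Above that, the "protection" pins
degradation *faster* than the Q10-scaled cold rate and raising the
threshold then lowers the fold. Monotonicity of the fold in the
threshold therefore holds in the protective regime, and sweep grids
default to fractions ≤ 0.1. Monotonicity in the fraction itself holds
unconditionally. Sweeps share one sampled population across all grid
cells so the heatmap isolates mechanism effects from sampling noise.

## Tag-count stages

* **TPM**: 10⁶ × count / library total; all-zero libraries are dropped
  with a warning.
* **Expression floor**: a tag is kept if some group of size n has
  ≥ n−1 samples at ≥ 2 TPM. Groups of size 1 are rejected (the rule is
  undefined there).
* **Replicate concordance**: the tag's mean over the first members of
  all technical-replicate pairs versus the mean over the partners; a
  ratio ≥ 3 in either direction removes the tag. The boundary is
  inclusive ("differed by threefold" read conservatively), a zero mean
  on exactly one side counts as infinitely discordant, and a zero on
  both sides is concordant. The filter is applied to TPM by default;
  which scale the original workflow used is not documented, so the
  choice is exposed.
* **Platform test**: the cross-platform differential test (negative
  binomial GLM with FDR correction) is consumed as a precomputed
  per-tag q-value column with a q ≥ 0.05 retention rule, not
  reimplemented.
* **Full-quantile normalization**: each column's sorted values are
  replaced by the across-column mean of order statistics; ties share the
  mean of the quantile values at their tied ranks (mid-rank
  interpolation). The operation is idempotent and equalizes the
  columns' sorted multisets exactly.
* **Patterns**: per-tag group means divided by the tag's grand mean of
  group means, in the fixed physiological order SpW, SpC, SA, IBA, Ent,
  ET, LT, EAr (configurable). Technical-replicate columns are excluded
  from downstream analyses.
* **DIANA**: classical divisive analysis on 1 − Pearson dissimilarity.
  Each cluster of positive diameter is split by seeding a splinter group
  with the object of maximal average dissimilarity and migrating objects
  whose average dissimilarity to the splinter group is smaller than to
  the remainder; the node's height is the diameter of the set it splits,
  so heights are monotone from root to leaves. Constant patterns (zero
  variance) have no defined correlation and are excluded with a warning.
* **Longest-branch cut**: the cut height is placed at the midpoint of
  the widest gap between consecutive distinct split heights (ties go to
  the higher gap); maximal subtrees below the cut become clusters. With
  fewer than two distinct heights there is no gap and a single cluster
  is returned.

## Poly(A)-fraction analysis

Loading correction without a housekeeping gene: each transcript's value
in a sample is divided by the within-group median across samples, and
the per-sample factor is the mean of those folds over transcripts.
Factors are identified only up to a per-group scale (the group's
absolute level is unobservable by construction), which is how recovery
is scored. Transcripts with a zero within-group median are excluded
from that factor with a warning.

Classification uses one-way ANOVA across the four states (IBA, LT, EAr,
SpW) at α = 0.05 per fraction, with a guard for zero within-group
variance (p → 0 if the means differ, 1 if not — the noise-free limits).
Directions compare LT (total RNA) or the LT/EAr mean (poly(A)
fractions) to IBA. The decision list:

1. **Class I** — total significant and falling, poly(A) significant and
   falling with it;
2. **Class IIA** — poly(A) fractions significantly rising;
3. **Class IIB** — total significant and falling, poly(A) not
   significant;
4. otherwise unclassified, with all test statistics recorded for audit.

A "poly(A) change" requires *both* the short- and long-fraction ANOVAs
significant by default (`polya_rule="both"`): the stabilized class gains
material in both fractions, and the disjunctive rule would carry a ~10%
family-wise false-positive rate against the flat-poly(A) Class IIB
archetype. `polya_rule="any"` is available. Where total RNA is
marginally significant the recorded statistics, not a hidden tie-break,
are the arbiter. Technical qPCR triplicates can be screened at 3 scaled
MADs (`remove_outliers_mad`); the underlying workflow removed outliers
without stating a rule, so the screen is explicit and configurable.
Spearman correlations to tag patterns use mid-ranks and an exact
permutation p-value for up to 8 states.

## Synthetic data

The tag simulator emulates the study design: eight groups with sizes
SpW 6, SpC 5, SA 5, IBA 4, Ent 5, ET 4, LT 4, EAr 5; negative-binomial
counts (gamma–Poisson, dispersion 0.1, typical of digital tag data;
dispersion 0 degenerates to rounded means) around per-tag base levels
(lognormal around 50 TPM) times archetype patterns times library size
(uniform 1–10 million); ET and SA samples sit on a second platform where
a planted 10% of tags carry a 4× bias; two cross-platform technical
replicate pairs re-draw counts around the partner's biological mean.
Six stylized archetypes span the group axis — two spring/summer-high
and four winter-high with peaks at IBA/Ent, ET, LT and EAr. They are
deliberately close to mutually orthogonal: real cluster centroids
overlap more, so passing recovery tests shows the pipeline recovers
identifiable structure, not that real clusters are this clean. Note the
TPM step compresses the planted platform bias (biased tags inflate the
platform-B library total), so the replicate filter is scored as strong
enrichment of biased tags among removals rather than an exact oracle.

Fraction-profile templates per class (states IBA, LT, EAr, SpW, three
replicates, mean-one lognormal noise at a given CV): Class I — total
1.0/0.35/0.55/1.1 with both poly(A) fractions falling and the long:short
ratio shrinking (tail shortening); Class IIA — flat total with short
2.0–2.6× and long 2.6–3.6× rises at LT/EAr (ratio rising, tail
lengthening); Class IIB — total 0.45–0.5× at LT/EAr with flat poly(A)
fractions (percent recovery rising). The qPCR generators plant
per-sample loading factors and multiplicative noise on a bias-free
table.

What the generators do *not* emulate: tag-to-gene annotation ambiguity,
zero inflation, within-group biological covariance, batch structure
beyond a single platform factor, and absolute qPCR calibration. Tests
passing on these fixtures demonstrate correctness of the algorithms
under their stated models, not performance on real libraries.

## Problem sizes

Default analyses run at the study scale: 1,450 transcripts over 17,280
one-minute grid cells for the headline simulation; 5-minute grids for
the 25-cell sweep and mechanism contrasts (grid refinement changes the
folds by far less than the margins being tested); 400-tag fixtures for
the clustering pipeline; 100 draws per class for recovery rates. The
acceptance script completes in well under a minute on one CPU.

## Known limitations

* The Tb trace is stylized; fitting recorded datalogger traces is out
  of scope, and multi-bout season-long schedules are not modeled.
* Transcription kinetics are deterministic rate equations; stochastic
  birth–death effects and protein-level dynamics are not modeled.
* The classification boundary between IIA and IIB under marginal total
  significance follows the stated decision list; the audit statistics
  are reported so users can apply their own tie-break.
* DIANA's splinter heuristic is the classical algorithm, not an optimal
  bipartition; on well-separated data they coincide (verified against
  exhaustive enumeration on small instances).
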