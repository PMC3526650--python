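# Methods

## Cohort bookkeeping

All scenario families share one year-stepped engine. A subject is a birth
year plus an integer lifespan L; the state is a vector of cohort counts
indexed by formation-year offset (0 = the perinatal pool, treated as a
single cohort formed at birth). Event years are indexed by the subject age
attained at the *end* of the year, t = 1..L, and time-varying rates are
evaluated at that age. Within a year, formation and destruction are both
computed from the start-of-year state and applied simultaneously; a cohort
is never depleted during its own formation year. Counts are continuous
(real-valued): at 5×10⁸ cells the discrete process is deterministic in
expectation, and a Bernoulli/Poisson agent simulation is kept in the test
suite as an oracle for exactly this claim (continuous counts match agent
means within Monte-Carlo error on 10⁴-agent instances).

Two per-year survival kernels are available for a cohort carrying an annual
death rate d:

* `annual` — multiply by (1 − d). This makes constant full replacement
  exactly count-preserving and the surviving initial-pool fraction exactly
  (1 − r)^L, which is the closed-form oracle used throughout the tests.
* `continuous` — multiply by exp(−d), i.e. d acts as a constant hazard
  spread over the year (the limit of many small within-year sub-steps).

Direct rate schedules default to `annual`. The TVB-TVDR family defaults to
`continuous`, with formation computed as a fraction of the *count at birth*
rather than the current total. Both choices were open — the sources state
neither the within-year update order nor the formation denominator — and
were fixed once against the one printed quantitative trajectory available
for this family: a 70-year simulation at Bs = 0.10 %/yr², Bi = 2.5 %/yr,
Ds = 0.5 %/yr², Di = 1.0 %/yr must reach ~130 % of the birth count near age
20 and ~87 % at year 70. The adopted conventions give 129.65 % and 87.06 %;
annual-kernel/current-total variants land at 140 %/79 % and are therefore
not the behaviour those dynamics describe, though both remain selectable
(`kernel=`, `formation_basis=`) and the equivalence and closed-form
invariants are asserted under the shared `annual` kernel.

Evaluated rates outside [0, 1]/year are clipped with a warning. Every
simulation satisfies the conservation identity
`trajectory[end] = trajectory[0] + Σ formed − Σ destroyed` to a relative
1e−9 and never produces negative cohorts.

### Stem-cell (hierarchical) formation

The default formation formula treats each cycling cardiac stem cell as
completing one mitosis per `mitosis_hours` and amplifies each activation by
`2^E` (E = expansion exponent, divisions before senescence):

    formed/year = n_csc(age) · cyc_frac(age) · (8766 / mitosis_hours) · 2^E(age)

Destruction is `total · apoptotic_frac(age) · (8766 / apoptosis_hours)`,
applied uniformly across cohorts (random elimination). The formula is a
pluggable callable because the hierarchical model's single-iteration count
change is reported in the source material only diagrammatically; the
default composes the stated components with the hours-per-year conversion
(8766 h). Parameter tables are inputs (CSV, linear interpolation between
listed ages, per sex); the tables bundled in `myoturn.fixtures` are
synthetic, calibrated once so the documented qualitative behaviours hold
(male counts decline monotonically; female counts rise to a midlife peak
and end above their value in youth; constant-denominator male turnover
~7 %/yr in young adulthood; E = 5 so a ±20 % change in E moves formation
two-fold). They are emulations of the reported trends, not measured data.

### E2 and time-dependent families

The E2 hazard is `γ₀ · a^(−γ₁)` (capped at 1) for CM age a ≥ 1 —
destruction inversely related to CM age — with formation balancing total
deaths so the count stays constant. The time-dependent family is full
random replacement with turnover linear in subject age. Both functional
forms are transcription choices (the originals appear only as figure
images); they implement the prose descriptions exactly and are isolated
behind the scenario union so alternative forms can be swapped in.

### Age-structured model

One reference cohort of size N is seeded at birth and each subsequent
year; a cohort of age a with half-life h retains `2^(−a/h)` (h evaluated at
the subject age of formation by default), with a mortality fraction
µ(a, t) deducted iteratively each year. The ledger's counts are the age
distribution n(a) at autopsy; with µ = 0 and lifespan = h the initial
cohort is exactly halved.

## Radiocarbon forward model

Atmospheric Δ14C is handled as a differential series, per mil relative to
1955; values before 1955 are identically 0, and loaders enforce this
(strict error or lenient zero-fill with warning). Smoothing is a 12-month
moving average resampled to yearly values (centered by default, trailing
selectable); raw monthly values are retained for the min/max initial-value
modes, which take the extreme reading within 12 months of birth.

A cohort formed in calendar year y starts at the smoothed curve value at
y − delay (delay 0 by default; 2 years models dietary incorporation lag,
implemented by shifting every atmospheric lookup, so a delayed policy and a
time-shifted curve are exactly equivalent). For each subsequent year of
subject life the polyploidization update mixes in contemporary atmosphere:

    value ← (value·1 + atm·p) / (1 + p)

with p the incremental polyploidization fraction at that subject age. The
update is implemented exactly as stated in the source methodology even
though the 1/(1+p) weighting is not a normalized partition; a normalized
variant `(1−p)·value + p·atm` is selectable for comparison. Each update
keeps the value between its previous value and the contemporaneous
atmosphere, so cohort values are convex combinations of the atmospheric
values spanned by the subject's life (a property test).

The cumulative polyploidization curve is a logistic in age, anchored to 0
at birth, with midpoint 8 y, steepness 2 y and plateau 0.6 by default —
chosen once to express "essentially complete during childhood"; the exact
published coefficients are not reproduced in the available text. The curve
is scaled by a single multiplier (1.0 reference, 0.78 for the lower
literature estimate, 0 disables correction — the identity on assignments).
Tabulated curves can be supplied instead.

ΛC14 = count-weighted end C14 − initial C14. On a constant curve with zero
ploidy, ΛC14 = 0 for any dynamics; for pre-1955 births the initial value is
0 and ΛC14 equals end C14.

## Inversion

Per-cohort C14-at-death values depend only on the subject, curve, ploidy
and policy — not on the dynamics — so solvers precompute them once and
candidate scenarios merely re-weight them. `solve_constant` scans a dense
rate grid (default 0–50 %/yr in 0.01 % steps), takes local minima of
|predicted − target| within a 1 per mil tolerance, and reports the
smallest-rate minimum as the low branch and the largest as the high branch.
For pre-pulse births the forward map has a single interior maximum, so two
preimages (a bifurcation) exist once the target exceeds the high-rate tail
value, which is reported as `threshold_lambda`. Degenerate inversions
(flat forward map) return rate 0 flagged `degenerate`; unreachable targets
return the best-effort minimum flagged non-converged, never an exception.

`fit_global` is exhaustive grid search — deliberately, matching the source
methodology; no gradient or stochastic optimizer is involved. SSE is
computed on ΛC14 (equivalent to end C14 since initial C14 is fixed per
subject). All grid points within 1e−9 of the minimum are reported as ties,
with the lexicographically smallest parameter vector as the canonical best
(determinism). The default strategy evaluates a 4× coarser sub-grid first
and refines around its optimum at full resolution, visiting only points of
the requested grid; tests assert it returns the exhaustive optimum on
fixtures. The AIC is `n·ln(SSE/n) + 2k` by default and pluggable (AICc and
a per-observation variant are included) because published AIC magnitudes
for these datasets do not identify a unique formula; AIC should be used to
*rank* families, not as an absolute target.

## Sensitivity analyses and bands

Multiplier sweeps scale one parameter uniformly across all ages. Bands are
pointwise envelopes over sweep members, or — for simultaneous ±20 %
variation of the apoptotic fraction and expansion exponent — over all
corner combinations of the multiplier hypercube (the combination rule was
unstated; the corner envelope contains the one-at-a-time variant by
construction). Gender-composite trajectories are pointwise weighted means
(default 75 % male / 25 % female). Band overlap is the per-age interval
[max of lowers, min of uppers], empty where inverted; it is commutative and
idempotent. Bands are scenario envelopes, not confidence intervals, and no
inference is attached to their widths.

## Synthetic study conditions, problem sizes, and what tests show

The bundled bomb-curve fixture is deterministic: 0 before 1955, a smooth
monotone rise to +800 per mil at 1963, then exponential relaxation at
0.04/yr, sampled monthly over 1930–2010. It emulates the shape of the
measured atmospheric record, not its values: month-to-month measurement
scatter, hemispheric offsets and the post-2000 fine structure are absent.
Synthetic cohorts (default 12 subjects, 75 % male, births 1933–1985,
deaths by 2006) carry ground-truth ΛC14 computed through the package's own
forward model. Passing tests therefore demonstrate internal consistency,
exact closed-form agreement, and recoverability of generating parameters
under realistic-shaped conditions — not agreement with measured biology.
The measured-data reproduction (global SSEs, per-subject branch rates,
delay and ploidy-scaling effects) is implemented in
`scripts/external_reproduction.py` and an acceptance test, but requires
the measured atmospheric series and subject table as user-supplied files;
that test fails until those inputs are provided.

Default problem sizes keep everything desk-scale: lifespans ≤ 90 years,
rate scans of 5001 points, recovery grids of 5⁴ points (the full
published-range TVB-TVDR grid of ~17M combinations is supported via the
coarse-to-fine strategy). The entire suite runs in well under a minute on
one CPU.

## Known limitations

* The hierarchical formation formula, the E2/time-dependent functional
  forms and the polyploidization sigmoid coefficients are reconstructions
  from prose; all are pluggable so exact transcriptions can replace them.
* Turnover is scale-invariant in N0, but absolute-count outputs inherit the
  10-gram bookkeeping convention (N0 configurable; two inconsistent
  published reference counts exist, 5×10⁸ is the default).
* No isotope-fractionation chemistry or AMS measurement-error model;
  measured C14 values are taken as given.
* Sub-annual event scheduling (individual mitoses/apoptoses within a year)
  is intentionally out of scope; sub-year kinetics enter only through the
  hours-per-year conversion.
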