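# Methods

`hdssmig` implements a migration-typology analysis for longitudinal Health
and Demographic Surveillance Site (HDSS) data on children and adolescents:
residence episodes are reduced to a quarterly panel, residence changes are
detected and classified into four move types (short/long crossed with
independent/accompanied), household composition and kin proximity are
derived from a kinship graph, and the association between family structure
and move type is estimated descriptively (with two-way clustered variances)
and by multilevel multinomial regression.  Because real HDSS registers are
access-restricted, the package ships a synthetic register generator that
reproduces the structural features the analysis relies on; every stage is
exercised and tested end-to-end on generated data.

## Panel construction

Episode data are snapshotted on the 15th of the middle month of each
quarter (Feb/May/Aug/Nov 15); a person contributes a record at a snapshot
iff a residence episode covers it (half-open convention: an episode covers
`start <= q < end`).  Ages are exact day differences divided by 365.25;
all age bands are half-open with the boundary age assigned upward (age
exactly 12.0 is an adolescent female).  Life stages: females are children
below 12 and adolescents in [12, 25); males are children below 16 and
adolescents in [16, 29); older people are out of scope.  Within-stage age
subgroups follow the four bands per sex; the male-child "young" band is
[3, 8) so that the partition is total.

Survey-derived covariates (parental secondary education, marital status)
are taken from the nearest survey whose validity window covers the
snapshot: 12 months forward and 6 months backward from the survey date
(configurable; the most recent prior survey wins when both directions
match).  Absent a valid survey the fields stay missing — no imputation;
missingness propagates to the regression exclusion rules.  Parental vital
status comes from the parent's own register record when the parent is
linked; unknown parents yield a missing flag, which the regression treats
as "not known to be dead".

Population density is the number of co-temporal residents within 250 m of
the household (housemates count, the index person does not), categorised
into within-dataset tertiles; the tertile boundaries are logged in the run
manifest for reproducibility.

## Move detection and typology

Between consecutive snapshots a move candidate arises when (a) the
location-tied geographic household ID differs (internal move — this
includes whole-household relocations, which change the geographic but not
the unique household ID), (b) an episode ends in out-migration inside the
quarter, or (c) an episode starts with in-migration inside the quarter.
Candidates displacing under 5 m are dropped before anything else: they are
artefacts of geographic-ID reassignment when a new household head is
declared.  If several candidates attach to one person-quarter (e.g. an
entry from outside the area followed by an exit in the same quarter),
exactly one is retained uniformly at random; the draw stream is consumed
in (person, quarter) order under the run seed, so results are reproducible.

A move is attributed to the earlier of its two bracketing snapshots (the
exposure quarter), so the covariates attached to a move describe the
sending household.  A consequence used by the regression stage: an
in-migration has no in-area record at its exposure quarter, so such moves
never enter as regression outcomes.

Distances are haversine great-circle displacements on a sphere of radius
6371.0088 km; at the scales involved this is within ~0.6% of an
ellipsoidal geodesic, negligible against the 4 km classification cutoff.
External moves are anchored on gazetteer coordinates — the centre of a
Malawian town, or the point of a foreign country nearest to Malawi.  A
label missing from the gazetteer leaves the distance unresolved: the move
is never distance-filtered, is excluded from distance-classified outputs,
and is counted in the run ledger.

Short means strictly below the cutoff (default 4 km); long means at or
above.  The cutoff is a configured constant, not an estimate: the
school-change diagnostic (consecutive-year survey pairs of primary-school
attenders whose geographic household ID changed, with mean moved distance
by same-school vs changed-school status and individual-clustered 95% CIs)
is reported alongside it to justify the choice on any given register.

Independence: co-movers of an internal move are origin-household members
found in the mover's destination household at the next snapshot; for
boundary crossings, members sharing the same normalised (case-folded,
trimmed) source or destination label in the same quarter, and for entries
additionally the same destination household.  A move is accompanied iff a
co-mover is a parent of the index (any age) or an adult aged 18+;
otherwise independent.  The index's own age is irrelevant.

## Kinship and household composition

Parent links define a typed directed graph (checked acyclic; mother edges
must originate from females); spousal links carry validity intervals.
Five kin sets are evaluated at a query date:

* maternal/paternal: blood kin reached through that parent, up to 3 blood
  edges beyond the parent (grandparents, parent's siblings, their
  children), excluding the parent, the index, the index's siblings and
  those siblings' children.  Blood paths may climb to ancestors and then
  descend but never climb again after descending, which keeps co-parents
  and other in-laws out.  The depth bound is configurable; 3 is deep
  enough to cover the relatives the composition rules name while staying
  computable.
* sister's/brother's family: siblings of that sex aged 18+ plus their
  current spouses and children (a 17-year-old sister belongs to the
  nuclear set instead).
* nuclear: parents plus siblings under 18.

The household-composition category applies a fixed precedence to rules
that are individually non-exclusive: `no_ids` (index lacks both parent
IDs), `external` (household outside the surveillance area), `spouse`,
sister's/brother's family (requiring a strict majority over the other
when both are present, and a co-resident parent or no co-resident
maternal/paternal kin), `mother & siblings`, `father & stepmother` (a
father's other wife counts via his concurrent marriages), `maternal` /
`paternal` (strict majorities; ties fall through), `parents & siblings`
(both parents present), else `other`.  Spouse dominates because spousal
households are the modal adolescent state and any spousal co-residence is
the decisive fact about them.  The cascade is total by construction and is
property-tested against an independent declarative re-implementation on
10,000 random rosters.

Kin-proximity flags are true when at least one member of the corresponding
set lives within 250 m (inclusive) in a *different* household at the
quarter.  Household age-band counts use bands <1, 1–4, 5–11, 12–18, 19–29,
30–59, 60+, excluding the index.

## Clustered descriptive statistics

Observations repeat within individuals and individuals cluster within
households, and people change households, so the two groupings cross-cut.
Variances therefore combine one-way clustered sandwich meats and subtract
the household-by-individual intersection (the standard two-way
cluster-robust combination): V = V_hh + V_ind − V_hh×ind, with negative
diagonal entries clamped at zero.  Proportions get normal-approximation
CIs truncated to [0, 100]; sex comparisons are two-sided Wald tests of the
male coefficient in a linear-probability contrast.  With singleton
clusters both reduce exactly to HC0, which the tests verify, and the
type-I error of the Wald test under a two-way clustered null is checked by
simulation (1,000 replicates).  Printed-table comparisons round half-up to
one decimal.

Flow tables use short moves only (the moves for which both sending and
receiving information is most complete): sending composition at the
exposure quarter (external for entries), receiving composition at the next
snapshot (external for exits or when no post-move record exists).  Sankey
exports are plain nodes/links JSON.

## Multilevel multinomial model

Outcome per person-quarter: no move (baseline) or one of the four move
types.  For category k,

    log P(y=k) / P(y=none) = x'β_k + σ_k a_i,   a_i ~ N(0, 1),

i.e. individual-level random intercepts u_ik = σ_k a_i with variances
σ_k², carried by one shared standard-normal factor per individual.  The
one-factor structure keeps the marginal likelihood a one-dimensional
integral, evaluated by Gauss–Hermite quadrature (15 nodes by default; 5–9
in the fast paths) and maximised by L-BFGS-B with analytic gradients and
σ_k ≥ 0 bounds.  Model-based SEs come from the numerically differentiated
observed information; a second, household-clustered covariance is
computed by the sandwich over per-individual score vectors grouped by the
individual's modal household, because individuals nest only approximately
within households.  Fully cross-classified category-specific random
intercepts would require a multi-dimensional integral that no available
estimator provides; the one-factor-plus-clustered-SE design is gated by
simulation: null recovery, exact reduction to a plain multinomial logit at
σ = 0 (checked against an independent implementation), shrinking bias in
n, and 95%-interval coverage of a focal fixed effect within [0.90, 0.99]
over 50 replicates at 5,000 individuals.

Dataset rules: in-migration moves never appear as outcomes (no sending
information); persons lacking both parent IDs are excluded; rows with
composition `other`, `no_ids` or `external`, or with any missing household
socio-economic field, are dropped, with counts logged per reason.
Covariates: composition (baseline `parents & siblings`), the seven
age-band counts, the five kin-proximity flags, own-child presence
(adolescent strata only), known parental deaths, age subgroup, two-year
calendar bands (2004–05 … 2016–17), road distance (linear), density
tertile, parental secondary education, and household-head employment rank.
Constant columns at small synthetic scale are dropped and recorded.
Models run separately by sex and life stage.

## Synthetic register generator

The generator emulates the study conditions: a rural lakeshore population
observed 2004–2017 with quarterly analysis cadence and annual surveys
(July round), two-peak age mobility (accompanied moves of young children
through household relocation and divorce; independent adolescent moves
through marriage and fostering), patrilocal female marriage migration
(probability 0.8 by default), divorce return-moves to the natal household,
maternal-weighted child fostering (weight 0.7), household relocations
(0.04/household-year, 60% within 4 km), boundary crossings (15% of moves
leave the area, destinations drawn from a bundled gazetteer) and
out-migrant returns (0.2/year).  Default vital rates are plausible for a
high-fertility rural population (age-banded fertility peaking at
0.22/woman-year, infant mortality 0.05/year); they are stated as defaults,
not calibrated to any real register's totals.  Events are competing
exponential hazards held constant within calendar months, with dates drawn
at day resolution; identical seed and config give a byte-identical
register.

Founder compounds create the kin structure the classifiers need: brother
households share placeholder parents and sit 10–500 m apart, some wives
are sisters of earlier household heads (cross-household maternal kin), and
most in-married wives lack parent links (driving the `no_ids` path, as in
real registers).  A marrying man founds a new household near his father's
compound; a polygynous husband holds concurrent flagged episodes in each
wife's household — the only permitted episode overlap.  Household
relocations close and reopen members' episodes on the move day, so the
ground-truth event list is an exact recount of episode boundaries and
serves as the move-detection oracle.

What the generator does not emulate: reporting error and survey
non-response, seasonal labour migration, within-quarter multiple moves
beyond simple in-and-out pairs, household dissolution other than via
death/divorce, and real geographic clustering beyond uniform placement
with compound offsets.  Passing tests therefore demonstrate correctness of
the pipeline's logic under clean event data, not robustness to the
measurement problems of a real register.

## Problem sizes and numerical choices

The demo pipeline uses 40 founder compounds (~300 people, ~11,000
person-quarters), chosen so a full run — including four stratum models —
completes in well under a minute while every composition category and move
type is populated.  Recovery simulations use 5,000 individuals × 4
quarters with a compact design matrix.  Quadrature: 15 nodes for final
fits, 9 for simulation batteries, 5 inside the demo pipeline; the σ = 0
reduction is exact regardless of node count.  Ties in the random
single-move rule are broken by one seeded global stream consumed in
(person, quarter) order.  Degenerate inputs: empty strata are flagged
rather than fitted; a boundary σ̂ = 0 contributes no information row;
zero denominators yield flagged NaNs, never silent zeros.

## Known limitations

* The one-factor random-intercept structure implies perfectly correlated
  category intercepts within individuals; with strongly category-specific
  unobserved heterogeneity the variance partition is misspecified even
  though fixed effects remain well calibrated in the tested regimes.
* Household clustering enters only through robust SEs, not the likelihood.
* The within-dataset density tertiles make the density covariate
  register-relative, not comparable across runs.
* The sub-5 m artefact filter requires resolved coordinates; unresolved
  boundary moves can never be dropped by it.
* Kin sets are bounded at 3 blood edges beyond the linking parent;
  deeper classificatory kinship is invisible.
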