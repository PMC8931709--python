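# Methods

`doublecount` analyzes double-observer aerial strip-transect count data of
the kind collected in nearshore waterbird surveys: a front-seat and a
rear-seat observer on the same side of the aircraft independently record
every group ("flock") they see — taxon (species, or family when species
identification is impossible), group count, and time. Because the two
streams are never reconciled in flight, all inference about the three
classic aerial-survey error processes — nondetection, counting error, and
species misidentification — happens post hoc, and this package implements
that post-hoc pipeline together with a simulator for design-stage error
studies.

## Temporal reconciliation

Records from the two seats are paired when made within a closed temporal
window (default |Δt| ≤ 10 s, the conventional allowance for visibility
differences and recording lag between seats; the front observer can see
farther ahead, so the rear stream lags by a couple of seconds). Records on
different transects are never paired. Each record belongs to exactly one
*reconciled event*: a front/rear pair, or an unmatched singleton ("No
Match"), so `#front + #rear = 2·pairs + singletons` always holds, and an
event count per season equals the record count only under the
pair-counts-once convention used throughout (the alternative — counting a
pair as two records — cannot reproduce odd category totals and is not
offered).

**Pairing rule.** Which front record goes with which rear record is
underdetermined by the data, so we make the pairing a well-defined optimum
rather than an artifact of processing order: within each connected component
of the time-feasibility graph, we take the **maximum-cardinality one-to-one
assignment**, and among assignments of equal size prefer (i) the greatest
total identification agreement (species > family > none), then (ii) the
smallest total |Δt|. This is solved exactly with a linear assignment on
hierarchically scaled scores (cardinality ≫ identification level ≫
closeness), with inputs canonically sorted by (time, record id) so identical
data always yield identical events. A simpler per-record greedy rule
(nearest unclaimed partner) can strand matchable records — e.g. fronts at
t = 0 and 5 with rears at t = 4 and −6 under a 10-s window — which is why
the pair count is defined as the assignment optimum; a greedy pass is only
guaranteed to agree with it on cardinality when it happens to be optimal,
and the test suite certifies the optimum against exact enumeration.

**Categories.** Paired events are classified by strict precedence: exact
count match, then log10-bin match, then identification-only, each at
species level before family level; paired events agreeing on neither
species nor family are Mismatch; singletons are No Match. The log10 bins
are 0, 1–10, 11–100, 101–1000, 1000+; the printed labels overlap at 1000
and we resolve the tie downward (1000 ∈ 101–1000, so 1000+ means ≥ 1001).
The generic codes `gull` and `tern` are treated as species-level
identifications when identical and pool under Laridae for family-level
comparisons, reflecting how aerial observers actually use them; all other
generic codes match at family level only.

## Summary statistics

* **Category table / percentages** — events per (survey event, category);
  percentages to one decimal. On the published three-season table the
  counts give 32.59% and 35.94% where the source prints 32.5% and 36.0%
  (its own rounding is inconsistent by ≤ 0.09 points); we report the
  computed values. Similarly, the source's prose "roughly 33% of counts
  matched (N = 1996)" conflicts with 1996/5382 = 37.1%; this package
  reports the table-derived 37%.
* **Agreement rates** — share of *paired* events with exact count
  agreement, and with count-or-bin agreement, overall and by flock-size
  class (≤ 5, 6–30, > 30). A pair's size class uses the larger of the two
  recorded counts, since under predominant undercounting the larger count
  is the better proxy for true size.
* **Naive detection** — for observer X partnered with Y,
  `p̂(X) = pairs / (pairs + Y-only singletons)`: the share of the partner's
  events X also recorded, with no model-based correction. Under independent
  detection E[p̂(X)] = p(X). Reported per observer × survey event with
  row/column standard deviations.
* **Missed-size distribution** — recorded sizes of No Match singletons;
  under detection increasing with group size, misses concentrate at size 1.

## Mark-recapture estimation

Treating the front observer as the marking occasion and the rear as the
recapture occasion gives per-stratum capture counts n1, n2, m (m = paired
events). The default estimator is Chapman's bias-corrected form

    N̂ = (n1+1)(n2+1)/(m+1) − 1,
    var(N̂) = (n1+1)(n2+1)(n1−m)(n2−m) / [(m+1)²(m+2)],

with p̂1 = m/n2 and p̂2 = m/n1; the raw Lincoln–Petersen form (n1·n2/m) is
available but undefined at m = 0 and more biased in sparse strata.
Independence of the observers is assumed; correlated detection (shared
visibility) biases N̂ downward and can be explored with the simulator's
`detection_correlation` option rather than modeled here.

**Analytic check.** With equal independent detection p per observer and no
other errors, a flock produces a paired event with probability p², a
singleton with 2p(1−p), and nothing otherwise, so the expected No Match
share of events is 2p(1−p)/(p² + 2p(1−p)) = 2(1−p)/(2−p) — exactly 1/3 at
p = 0.8. This derivation (and the unbiasedness of naive detection and
Chapman) presumes each flock is temporally isolated, i.e. no cross-flock
pairing; validation configurations therefore use fixed inter-flock spacing,
while the realistic default is exponential spacing, under which neighbor
collisions within the window genuinely depress the No Match share (a real
property of window-based reconciliation, visible in the window-sweep
example).

## Counting-quiz analysis

Known-truth quiz responses (observers counting timed images of flocks of
known size) are summarized per image by the mean absolute percent
difference |100·(response − truth)/truth| with a Student-t 95% CI
(bootstrap percentile CI optional; the t interval is the default because
per-image samples are moderate and the statistic is a mean), the shares of
under/over/exact counts (a partition of 1; a response of 0 is a legitimate
−100%), and the mean response/truth ratio. Group comparisons (experience,
confidence) report group means with CIs per image-size stratum and test
equality of group means with a two-sided permutation test on the
size-weighted between-group variance of mean |%diff| (equivalent to the
absolute mean difference for two groups); a permutation test is used
because |%diff| is strongly right-skewed and group sizes are unequal.

## Simulator

The simulator is the package's test harness and a design-stage tool: all
error processes are explicit, independently switchable conventions (the
field data constrain their magnitudes but not their functional forms).

* **Flock sizes** — singleton with probability 0.70 (observed singleton
  shares ran 66–77%), otherwise lognormal(μ = 1.6, σ = 1.4) rounded and
  clamped ≥ 2: overall median 1, heavy tail into the thousands.
* **Detection** — Bernoulli with logit p = a + b·log10(size), b > 0
  (missed observations decrease in frequency with group size); defaults
  a = 1.4/1.0 (front/rear), b = 0.8. Correlated detection via a Gaussian
  copula on a shared availability draw preserves marginal p exactly.
* **Counting error** — multiplicative lognormal ratio R;
  E[R] = 1 for sizes ≤ 5 declining linearly in log10(size) to 0.45 at
  1000 (the midpoint of the observed 35–48% large-flock ratio), clamped
  beyond; sd(R) grows from 0.05 to 0.35 on the same scale. Recorded count
  = max(1, round(size·R)). The lognormal form gives the observed undercount
  skew and size-growing spread with two interpretable parameters.
* **Misidentification** — with probability `misid_prob` the taxon becomes a
  same-family confusable species; otherwise with probability
  `generic_id_prob` it becomes the family's generic code (defaults 0.05 and
  0.10; mutually exclusive draws).
* **Timing** — flock times with exponential spacing (mean 30 s; `fixed`
  spacing available for analytic validation), plus per-observer recording
  lag Normal(0, 1) s front and Normal(+2, 1) s rear.
* **Seeding** — one master seed; child generators for flock truth, shared
  availability, and each observer are spawned deterministically, so
  identical (seed, config) gives byte-identical CSV output.

The quiz generator applies the same counting-error model to 78 respondents
across four experience levels and 22 images spanning sizes 4–1000, with an
optional per-group error-scale multiplier to inject an experience effect
(none by default, matching the observed absence of one).

**What the simulator does not emulate:** spatial transect geometry and
flushing dynamics, observer fatigue or learning, clumped multispecies
aggregations (taxa are drawn independently of size and time), and real
clock-sync failures (a constant per-stream offset can be applied at load
time instead). Passing recovery tests therefore demonstrates correctness of
the estimators under the stated error model, not robustness to every field
condition.

## Problem sizes and numerics

Validation runs use 5,000–10,000 flocks for law-of-large-number checks,
200 replicate surveys of 2,000 flocks for Chapman recovery, 500 random
instances (≤ 8 records per side) against the exact pairing oracle (a
bitmask dynamic program), and 10,000 label permutations for quiz tests —
sizes at which Monte-Carlo error is far inside each assertion's tolerance
while the whole suite runs in seconds. Percentages are reported to one
decimal and detection probabilities to two, matching the conventional
table formats. Degenerate inputs are defined, not special-cased: empty
event lists give empty tables, m = 0 is valid for Chapman, single-response
images carry a point estimate without a CI, and empty size classes are
absent rather than zero.
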