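# Methods

This note documents the models the package implements, the parameter
choices that matter, what the synthetic-herd generator does and does not
emulate, and the numerical conventions, in the package's own terms.

## Event processing

Raw interaction logs are cleaned with two observational conventions
before any index is computed:

* **Minimum fight duration** — events shorter than `min_dur_s` (default
  3 s) are discarded.
* **Fight merging** — two fights of the same unordered pair separated by
  less than `merge_gap_s` (default 8 s, measured end-to-start) are
  treated as bouts of one fight and merged into a single event spanning
  both. Merging runs transitively left-to-right over the time-sorted
  stream; the merged event takes its behavior class and outcome from the
  last constituent bout, on the reasoning that the final bout is the one
  that resolves the encounter. With both thresholds at 0 the step is the
  identity.

Per-animal dyadic summaries credit active-attack duration/frequency
(DAA/FAA) to the aggressor, being-bullied duration/frequency (DBB/FBB)
to the receiver of *either* an active attack or a being-bullied event
(the receiving experience is the same; only the victim's response
differs), and standoffs (DSO/FSO) symmetrically to both participants,
since a standoff has no aggressor by definition.

All downstream statistics use `log10(x + 1)` of the six indicators. The
offset keeps zero-activity animals defined (lg = 0) and the base-10
choice makes a unit step interpretable as a tenfold activity change;
results are insensitive to the base since it rescales coefficients
uniformly.

Backtest struggling counts are recorded twice per animal; the package
keeps both replicates and exposes their mean, which the stats panel uses
as the coping-style score. The mean is the natural pooling for a count
assay repeated under identical conditions.

## Sociomatrix and I&SI

Decided wins are tallied into a per-pen matrix `W` (winners in rows,
losers in columns; draws contribute nothing), binarized by dyad
majority: `B[i,j] = 1` iff `W[i,j] > W[j,i]`, with tied dyads —
including never-interacted pairs — zero in both cells.

For a candidate order σ, an inconsistency is a dyad whose dominance
points up the order (`B[σ(j), σ(i)] = 1` with i placed before j); `I` is
the count of such dyads and `SI` the sum of their positional distances
`j − i`. The optimizer minimizes `(I, SI)` lexicographically with a
seeded two-phase heuristic:

1. initial order by descending net wins (row minus column sums of `B`),
   ties by animal id;
2. greedy improvement sweeps over candidate moves — swapping every
   currently inconsistent pair and every adjacent pair — accepting only
   lexicographic improvements, to a fixed point;
3. seeded random restarts (default 20), keeping the best order found and
   flagging whether distinct equally-optimal orders were observed.

Only improving moves are ever accepted, so the incumbent objective is
monotone. The test suite holds the heuristic to exact optimality against
a brute-force permutation oracle for n ≤ 7; at pen size (n = 10–11) the
restarts make failure to reach the optimum rare, but optimality is a
tested expectation, not a guarantee — which is the standard contract for
this family of heuristics. A worked consequence of the definitions worth
recording: for a 3-cycle the optimum is `(I, SI) = (1, 2)`, because the
single inconsistent dyad under any best order spans distance 2.

## Elo

Parameters: `k = 100`, initial rating 1000. The expected score of the
favourite is `p = Φ((r_high − r_low)/200)` (normal-CDF model, the
convention of the animal-dominance Elo literature); a logistic
alternative `p = 1/(1 + 10^(−diff/400))` is available by configuration.
The favourite's win moves both ratings by `(1 − p)·k`, an upset by
`p·k`; equal ratings fall into the favourite branch, where both coincide
at `p = 0.5`. Draws are excluded — Elo here is defined over decided
interactions only. Updates are exactly zero-sum, each rating change lies
in `(0, k)`, and final ratings depend on interaction order by design.

## Glicko

Glicko-1 with initial rating 2200 and rating deviation 300. Updates are
aggregated per rating period using opponents' pre-period values, with
the standard `q = ln 10 / 400`, `g(RD)`, expected score, `d²` and
posterior formulas. Choices the method leaves open:

* **Rating period = 1 h** (72 periods over the window), matching the
  hourly granularity at which trajectories and stability are analyzed.
* **c = 0** — no RD inflation during inactivity. The observation window
  is a single continuous 72 h episode; inflating uncertainty within it
  has no substantive motivation and would break determinism of flat
  segments. With c = 0, RD is non-increasing and bounded below by
  `rd_floor` (default 30, preventing degenerate certainty).
* **Draws excluded** by default, for consistency with the Elo
  convention; a score-0.5 mode is available.

Glicko is not exactly zero-sum; on synthetic herds the pen mean stays
within a narrow band of 2200 (the test suite checks the symmetric
single-game case exactly and the update formulas against an independent
hand computation frozen at 1e-6).

## Temporal dynamics

Hourly ranks are computed per pen from the Glicko trajectories (dense
ranks by descending rating; ties broken by the previous hour's rating,
then id — a full permutation every hour). Two stability definitions are
computed and reported side by side:

* **rank fixation** (primary): the smallest hour h such that the
  animal's rank is identical from h through hour 72; 1 if the rank never
  changes, 72 if it changes at the last hour.
* **rating plateau** (sensitivity): the smallest hour from which all
  consecutive rating changes stay below ε (default 10 points).

Rank fixation is adopted as primary because rank, not rating level, is
the socially meaningful quantity, and because it is parameter-free. The
first-rank emergence hour applies the same backward scan to the identity
of the rank-1 animal. Hourly-versus-final Spearman correlations require
at least three animals; hours with a constant rating vector are reported
as missing rather than given an arbitrary coefficient.

## Statistical panel

* Index inter-correlations: pairwise Spearman over pooled animals, with
  I&SI entering as integer within-pen rank (1 = most dominant), so its
  correlations with the cardinal ratings are negative; |rho| is reported
  alongside the signed value.
* Partial correlations: residual-on-residual Pearson after projecting
  both variables on the covariates, p from the t distribution with
  n − k − 2 df. Each index–indicator pair is controlled for the other
  five indicators; the backtest / body-weight / ADG panel is controlled
  for all six behavior indicators. A singular covariate matrix raises an
  error naming the columns; a numerically zero residual (e.g. the target
  equals a covariate) is reported missing.
* Multiple regression: OLS with intercept of each index on the six
  log-indicators, reporting B, SE, t and p per covariate; unidentifiable
  fits (n ≤ covariates + 1) are rejected.
* Sex contrast on stability time: fixed-effects OLS of stability hours
  on sex, parity, sire, initial body weight and sex × body weight.
  Adjusted sex means are g-computation averages (each animal's
  prediction with sex forced to the level, averaged), with delta-method
  standard errors; the p-value tests their difference. With covariates
  disabled this reduces exactly to the pooled two-sample t test. A pen
  random effect is deliberately not fitted — with 10 pens fully
  confounded with sex at the design level, a fixed-effects analysis is
  the transparent choice for this package; pen can be added as a fixed
  factor by the user.
* No multiple-testing correction: raw p-values are reported with
  0.05/0.1 read as significance/tendency thresholds.

## Synthetic herds

The generator emulates the target study design: 102 animals in 10
single-sex pens (five female, five barrow; sizes 10 or 11) observed for
72 h. Per animal a latent dominance `d_i = steepness × z_i`
(`z_i ~ N(0,1)`) is drawn; conditional on a decided fight, animal i
beats j with Bradley–Terry probability `1/(1 + exp(−(d_i − d_j)))`, and
the winner is recorded as the aggressor. Dyad fight times follow an
inhomogeneous Poisson process whose rate halves every `h_decay` hours
(default 24), reproducing the concentration of aggression in the first
hours after mixing; the default initial rate (0.17 fights/dyad/h, ~5
fights per dyad over the window) is calibrated to the ~150 interactions
per 8-to-11-animal pen typical of post-mixing observation. Female pens
use a half-life shorter by `sex_effect_h` (default 15 h → 9 h), so their
hierarchies settle earlier and the sex contrast has a recoverable
direction. Standoffs are always draws; fight classes draw with
probability `draw_prob` (0.15); durations are lognormal (median ~12 s),
so a realistic fraction falls under the 3 s validity threshold.
Steepness defaults to 1.5 — a clear but imperfect hierarchy, producing
index inter-correlations in the 0.8–0.97 range rather than the trivial
1.0 of a noiseless order.

What the generator does **not** emulate: winner–loser (experience)
effects, bystander effects, litter-mate familiarity, body-weight
asymmetries feeding into fight outcomes, and observer error. Passing
recovery tests therefore show that the pipeline correctly extracts a
static latent order from noisy sequential outcomes — not that real pig
hierarchies are static or Bradley–Terry distributed.

The rank-recovery experiment converts latent dominance and each index to
within-pen ranks and pools pens before correlating, since hierarchy
position is only defined within a pen; at steepness 0 the (identically
zero) scaled latent values are replaced by the unscaled draws, which
preserves the order whenever steepness > 0 and keeps the null
experiment non-degenerate.

## Numerical conventions and limitations

* All times are seconds since mixing internally; hours appear only at
  presentation boundaries.
* Matrix row/column order and all id-dependent tie-breaks use the stable
  sort of animal ids, so results are independent of input row order.
* Pipelines are deterministic given (seed, config); `run_all` writes a
  sha256 manifest so byte-identity across reruns is checkable.
* Stability times are integer hours in [1, 72]; analyses at other
  granularities require changing the Glicko rating period.
* The I&SI optimum need not be unique; the reported order is the first
  found under the seeded search and a flag records whether other optima
  were observed.
* Problem sizes used in validation: pens of 10–11 animals, ~150–550
  fights per pen, 10 replicate herds per recovery condition — chosen to
  mirror the emulated study design while keeping the full suite fast.
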