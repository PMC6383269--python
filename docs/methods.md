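# Methods

## The problem and the pipeline

A colony of bumblebee foragers exploiting a shared array of renewable
nectar sources tends, over time, to partition the array: different bees
concentrate on different flowers. `beepartite` quantifies that process from
a time-stamped flower-visit log. The pipeline is:

1. **Ingest & validate** the visit log (one row per landing: day, bee,
   flower, arrival/departure seconds, fed flag, optional bout id).
2. **Segment foraging bouts** — round trips from the nest. An explicit
   `bout_id` column takes precedence; otherwise nest-entrance exit/entry
   events define the trip intervals; failing both, a configurable
   inter-visit gap threshold (default 300 s) starts a new bout, with a hard
   break at every day boundary. The bout definition in the field requires
   nest events that public visitation data often lack, hence this ladder of
   fallbacks.
3. **Motivated-bee filter**: only bees with strictly more than 20 visits
   over the whole record are analysed.
4. **Eight-bout bins**: within each day, bout completions (nest-return
   times) are scanned chronologically; a bin closes when the first bee
   accumulates 8 completed bouts since the bin opened, and per-bee counters
   reset. Each bee therefore contributes 0–8 bouts per bin. A trailing
   partial period at day end is merged into that day's last closed bin
   (flagged `merged_tail`; configurable to keep it separate); if no bee
   ever reaches the quota, the day becomes a single flagged bin. Bins never
   span days — the alternative would invent overnight intervals with no
   observational meaning.
5. **Visitation matrices**: per bin, a flowers x bees integer count matrix.
   All declared flowers remain as rows even when unvisited; bees with zero
   visits in the bin contribute no column (they were not foraging then).

## Foraging metrics

Per bee and bin: **activity** (visits in the bin), **experience**
(cumulative visits over all earlier bins; measured in visits, not bouts),
and **flower specificity** — the population coefficient of variation of the
bee's visit counts over the full R-flower set, divided by sqrt(R − 1).
That normalizer is the unique scale-free choice pinning the endpoints:
0 for uniform use of all flowers, 1 when every visit lands on one flower
(the maximum CV over nonnegative vectors with fixed sum is sqrt(R − 1),
attained only at a one-hot vector). Metric rows exist only for bee-bins
with at least one visit.

Specificity is modelled as
`specificity ~ activity + experience + (1 | bee)` by REML (statsmodels
MixedLM); only a random intercept is used, which is the minimal structure
for repeated measures per bee. If the random-effect variance is singular
the fit falls back to OLS with a warning. Collinearity between activity
and experience is screened with variance inflation factors (threshold 2).
Per-bin modularity is regressed on mean activity, mean experience and the
number of bees foraging by OLS.

## Bipartite modularity

For a count matrix A with row sums k, column sums d and total F, a joint
partition (rows g, columns h) scores Barber's weighted modularity

    Q = (1/F) Σ_ij (A_ij − k_i d_j / F) · 1[g_i = h_j].

Q is maximized with weighted label propagation (LPAwb+-style): rows and
columns repeatedly adopt the label with the largest local gain
(sequentially, node order shuffled by the seeded RNG each sweep; ties go to
the lowest label index, making runs reproducible under a seed), followed by
greedy module merges while Q increases; propagate/merge alternate until a
fixed point (sweep cap 200 guards cycling). The multi-start wrapper
(DIRTLPAwb+-style) reruns the propagation `reps` times (default 10) from
random initialisations at each initial module count in 2..min(rows, cols),
plus the classic every-row-its-own-module start, and keeps the best Q. The
wrapper result is reported as *the* modularity of a network (the procedure
returns a single best value, not an ensemble average).

A brute-force oracle enumerates every set partition of the row+column node
set (feasible to 10 nodes, Bell(10) = 115 975 partitions) and anchors the
heuristic in tests: on random small matrices the multi-start search matches
the global optimum in ≳95% of cases and can never exceed it.

## Null model and significance

Observed Q is standardized against 100 random tables with the observed row
and column margins, drawn exactly (not by swap MCMC) with Patefield's
sequential hypergeometric construction (scipy's `random_table`; degenerate
single-row/column margins are forced analytically, working around a scipy
edge-case bug). Each null matrix is maximized with the same multi-start
settings as the observed one, on an independent substream of the master
seed. The z-score uses the sample (n−1) SD — immaterial at n = 100 but
stated for reproducibility — and a network is called significantly modular
by the one-sided rule z > 2, with no correction across bins. A zero-spread
null ensemble yields a flagged undefined z, never a significant call.

## Persistence of bee-flower associations

For each bin's partition, a bee is associated with every flower sharing its
module. Counting co-memberships across bins (which needs no label alignment
between bins) gives a bee x flower table; each bee present in at least 2
bins is tested by goodness-of-fit chi-square against a **uniform**
expectation over the declared flowers, scaled to the bee's total. Uniform
is the minimal null; a margin-weighted expectation would also be defensible
and the choice is deliberately explicit here. Expected cell counts below 1
attach a small-sample flag without suppressing the test.

## Encounters on flowers

A two-bee encounter (clips with ≥3 bees are excluded upstream of this
package) resolves as *resident stays* (joiner leaves first) or *resident
leaves* (replacement). The flower's reward state is inferred from the
resident's pre-arrival feeding time with the strict rule `> 8 s` — the time
a lone bee needs to drain a full 40-uL cup at ~5 uL/s — giving *consumed*
vs *not consumed*; exact-boundary events are flagged. Crossing outcome with
reward state yields exactly four classes that partition any event set.

The replacement model is a binomial (logit) mixed model of the joiner
replacing the resident on: reward status, standardized pre-arrival feeding
time, standardized encounter duration (joiner arrival to first departure),
the timing x reward-status interactions, and joiner-minus-resident
differences in activity, experience, specificity and body size where
available (direction: joiner minus resident; configurable). Contact events
only, by default. The carry-over model is a Poisson mixed model of each
participant's next-bout visits to the contested flower on its outcome
(won/lost), the reward status, and their interaction. Both use crossed
random intercepts for the two bee identities and are estimated with
statsmodels' Bayes mixed GLM at the posterior mode (Laplace
approximation); fixed-effect z = mean/SD of the approximate posterior.
Constant predictor columns (e.g. when every encounter happens on a drained
cup) are dropped from the design rather than fitted; a single-outcome table
raises a separation error.

## Synthetic data

**Planted-module sampler** (`plant_modular_log`): each bee owns a planted
flower subset; every visit targets its module with probability `fidelity`,
else uniformly outside. Bouts (1 + Poisson(λ − 1) visits, λ default 7) are
laid on a regular staggered schedule, 18 bouts per bee per 6-h day over 5
days — matching the regime of a well-populated flight-cage record (~900
bouts, ~6000 visits, ~7 visits per bout).

**Flight-cage simulator** (`simulate_colony`): event-driven. Ten flowers on
a regular decagon with 9-m sides (the published array reports a 15.8-m
second-neighbour spacing, which no regular decagon has; the load-bearing
property — that the 9.6-m visual detection radius reaches only nearest
neighbours — holds for the decagon and is what movement uses). Cups of
40 uL refill at 3.3 uL/min, primed with 20 uL at session start. Bees drain
cups at 5 uL/s, linger a few seconds (mean 5 s), and move to a flower
within detection range of their current position (with a 5% long-range
exploration chance), weighted by module fidelity and by suppression of
flowers from which they were displaced in the previous bout. A bee returns
to the nest when its crop (150 uL) is full, after 3 consecutive near-empty
visits, or after 1500 s; nest turnaround averages 900 s. Landing on an
occupied flower emits an interaction: the resident leaves with probability
0.2 if the cup still holds reward, 0.7 if drained. Flight speed 1 m/s.

Crop capacity, flight speed, handling, nest turnaround and the displacement
probabilities are free parameters; their defaults were chosen once so the
emergent statistics sit in a realistic regime (≈3.7–3.9 unique flowers per
crop-limited bout, ≈900–1000 bouts and ≈8000–9500 visits per 5-day run, all
four encounter classes populated) and are exposed on `SimConfig`. A
per-flower nectar ledger (initial + secreted = consumed + standing) is
checked at every event; the largest residual is reported in the ground
truth and is ~1e-12 uL in tests.

What the simulator does *not* emulate: learned route formation (traplines),
3-D flight, weather, forager turnover, satiation dynamics, or
inter-individual differences beyond module preference. Passing tests on
simulated data therefore show the estimators recover structure *of the kind
the generators plant*, not that any particular biological conclusion holds
in the field.

## Numerical and design notes

- All randomness flows from `numpy.random.SeedSequence` substreams of one
  master seed; every stage is bit-reproducible under it.
- Label-propagation tie-break: lowest label index; improvement threshold
  1e-15 avoids cycling on exact ties.
- The motivated filter is strict (`> 20` visits); the consumed rule is
  strict (`> 8 s`).
- Specificity of an all-zero vector is undefined and raises (such bee-bins
  are excluded upstream by the zero-column drop).
- Experiment sizes in the validation suite (100 oracle matrices, 10 000
  Patefield draws, 200 calibration/power replicates with 100 nulls at
  1 multi-start rep, 100 model-recovery replicates) were chosen as the
  smallest sizes at which the binomial error of the measured rates is well
  inside the asserted bounds.

## Known limitations

- Without nest-entrance events, gap-threshold segmentation can merge two
  quick successive bouts or split a long within-bout pause; the threshold
  is exposed and the choice logged.
- The uniform expectation in the persistence chi-square ignores unequal
  bin counts per flower-module size; with 10 flowers and ≥10 bins the
  approximation is reasonable but small-sample flags should be heeded.
- The Laplace/posterior-mode GLMM gives slightly conservative SEs relative
  to REML-style fits on small crossed designs; acceptance for these models
  is therefore sign-and-significance recovery under planted effects, which
  the validation suite measures directly.
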