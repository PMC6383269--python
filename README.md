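# beepartite

Resource partitioning among bumblebee foragers, measured from raw
flower-visit logs with bipartite network statistics — plus a flight-cage
simulator so every estimator can be validated against known ground truth.

## What it does

When several foragers from one colony exploit a shared array of renewable
nectar sources, do they divide it up? `beepartite` answers this from a
time-stamped visit log (one row per landing of a tagged bee on a flower):

- **Bout segmentation and eight-bout bins.** Visits are grouped into
  foraging bouts (nest round trips) and each day is cut into intervals
  closing when the fastest bee completes 8 bouts; each interval yields a
  flowers × bees visit-count matrix.
- **Weighted bipartite modularity.** For matrix A (row sums k, column sums
  d, total F) and a joint partition of flowers and bees, Barber's
  Q = (1/F) Σᵢⱼ (Aᵢⱼ − kᵢdⱼ/F)·1[gᵢ=hⱼ] measures how strongly bees split
  into flower-sharing modules. Q is maximized by seeded weighted label
  propagation with multi-start (LPAwb+/DIRTLPAwb+-style), anchored in tests
  by an exhaustive-search oracle on small matrices.
- **Fixed-margins null significance.** Observed Q is standardized against
  100 Patefield-sampled random tables with the same row/column totals; a
  network is significantly modular when z > 2.
- **Individual metrics and models.** Per bee and bin: activity (visits),
  experience (cumulative prior visits) and flower specificity (normalized
  CV of the visit distribution, 0 = uses all flowers evenly, 1 = single
  flower), modelled with a random-intercept LMM; per-bin modularity is
  regressed on mean activity/experience and bee count.
- **Persistence.** How often each bee shares a module with each flower
  across bins, chi-square-tested per bee against a uniform spread.
- **Encounters on flowers.** Two-bee encounters are classified (resident
  stays/leaves × reward consumed/not, with the strict >8-s feeding rule)
  and modelled: a binomial GLMM for replacement probability and a Poisson
  GLMM for next-bout revisits to the contested flower, both with crossed
  random intercepts for the two bees.
- **Synthetic data.** A planted-module log sampler and a spatially
  explicit, event-driven flight-cage simulation (decagon array, 40-µL cups
  refilling at 3.3 µL/min, crop-limited bouts, displacement interactions)
  with exact per-flower nectar accounting.

See `docs/methods.md` for the full model descriptions and design choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (seed 1):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_segment_and_bin.py
python analysis/03_network_modularity.py --seed 1
python analysis/04_foraging_metrics.py
python analysis/05_persistence.py
python analysis/06_interaction_models.py
```

Script 01 simulates five 6-hour days of ten foragers on ten flowers and
prints:

```
simulated 5 days, 10 bees, 10 flowers (seed 1)
  9353 flower visits in 948 bouts
  3.94 unique flowers per bout on average
  341 two-bee encounters on flowers
  nectar ledger residual: 1.93e-12 uL
```

— crop-limited bouts touch ~4 distinct flowers, and the per-flower nectar
ledger (initial + secreted = consumed + standing) closes to floating-point
precision. Scripts 02–03 build 17 eight-bout networks and test each against
its fixed-margins null:

```
948 foraging bouts -> 17 eight-bout bins
17 networks; Q range 0.389-0.441
17 of 17 networks more modular than the fixed-margins null (z > 2)
```

With the simulator's module fidelity at its default 0.9, every network is
significantly modular — the planted resource partitioning is detected in
every bin. Script 04 fits the specificity LMM:

```
term                            estimate          SE         t           p
Intercept                         0.3906      0.0132    29.701  7.502e-194
activity                         -0.0010      0.0002    -5.717   1.083e-08
```

— bees that visit more within a bin spread over more flowers, so their
specificity falls (the negative activity slope). Script 05 finds all ten
simulated bees keep significantly persistent flower associations, and
script 06 classifies the 341 encounters into the four outcome × reward
classes and fits both mixed models; the revisit model recovers the planted
"avoid flowers you were displaced from" rule as a strong positive `won`
coefficient (β = 0.85, z = 9.4).

The same pipeline runs on a real visit log with one call:

```bash
beepartite run --visits visits.csv --seed 1 --out-dir results/run
```

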