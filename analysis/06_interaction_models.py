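"""Encounter outcomes and their carry-over into the next foraging bout.

Classifies every two-bee encounter (resident stays / leaves x consumed /
not consumed), fits the binomial mixed model of replacement probability,
and the Poisson mixed model of next-bout revisits to the contested flower.

Reads results/data/ (visits + interactions) and results/models/metrics.csv;
writes model summaries under results/models/.

Usage: python analysis/06_interaction_models.py
"""

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd

from beepartite import bin_by_bouts, filter_motivated, read_visit_log, segment_bouts
from beepartite.interactions import (
    build_interaction_table,
    build_revisit_table,
    classify_interaction,
    fit_replacement_model,
    fit_revisit_model,
    read_interaction_log,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--metrics", default="results/models/metrics.csv")
    ap.add_argument("--out-dir", default="results/models")
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events = read_interaction_log(Path(args.data) / "interactions.csv")
    classified = [classify_interaction(e) for e in events]
    counts = Counter((c.outcome, c.reward_status) for c in classified)
    print(f"{len(events)} two-bee encounters:")
    for (outcome, status), n in sorted(counts.items()):
        print(f"  {outcome:16s} {status:13s} {n}")

    log = filter_motivated(read_visit_log(Path(args.data) / "visits.csv"))
    bouts = segment_bouts(log)
    bins = bin_by_bouts(bouts)
    metrics = pd.read_csv(args.metrics)
    table = build_interaction_table(classified, metrics=metrics, bins=bins)
    table.to_csv(out / "interaction_table.csv", index=False)
    print(f"{len(table)} contact encounters enter the replacement model")

    try:
        rep = fit_replacement_model(table)
        rep.to_json(out / "replacement_glmm.json")
        print("\nP(joiner replaces resident) ~ reward status + timing (crossed bee intercepts):")
        print(rep.summary())
    except ValueError as err:
        print(f"replacement model not fitted: {err}")

    revisit = build_revisit_table(classified, bouts)
    revisit.to_csv(out / "revisit_table.csv", index=False)
    try:
        rv = fit_revisit_model(revisit)
        rv.to_json(out / "revisit_glmm.json")
        print("\nnext-bout visits to the contested flower ~ outcome x reward status:")
        print(rv.summary())
    except ValueError as err:
        print(f"revisit model not fitted: {err}")
    print(f"\nwrote interaction tables and model summaries -> {out}")


if __name__ == "__main__":
    main()
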