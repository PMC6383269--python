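"""Segment bouts, apply the motivated-bee filter, and build the
eight-bout-bin visitation matrices.

Reads results/data/visits.csv; writes one TSV matrix per bin plus a bin
summary under results/networks/.

Usage: python analysis/02_segment_and_bin.py
"""

import argparse
from pathlib import Path

import pandas as pd

from beepartite import (
    bin_by_bouts,
    build_visitation_matrix,
    filter_motivated,
    read_visit_log,
    segment_bouts,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--visits", default="results/data/visits.csv")
    ap.add_argument("--out-dir", default="results/networks")
    ap.add_argument("--min-visits", type=int, default=21)
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = read_visit_log(args.visits)
    print(f"{len(log)} visits by {len(log.bees)} bees")
    motivated = filter_motivated(log, min_visits=args.min_visits)
    print(f"motivated filter (> {args.min_visits - 1} visits): kept {len(motivated.bees)} bees, {len(motivated)} visits")

    bouts = segment_bouts(motivated)
    bins = bin_by_bouts(bouts)
    print(f"{len(bouts)} foraging bouts -> {len(bins)} eight-bout bins")

    rows = []
    for b in bins:
        m = build_visitation_matrix(b, motivated.flowers)
        m.to_tsv(out / f"matrix_bin{b.index:02d}.tsv")
        rows.append(
            {
                "bin_index": b.index, "day": b.day, "t_start": b.t_start, "t_end": b.t_end,
                "n_bees": m.n_bees, "n_visits": m.total,
                "merged_tail": b.merged_tail, "whole_day": b.whole_day,
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "bins.csv", index=False)
    print(f"mean bees active per bin: {summary['n_bees'].mean():.2f}")
    print(f"matrix totals sum to {summary['n_visits'].sum()} (= retained visits: {summary['n_visits'].sum() == len(motivated)})")
    print(f"wrote {len(bins)} matrices and bins.csv -> {out}")


if __name__ == "__main__":
    main()
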