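"""Persistence of bee-flower associations across the bins.

Counts, for every bee, how often each flower shared its module across the
bins, and chi-square-tests each bee's counts against a uniform spread.

Reads results/networks/ (matrices + modules.json); writes associations.csv
and persistence.csv under results/persistence/.

Usage: python analysis/05_persistence.py
"""

import argparse
import json
from pathlib import Path

import numpy as np

from beepartite import association_counts, persistence_table
from beepartite.modularity import BipartitePartition
from beepartite.visitlog import VisitationMatrix


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--networks", default="results/networks")
    ap.add_argument("--out-dir", default="results/persistence")
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    modules = json.loads((Path(args.networks) / "modules.json").read_text())
    pairs = []
    for path in sorted(Path(args.networks).glob("matrix_bin*.tsv")):
        k = str(int(path.stem.replace("matrix_bin", "")))
        m = VisitationMatrix.from_tsv(path)
        labels = modules[k]
        part = BipartitePartition(
            np.array([labels["flowers"][f] for f in m.row_labels]),
            np.array([labels["bees"][b] for b in m.col_labels]),
            float("nan"),
        )
        pairs.append((m, part))

    assoc = association_counts(pairs)
    assoc.counts.to_csv(out / "associations.csv")
    table = persistence_table(assoc)
    table.to_csv(out / "persistence.csv", index=False)

    n_sig = int(table["significant"].sum())
    print(f"association counts over {len(pairs)} networks for {len(assoc.bees)} bees")
    print(f"{n_sig} of {len(table)} bees keep significantly persistent flower associations (chi-square, p < 0.05)")
    print(f"wrote associations.csv and persistence.csv -> {out}")


if __name__ == "__main__":
    main()
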