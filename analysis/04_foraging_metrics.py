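"""Per-bee activity, experience and flower specificity; the specificity
mixed model; the modularity regression.

Reads results/networks/ (matrices + modularity.csv); writes metrics.csv and
the two model summaries under results/models/.

Usage: python analysis/04_foraging_metrics.py
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from beepartite import compute_metrics, fit_modularity_lm, fit_specificity_lmm, variance_inflation
from beepartite.visitlog import VisitationMatrix


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--networks", default="results/networks")
    ap.add_argument("--out-dir", default="results/models")
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices = [VisitationMatrix.from_tsv(p) for p in sorted(Path(args.networks).glob("matrix_bin*.tsv"))]
    for p, m in zip(sorted(Path(args.networks).glob("matrix_bin*.tsv")), matrices):
        m.bin_index = int(p.stem.replace("matrix_bin", ""))
    metrics = compute_metrics(matrices)
    metrics.to_csv(out / "metrics.csv", index=False)
    print(f"{len(metrics)} bee-bin rows across {metrics['bin_index'].nunique()} bins")

    rho = np.corrcoef(metrics["activity"], metrics["experience"])[0, 1]
    vif = variance_inflation(metrics[["activity", "experience"]])
    print(f"activity-experience correlation rho = {rho:.2f}; VIF = {vif['vif'].iloc[0]:.2f} (keep both: {not vif['flagged'].any()})")

    lmm = fit_specificity_lmm(metrics)
    lmm.to_json(out / "specificity_lmm.json")
    print("\nflower specificity ~ activity + experience + (1 | bee):")
    print(lmm.summary())

    mod = pd.read_csv(Path(args.networks) / "modularity.csv")
    summaries = pd.DataFrame(
        {
            "bin_index": mod["bin_index"],
            "modularity": mod["Q_obs"],
            "mean_activity": [metrics[metrics.bin_index == k]["activity"].mean() for k in mod["bin_index"]],
            "mean_experience": [metrics[metrics.bin_index == k]["experience"].mean() for k in mod["bin_index"]],
            "n_bees": mod["n_bees"],
        }
    )
    lm = fit_modularity_lm(summaries)
    lm.to_json(out / "modularity_lm.json")
    print("\nmodularity ~ mean activity + mean experience + n bees:")
    print(lm.summary())
    print(f"\nwrote metrics.csv and model summaries -> {out}")


if __name__ == "__main__":
    main()
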