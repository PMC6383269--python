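"""Persistence of bee-flower associations across bins.

For each bin's module partition, a bee is "associated" with every flower
sharing its module label. Counting those co-memberships across all bins
gives a bee x flower association table; a bee whose counts depart from a
uniform spread over the declared flowers (goodness-of-fit chi-square) is
using a persistently structured subset of flowers. Counting co-membership
directly sidesteps the need to align module labels across bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .modularity import BipartitePartition
from .visitlog import VisitationMatrix

__all__ = ["AssociationCounts", "association_counts", "persistence_chisq", "persistence_table"]

MIN_BINS_FOR_TEST = 2


@dataclass
class AssociationCounts:
    """Bee x flower co-membership counts across bins."""

    counts: pd.DataFrame  # index bees, columns flowers
    n_bins_present: pd.Series  # per bee

    @property
    def bees(self) -> list[str]:
        return list(self.counts.index)

    @property
    def flowers(self) -> list[str]:
        return list(self.counts.columns)


def association_counts(
    partitions: list[tuple[VisitationMatrix, BipartitePartition]],
    flower_set=None,
) -> AssociationCounts:
    """Count, for every bee, how many bins placed it in the same module as
    each flower.

    ``partitions`` pairs each bin's matrix (carrying the labels) with its
    module partition. Every bin where the bee appears increments the count
    of all flowers sharing its module label in that bin.
    """
    if not partitions:
        raise ValueError("no partitions supplied")
    if flower_set is None:
        flower_set = partitions[0][0].row_labels
    flowers = [str(f) for f in flower_set]
    bees = sorted({b for m, _ in partitions for b in m.col_labels})
    counts = pd.DataFrame(0, index=bees, columns=flowers)
    present = pd.Series(0, index=bees)
    for m, part in partitions:
        for j, bee in enumerate(m.col_labels):
            present[bee] += 1
            lab = part.col_modules[j]
            for i, fl in enumerate(m.row_labels):
                if part.row_modules[i] == lab:
                    counts.loc[bee, fl] += 1
    empty = present.index[present == 0]
    if len(empty):
        warnings.warn(f"bee(s) absent from all bins: {list(empty)}")
    return AssociationCounts(counts, present)


def persistence_chisq(assoc: AssociationCounts, bee: str) -> tuple[float, float, int, bool]:
    """Goodness-of-fit chi-square of one bee's flower-association counts
    against a uniform expectation over the declared flowers.

    Returns ``(statistic, p_value, df, small_expected_flag)``; the flag is
    raised when any expected cell count falls below 1 (the test is still
    computed).
    """
    obs = assoc.counts.loc[bee].to_numpy(dtype=float)
    total = obs.sum()
    if total <= 0:
        raise ValueError(f"bee {bee!r} has no associations")
    expected = np.full(len(obs), total / len(obs))
    flag = bool((expected < 1).any())
    if flag:
        warnings.warn(f"bee {bee!r}: expected cell count < 1; chi-square approximation is weak")
    stat, p = stats.chisquare(obs, expected)
    return float(stat), float(p), len(obs) - 1, flag


def persistence_table(assoc: AssociationCounts, alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square results for every testable bee (present in >= 2 bins)."""
    rows = []
    for bee in assoc.bees:
        if assoc.n_bins_present[bee] < MIN_BINS_FOR_TEST:
            warnings.warn(f"bee {bee!r} present in < {MIN_BINS_FOR_TEST} bins; excluded from test roster")
            continue
        stat, p, df, flag = persistence_chisq(assoc, bee)
        rows.append(
            {
                "bee_id": bee,
                "statistic": stat,
                "df": df,
                "p": p,
                "significant": p < alpha,
                "small_expected": flag,
                "n_bins_present": int(assoc.n_bins_present[bee]),
            }
        )
    return pd.DataFrame(rows)
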