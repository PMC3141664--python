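"""Agreement statistics between replicate expression measurements.

Correlation between replicates is nearly always high in RNA-seq and says
little about *agreement* — whether two lanes assign a region the same
expression level.  This module quantifies agreement directly: expression is
binned onto an ordinal scale and replicates are cross-tabulated, then
summarized by simple agreement, Cohen's kappa (chance-corrected), and
weighted kappa (penalizing disagreements by ordinal distance).

Two binning schemes are provided:

* three levels — undetected (0) / low-medium (1) / high (2), where high is
  RPKM > 20;
* nine levels — undetected (0, zero reads), then RPKM in [0,10), [10,20),
  [20,40), [40,80), [80,160), [160,320), [320,1000), [1000, inf) as
  categories 1..8.

A published 9x9 cross-classification of 60,277 D. melanogaster exonic
regions between two technical replicate lanes (female heads, biological
replicate 2) ships as a data fixture for tests and worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

NINE_LEVEL_BOUNDS = (10.0, 20.0, 40.0, 80.0, 160.0, 320.0, 1000.0)
THREE_LEVEL_HIGH_RPKM = 20.0


@dataclass(frozen=True)
class ContingencyTable:
    """k x k cross-classification; rows = replicate A, columns = replicate B."""

    counts: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(str(i) for i in range(counts.shape[0]))
            )

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T, self.labels)

    def collapse_detection(self) -> "ContingencyTable":
        """Collapse to 2x2 detected/undetected: category 0 vs the rest."""
        c = self.counts
        collapsed = np.array(
            [
                [c[0, 0], c[0, 1:].sum()],
                [c[1:, 0].sum(), c[1:, 1:].sum()],
            ]
        )
        return ContingencyTable(collapsed, ("undetected", "detected"))


@dataclass(frozen=True)
class ComparisonReport:
    """Pairwise replicate agreement summary (one table row per lane pair)."""

    pair: tuple[str, str]
    n_common: int
    n_only_one: int
    kappa_detection: float
    kappa_3level: float
    kappa_3level_weighted: float
    kappa_9level_weighted: float
    n_disagree_ge1log: int
    n_disagree_gt2log: int


def bin_rpkm(
    rpkm_value: float, detected: bool, scheme: str = "nine"
) -> int:
    """Ordinal expression category for one region in one lane.

    Category 0 is driven by the detection flag (zero reads), not by a
    rounded RPKM of 0.  Nine-level bins are half-open [lower, upper), so a
    detected region with RPKM exactly 20 falls in category 3.
    """
    if rpkm_value < 0:
        raise ValueError("rpkm must be non-negative")
    if not detected:
        return 0
    if scheme == "three":
        return 2 if rpkm_value > THREE_LEVEL_HIGH_RPKM else 1
    if scheme == "nine":
        return 1 + int(np.searchsorted(NINE_LEVEL_BOUNDS, rpkm_value, side="right"))
    raise ValueError(f"unknown binning scheme: {scheme!r}")


def bin_rpkm_series(
    rpkm_values: Sequence[float],
    detected: Sequence[bool],
    scheme: str = "nine",
) -> np.ndarray:
    """Vectorized :func:`bin_rpkm`."""
    r = np.asarray(rpkm_values, dtype=float)
    d = np.asarray(detected, dtype=bool)
    if (r < 0).any():
        raise ValueError("rpkm must be non-negative")
    if scheme == "three":
        cats = np.where(r > THREE_LEVEL_HIGH_RPKM, 2, 1)
    elif scheme == "nine":
        cats = 1 + np.searchsorted(NINE_LEVEL_BOUNDS, r, side="right")
    else:
        raise ValueError(f"unknown binning scheme: {scheme!r}")
    return np.where(d, cats, 0)


def contingency_table(
    categories_a: Sequence[int], categories_b: Sequence[int], k: int
) -> ContingencyTable:
    """Cross-tabulate two equal-length ordinal category sequences."""
    a = np.asarray(categories_a, dtype=np.int64)
    b = np.asarray(categories_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("category sequences must have equal length")
    if a.size == 0:
        raise ValueError("empty category sequences (N must be > 0)")
    if ((a < 0) | (a >= k) | (b < 0) | (b >= k)).any():
        raise ValueError(f"categories must lie in 0..{k - 1}")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    return ContingencyTable(counts)


def simple_agreement(table: ContingencyTable) -> float:
    """Proportion of observations on the diagonal (same category)."""
    if table.n == 0:
        raise ValueError("empty table")
    return float(np.trace(table.counts) / table.n)


def cohens_kappa(table: ContingencyTable) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    n = table.n
    if n == 0:
        raise ValueError("empty table")
    p_o = simple_agreement(table)
    p_e = float(table.row_margins @ table.col_margins) / (n * n)
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def _disagreement_weights(k: int, weights: str) -> np.ndarray:
    i, j = np.indices((k, k))
    d = np.abs(i - j) / (k - 1)
    if weights == "linear":
        return d
    if weights == "quadratic":
        return d**2
    raise ValueError(f"unknown weights: {weights!r}")


def weighted_kappa(table: ContingencyTable, weights: str = "linear") -> float:
    """Kappa with ordinal-distance disagreement weights.

    Disagreement weights d_ij = |i-j|/(k-1) (linear, Cicchetti-Allison;
    the default) or its square (quadratic, Fleiss-Cohen):
    kappa_w = 1 - observed weighted disagreement / expected weighted
    disagreement under independent margins.
    """
    if table.k < 2:
        raise ValueError("weighted kappa needs k >= 2")
    n = table.n
    if n == 0:
        raise ValueError("empty table")
    d = _disagreement_weights(table.k, weights)
    observed = float((table.counts * d).sum()) / n
    expected = float(
        (np.outer(table.row_margins, table.col_margins) * d).sum()
    ) / (n * n)
    if expected == 0.0:
        if observed == 0.0:
            return 1.0
        raise ValueError("weighted kappa undefined: expected disagreement is 0")
    return 1.0 - observed / expected


def detection_comparison(
    detected_a: Sequence[bool], detected_b: Sequence[bool]
) -> tuple[ContingencyTable, int, int]:
    """2x2 detected/undetected cross-tab plus (n_common, n_only_one).

    ``n_common`` is the both-detected cell; ``n_only_one`` the off-diagonal
    sum (regions detected in exactly one replicate).
    """
    a = np.asarray(detected_a, dtype=bool)
    b = np.asarray(detected_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("replicates cover different region sets")
    table = contingency_table(a.astype(int), b.astype(int), k=2)
    table = ContingencyTable(table.counts, ("undetected", "detected"))
    n_common = int(table.counts[1, 1])
    n_only_one = int(table.counts[0, 1] + table.counts[1, 0])
    return table, n_common, n_only_one


def log_disagreement_counts(
    rpkm_a: Sequence[float],
    rpkm_b: Sequence[float],
    log_base: float = np.e,
    thresholds: Sequence[float] = (1.0, 2.0),
) -> dict[str, int | dict[float, int]]:
    """Count pairs whose log-scale expression estimates disagree.

    Only pairs with non-zero values in both replicates enter the log
    comparison; zero-in-either pairs are excluded and reported separately.
    The first threshold is inclusive (disagreement of t *or more*), later
    thresholds strict (*greater than* t), matching the usual "1 log or
    more" / "greater than 2 logs" phrasing.
    """
    a = np.asarray(rpkm_a, dtype=float)
    b = np.asarray(rpkm_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("rpkm must be non-negative")
    if log_base <= 1:
        raise ValueError("log_base must be > 1")
    both = (a > 0) & (b > 0)
    diff = np.abs(np.log(a[both]) - np.log(b[both])) / np.log(log_base)
    counts: dict[float, int] = {}
    for idx, t in enumerate(thresholds):
        counts[t] = int((diff >= t).sum()) if idx == 0 else int((diff > t).sum())
    return {
        "counts": counts,
        "n_used": int(both.sum()),
        "n_excluded_zero": int((~both).sum()),
    }


def compare_replicates(
    quants: pd.DataFrame,
    lane_a: str,
    lane_b: str,
    log_base: float = np.e,
) -> ComparisonReport:
    """Full pairwise agreement summary from a quantitation grid.

    ``quants`` is the region x lane DataFrame from
    :func:`techvar.quantitation.quantify_experiment`.
    """
    qa = quants[quants.lane_id == lane_a].set_index("region_id").sort_index()
    qb = quants[quants.lane_id == lane_b].set_index("region_id").sort_index()
    if not qa.index.equals(qb.index):
        raise ValueError("replicates cover different region sets")
    det_table, n_common, n_only_one = detection_comparison(
        qa.detected.to_numpy(), qb.detected.to_numpy()
    )
    cats9_a = bin_rpkm_series(qa.rpkm, qa.detected, "nine")
    cats9_b = bin_rpkm_series(qb.rpkm, qb.detected, "nine")
    cats3_a = bin_rpkm_series(qa.rpkm, qa.detected, "three")
    cats3_b = bin_rpkm_series(qb.rpkm, qb.detected, "three")
    table9 = contingency_table(cats9_a, cats9_b, 9)
    table3 = contingency_table(cats3_a, cats3_b, 3)
    logs = log_disagreement_counts(
        qa.rpkm.to_numpy(), qb.rpkm.to_numpy(), log_base=log_base
    )
    return ComparisonReport(
        pair=(lane_a, lane_b),
        n_common=n_common,
        n_only_one=n_only_one,
        kappa_detection=cohens_kappa(det_table),
        kappa_3level=cohens_kappa(table3),
        kappa_3level_weighted=weighted_kappa(table3, "linear"),
        kappa_9level_weighted=weighted_kappa(table9, "linear"),
        n_disagree_ge1log=logs["counts"][1.0],
        n_disagree_gt2log=logs["counts"][2.0],
    )


def load_reference_agreement_table() -> ContingencyTable:
    """Published 9x9 replicate cross-classification shipped with the package.

    60,277 D. melanogaster female-head exonic regions (biological
    replicate 2) classified on the nine-level RPKM scale in each of two
    technical replicate lanes.
    """
    ref = resources.files("techvar.data").joinpath(
        "dmel_female_heads_br2_tr1_tr2_9x9.tsv"
    )
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return ContingencyTable(df.to_numpy(), tuple(df.columns))
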