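"""Replicate mutual information on categorical repair outcomes.

Reporter-intrinsic biases are tested by asking whether knowing how a barcode
was repaired in one replicate predicts its outcome in another.  Barcodes
seen in at least two replicates are assigned a single majority outcome per
replicate; every unordered replicate pair contributes one (symmetrized)
count to a 2x2 contingency table, from which the plug-in mutual information
is computed in bits.  Independent outcomes give 0 bits, clonal outcomes with
balanced alleles approach the 1-bit maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

OUTCOMES = ("top", "bottom")


@dataclass
class ContingencyTable2x2:
    """Counts ``n[x][y]`` for x, y in {top, bottom}; symmetrized by construction."""

    counts: np.ndarray  # shape (2, 2), float (symmetrization halves counts)

    @classmethod
    def zeros(cls) -> "ContingencyTable2x2":
        return cls(np.zeros((2, 2)))

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def margins(self) -> tuple[np.ndarray, np.ndarray]:
        return self.counts.sum(axis=1), self.counts.sum(axis=0)

    def add_pair(self, x: str, y: str, weight: float = 1.0) -> None:
        i, j = OUTCOMES.index(x), OUTCOMES.index(y)
        # Half to (x, y) and half to (y, x): replicate order is arbitrary.
        self.counts[i, j] += weight / 2.0
        self.counts[j, i] += weight / 2.0


def majority_outcome(umi_votes: dict[str, int], min_umis: int = 5) -> str | None:
    """Majority allele of one barcode, or None if below the UMI floor or tied.

    ``umi_votes`` maps "top"/"bottom" to UMI counts.  Barcodes with fewer
    than ``min_umis`` allele-reporting UMIs are excluded, as are exact ties
    (excluding rather than randomizing keeps the statistic deterministic).
    """
    n_top = umi_votes.get("top", 0)
    n_bottom = umi_votes.get("bottom", 0)
    if n_top + n_bottom < min_umis or n_top == n_bottom:
        return None
    return "top" if n_top > n_bottom else "bottom"


def pairwise_table(
    outcomes_by_barcode: dict[str, dict[str, str]]
) -> ContingencyTable2x2:
    """Fill the replicate-pair table from per-barcode, per-replicate outcomes.

    ``outcomes_by_barcode[barcode][replicate]`` is "top" or "bottom".  Every
    unordered pair of replicates in which a barcode appears contributes one
    count, split evenly between the two orientations.
    """
    table = ContingencyTable2x2.zeros()
    n_pairs = 0
    for outcomes in outcomes_by_barcode.values():
        reps = sorted(outcomes)
        for r1, r2 in combinations(reps, 2):
            table.add_pair(outcomes[r1], outcomes[r2])
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no barcode appears in at least two replicates")
    return table


def mutual_information(table: ContingencyTable2x2) -> float:
    """Plug-in mutual information of the table, in bits (0*log0 = 0)."""
    n = table.total
    if n <= 0:
        raise ValueError("empty contingency table")
    p = table.counts / n
    px, py = p.sum(axis=1), p.sum(axis=0)
    mi = 0.0
    for i in range(2):
        for j in range(2):
            if p[i, j] > 0:
                mi += p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
    # Clip the tiny negative round-off that the plug-in form can produce.
    return float(max(mi, 0.0))
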