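"""Data cleansing: drop near-constant and strongly correlated attributes.

Attributes with sample standard deviation <= 0.1 are removed first; among
the survivors, any pair with |Pearson r| > 0.9 loses the attribute that
comes later in inventory order (greedy, left to right).  The surviving
table is the Final Clean Dataset (FCD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AttributeTable


@dataclass
class CleanseReport:
    removed_low_sd: list[str] = field(default_factory=list)
    removed_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    table: AttributeTable | None = None  # the FCD

    @property
    def removed(self) -> set[str]:
        return set(self.removed_low_sd) | {d for _, d, _ in self.removed_correlated}


def clean_low_sd(table: AttributeTable, threshold: float = 0.1) -> CleanseReport:
    """Drop attributes whose sample (n-1) SD is <= ``threshold``."""
    if table.data.shape[0] < 2:
        raise ValueError("cleansing needs at least two rows")
    sd = table.data.std(axis=0, ddof=1)
    removed = [a for a in table.attributes if sd[a] <= threshold]
    if len(removed) == len(table.attributes):
        raise ValueError("all attributes removed by the SD rule; degenerate dataset")
    kept = [a for a in table.attributes if sd[a] > threshold]
    return CleanseReport(removed_low_sd=removed, table=table.subset(kept))


def clean_correlated(table: AttributeTable, threshold: float = 0.9) -> CleanseReport:
    """Greedy left-to-right removal of |r| > ``threshold`` attribute pairs.

    An attribute is kept iff its absolute Pearson correlation with every
    previously kept attribute is <= threshold; the report records, for
    each dropped attribute, the kept attribute that triggered the drop.
    """
    cols = table.attributes
    X = table.data.to_numpy(dtype=float)
    corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    kept_idx: list[int] = []
    removed: list[tuple[str, str, float]] = []
    for j in range(len(cols)):
        hit = None
        for i in kept_idx:
            if abs(corr[i, j]) > threshold:
                hit = i
                break
        if hit is None:
            kept_idx.append(j)
        else:
            removed.append((cols[hit], cols[j], float(corr[hit, j])))
    return CleanseReport(
        removed_correlated=removed, table=table.subset([cols[i] for i in kept_idx])
    )


def cleanse(
    table: AttributeTable, sd_threshold: float = 0.1, correlation_threshold: float = 0.9
) -> CleanseReport:
    """Apply both rules in order and return the combined report (FCD)."""
    step1 = clean_low_sd(table, sd_threshold)
    step2 = clean_correlated(step1.table, correlation_threshold)
    fcd = step2.table
    fcd.provenance["dataset"] = "fcd"
    return CleanseReport(
        removed_low_sd=step1.removed_low_sd,
        removed_correlated=step2.removed_correlated,
        table=fcd,
    )
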