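"""Low-expression filtering, RPM scaling, log2 transform and quantile normalization.

The stage order is fixed: filter on RAW counts, then reads-per-million,
then log2(x + pseudocount), then quantile normalization across samples.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .data_io import CountTable, DataError, FLOAT_FORMAT, _read_design

log = logging.getLogger("mitoskew")

#: how the low-expression rule combines the two group means
FILTER_RULES = ("both-groups-below", "overall-mean-below")


@dataclass
class NormalizedTable:
    """Gene-by-sample log2 quantile-normalized reads-per-million values."""

    values: pd.DataFrame                 # genes x samples, float
    groups: pd.Series                    # sample_id -> group label
    group_levels: tuple[str, str]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, level: str) -> list[str]:
        return list(self.groups.index[self.groups == level])


def filter_low_expression(
    table: CountTable,
    threshold: float = 10.0,
    rule: str = "both-groups-below",
) -> tuple[CountTable, int]:
    """Drop genes whose mean raw count falls below ``threshold``.

    Under the default rule a gene is removed iff its mean raw count is
    strictly below the threshold in BOTH groups, so genes expressed in only
    one group survive.  ``overall-mean-below`` instead drops on the pooled
    mean across all samples.  Returns the filtered table and the number of
    genes removed.
    """
    if threshold < 0:
        raise DataError("threshold must be nonnegative")
    if rule not in FILTER_RULES:
        raise DataError(f"unknown filter rule {rule!r}; choose from {FILTER_RULES}")
    a, b = table.group_levels
    mean_a = table.counts[table.samples_in(a)].mean(axis=1)
    mean_b = table.counts[table.samples_in(b)].mean(axis=1)
    if rule == "both-groups-below":
        removed = (mean_a < threshold) & (mean_b < threshold)
    else:
        removed = table.counts.mean(axis=1) < threshold
    kept = table.counts.loc[~removed]
    n_removed = int(removed.sum())
    log.info("filter_low_expression: removed %d of %d genes (threshold %g, %s)",
             n_removed, len(table.gene_ids), threshold, rule)
    return (
        CountTable(counts=kept, groups=table.groups.copy(),
                   group_levels=table.group_levels),
        n_removed,
    )


def compute_rpm(table: CountTable) -> pd.DataFrame:
    """Scale each sample to reads per million: count / sample total * 1e6."""
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise DataError(f"sample(s) with zero total count: {zero}")
    return table.counts / totals * 1.0e6


def log2_transform(rpm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(rpm + pseudocount); with the default pseudocount a zero stays 0."""
    if pseudocount <= 0:
        raise DataError("pseudocount must be > 0")
    if (rpm.to_numpy() < 0).any():
        raise DataError("RPM values must be nonnegative")
    return np.log2(rpm + pseudocount)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Classic rank-mean quantile normalization across columns.

    The reference distribution is the per-rank mean of the sorted columns;
    each value is replaced by the reference entry at its rank.  Values tied
    within a column receive the mean of the reference entries across their
    tied rank span, so the procedure is exactly idempotent.
    """
    if values.isna().any().any():
        raise DataError("quantile normalization requires a complete matrix")
    arr = values.to_numpy(dtype=float)
    n, m = arr.shape
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(m):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = reference
        # average the reference over tied spans
        out[:, j] = (
            pd.Series(assigned).groupby(pd.Series(col), sort=False).transform("mean")
        ).to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_counts(
    table: CountTable,
    threshold: float = 10.0,
    pseudocount: float = 1.0,
    rule: str = "both-groups-below",
) -> tuple[NormalizedTable, int]:
    """Full normalization pipeline: filter -> RPM -> log2 -> quantile normalize."""
    filtered, n_removed = filter_low_expression(table, threshold, rule)
    rpm = compute_rpm(filtered)
    logged = log2_transform(rpm, pseudocount)
    norm = quantile_normalize(logged)
    return (
        NormalizedTable(values=norm, groups=filtered.groups,
                        group_levels=filtered.group_levels),
        n_removed,
    )


def write_normalized_table(norm: NormalizedTable, path: Union[str, Path]) -> None:
    norm.values.rename_axis("gene_id").to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_normalized_table(path: Union[str, Path],
                          design_path: Union[str, Path]) -> NormalizedTable:
    values = pd.read_csv(path, sep="\t", index_col=0)
    groups, levels = _read_design(design_path)
    missing = set(values.columns) ^ set(groups.index)
    if missing:
        raise DataError(f"normalized table and design disagree on samples: {sorted(missing)}")
    return NormalizedTable(values=values[groups.index.tolist()],
                           groups=groups, group_levels=levels)
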