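"""Validated containers and TSV readers/writers for the pipeline's on-disk artifacts.

All tabular artifacts are plain tab-separated UTF-8 text with a mandatory
header row and no quoting, so that repeated runs diff byte-for-byte.
Tables are canonically ordered on construction: genes lexicographic,
samples grouped by group label (group A first) then lexicographic.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

log = logging.getLogger("mitoskew")

#: float rendering used by every writer: >= 6 significant digits, stable.
FLOAT_FORMAT = "%.10g"


class DataError(ValueError):
    """An on-disk artifact or in-memory table violates its contract."""


class ConfigError(ValueError):
    """A pipeline configuration is invalid before any compute starts."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Gene-by-sample raw read counts plus a two-level group design.

    ``group_levels`` fixes the contrast orientation: the first level is
    "group A" (e.g. the selected broiler line in a PeM-vs-BPR contrast)
    and all downstream differences are A minus B.
    """

    counts: pd.DataFrame                 # genes x samples, nonnegative ints
    groups: pd.Series                    # sample_id -> group label
    group_levels: tuple[str, str]        # (group A, group B)

    def __post_init__(self) -> None:
        counts, groups = self.counts, self.groups
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        if dup:
            raise DataError(f"duplicate gene id(s): {', '.join(map(str, dup))}")
        if counts.isna().any().any():
            gene, sample = _first_offender(counts.isna())
            raise DataError(f"missing count at gene {gene!r}, sample {sample!r}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac = counts != np.floor(counts)
            if frac.any().any():
                gene, sample = _first_offender(frac)
                raise DataError(
                    f"non-integer count at gene {gene!r}, sample {sample!r}"
                )
            counts = counts.astype(np.int64)
        if (counts < 0).any().any():
            gene, sample = _first_offender(counts < 0)
            raise DataError(f"negative count at gene {gene!r}, sample {sample!r}")

        if len(self.group_levels) != 2 or self.group_levels[0] == self.group_levels[1]:
            raise DataError(f"exactly two distinct group labels required, got {self.group_levels}")
        missing = set(counts.columns) - set(groups.index)
        if missing:
            raise DataError(f"sample(s) in counts missing from design: {sorted(missing)}")
        extra = set(groups.index) - set(counts.columns)
        if extra:
            raise DataError(f"sample(s) in design missing from counts: {sorted(extra)}")
        unknown = set(groups.unique()) - set(self.group_levels)
        if unknown:
            raise DataError(f"unknown group label(s): {sorted(unknown)}")
        for level in self.group_levels:
            n = int((groups == level).sum())
            if n < 2:
                raise DataError(f"group {level!r} has {n} sample(s); >= 2 required")

        # canonical ordering: genes lexicographic; samples by (group, id)
        level_rank = {g: i for i, g in enumerate(self.group_levels)}
        sample_order = sorted(counts.columns, key=lambda s: (level_rank[groups[s]], s))
        self.counts = counts.loc[sorted(counts.index), sample_order]
        self.counts.index.name = "gene_id"
        self.groups = groups.loc[sample_order]
        self.groups.name = "group"
        self.groups.index.name = "sample_id"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, level: str) -> list[str]:
        return list(self.groups.index[self.groups == level])


def _first_offender(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    gene, sample = stacked[stacked].index[0]
    return str(gene), str(sample)


def _read_design(design_path: Union[str, Path]) -> tuple[pd.Series, tuple[str, str]]:
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in design.columns:
            raise DataError(f"design file {design_path} lacks required column {col!r}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"duplicate sample id(s) in design: {dup}")
    groups = pd.Series(design["group"].values, index=design["sample_id"].values)
    levels = list(dict.fromkeys(design["group"]))  # order of first appearance
    if len(levels) != 2:
        raise DataError(f"design must contain exactly two group labels, got {levels}")
    return groups, (levels[0], levels[1])


def read_count_table(path: Union[str, Path], design_path: Union[str, Path]) -> CountTable:
    """Load a genes-in-rows count TSV plus its sample design.

    Samples are reconciled with the design by id, never by position.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    groups, levels = _read_design(design_path)
    return CountTable(counts=counts, groups=groups, group_levels=levels)


def write_count_table(table: CountTable, path: Union[str, Path],
                      design_path: Union[str, Path]) -> None:
    table.counts.to_csv(path, sep="\t")
    table.groups.rename("group").rename_axis("sample_id").reset_index().to_csv(
        design_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GeneSet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols, upper-cased for matching."""

    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise DataError(f"gene set {self.name!r} is empty")


def read_gene_set(path: Union[str, Path]) -> GeneSet:
    """Parse a gene set from a GMT line or a one-symbol-per-line file.

    A first line containing two or more tabs is treated as GMT
    (name, description, symbols...); anything else as one symbol per line.
    Symbols are upper-cased; duplicates are collapsed and counted.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise DataError(f"gene set file {path} is empty")
    if lines[0].count("\t") >= 2:
        fields = lines[0].split("\t")
        name, raw = fields[0], fields[2:]
        if len(lines) > 1:
            log.warning("GMT file %s has %d lines; only the first set is used",
                        path, len(lines))
    else:
        name, raw = path.stem, [tok for ln in lines for tok in ln.split("\t")]
    upper = [s.upper() for s in raw if s]
    symbols = frozenset(upper)
    dropped = len(upper) - len(symbols)
    if dropped:
        log.info("gene set %s: collapsed %d duplicate symbol(s)", name, dropped)
    if not symbols:
        raise DataError(f"gene set file {path} contains no symbols")
    return GeneSet(name=name, symbols=symbols)


def write_gene_set(gene_set: GeneSet, path: Union[str, Path]) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.symbols)) + "\n")


# ---------------------------------------------------------------------------
# CtTable
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """qPCR cycle thresholds in long form, one row per replicate reaction.

    ``data`` columns: gene_id, sample_id, replicate, ct_target, ct_reference
    (the reference gene, e.g. GAPDH, measured alongside each reaction).
    """

    data: pd.DataFrame
    groups: pd.Series
    group_levels: tuple[str, str]

    REQUIRED = ("gene_id", "sample_id", "replicate", "ct_target", "ct_reference")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise DataError(f"Ct table lacks required column {col!r}")
        for col in ("ct_target", "ct_reference"):
            vals = self.data[col]
            if vals.isna().any():
                bad = self.data.loc[vals.isna()].iloc[0]
                raise DataError(
                    f"missing {col} for gene {bad['gene_id']!r}, sample {bad['sample_id']!r}"
                )
            if not np.isfinite(vals).all() or (vals <= 0).any():
                raise DataError(f"{col} values must be finite and > 0")
        samples = set(self.data["sample_id"])
        missing = samples - set(self.groups.index)
        if missing:
            raise DataError(f"Ct sample(s) missing from design: {sorted(missing)}")
        # every gene must be measured (>= 1 replicate) in every sample it appears in both groups
        per = self.data.groupby(["gene_id", "sample_id"]).size()
        if (per < 1).any():  # pragma: no cover - groupby cannot produce 0
            raise DataError("each gene/sample cell needs >= 1 replicate")
        for level in self.group_levels:
            level_samples = set(self.groups.index[self.groups == level]) & samples
            if not level_samples:
                raise DataError(f"no Ct measurements in group {level!r}")
        self.data = self.data.sort_values(
            ["gene_id", "sample_id", "replicate"]
        ).reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.data["gene_id"].unique())


def read_ct_table(path: Union[str, Path], design_path: Union[str, Path]) -> CtTable:
    data = pd.read_csv(path, sep="\t")
    groups, levels = _read_design(design_path)
    return CtTable(data=data, groups=groups, group_levels=levels)


def write_ct_table(ct: CtTable, path: Union[str, Path]) -> None:
    ct.data.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Generic results I/O
# ---------------------------------------------------------------------------

def write_results(records, path: Union[str, Path]) -> None:
    """Write a results object (DataFrame or anything with ``to_frame()``) as TSV.

    Column order is the object's own; floats are rendered with
    ``FLOAT_FORMAT`` so rewriting identical inputs is byte-identical.
    """
    frame = records if isinstance(records, pd.DataFrame) else records.to_frame()
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
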