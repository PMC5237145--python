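"""Directional gene-set skew: match a set, classify up/down, test against 50:50.

This is the mitoproteome-style analysis: every matched gene is classified
by the sign of its between-group log2 difference (M value), and the up/down
split is tested against an exact symmetric binomial null.  Ties carry no
directional evidence and are excluded from the trial count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import DataError, GeneSet
from .de_analysis import ma_values
from .normalize_filter import NormalizedTable

log = logging.getLogger("mitoskew")


@dataclass
class SkewResult:
    """Direction counts for a matched gene set and the binomial skew p-value."""

    set_name: str
    n_matched: int
    n_up: int      # higher in group A
    n_down: int    # lower in group A
    n_tied: int
    p_two_sided: float

    @property
    def down_fraction(self) -> float:
        """n_down / (n_up + n_down); ties excluded."""
        return self.n_down / (self.n_up + self.n_down)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "set_name": self.set_name,
            "n_matched": self.n_matched,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "n_tied": self.n_tied,
            "down_fraction": self.down_fraction,
            "p_two_sided": self.p_two_sided,
        }])


def match_gene_set(gene_set: GeneSet, norm: NormalizedTable) -> tuple[list[str], list[str]]:
    """Case-insensitive intersection of set symbols with the table's gene ids.

    Returns (matched table gene ids, unmatched set symbols).  Zero matches
    is an error — a skew test on nothing is meaningless.
    """
    if not norm.gene_ids:
        raise DataError("normalized table is empty")
    by_upper: dict[str, str] = {}
    for gid in norm.gene_ids:
        by_upper.setdefault(str(gid).upper(), gid)
    wanted = sorted({s.upper() for s in gene_set.symbols})
    matched = [by_upper[s] for s in wanted if s in by_upper]
    unmatched = [s for s in wanted if s not in by_upper]
    if not matched:
        raise DataError(f"gene set {gene_set.name!r} shares no genes with the table")
    log.info("match_gene_set: %d/%d symbols matched (%d unmatched)",
             len(matched), len(gene_set.symbols), len(unmatched))
    return matched, unmatched


def classify_directions(m_values: pd.Series, epsilon: float = 0.0) -> tuple[int, int, int]:
    """Count genes up (m > eps), down (m < -eps) and tied (|m| <= eps)."""
    if epsilon < 0:
        raise DataError("epsilon must be nonnegative")
    m = np.asarray(m_values, dtype=float)
    n_up = int((m > epsilon).sum())
    n_down = int((m < -epsilon).sum())
    return n_up, n_down, int(m.size - n_up - n_down)


def binomial_skew_test(n_up: int, n_down: int, normal_approx: bool = False) -> float:
    """Two-sided test of an up/down split against a fair-coin null.

    Exact by default: with n = n_up + n_down trials and k = min(n_up, n_down),
    p = min(1, 2 * P[X <= k]) under Binomial(n, 1/2).  The normal
    approximation (continuity-corrected) is available for very large sets.
    """
    if n_up < 0 or n_down < 0:
        raise DataError("counts must be nonnegative")
    n = n_up + n_down
    if n == 0:
        raise DataError("no directional genes: n_up + n_down must be >= 1")
    k = min(n_up, n_down)
    if normal_approx:
        z = (k + 0.5 - n / 2.0) / np.sqrt(n / 4.0)
        return float(min(1.0, 2.0 * stats.norm.cdf(z)))
    return float(min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5)))


def skew_report(gene_set: GeneSet, norm: NormalizedTable,
                epsilon: float = 0.0) -> tuple[SkewResult, pd.DataFrame]:
    """Match, classify and test a gene set; also emit an MA table for plotting.

    The per-gene table carries a_value, m_value and a direction code
    (``red`` = higher in group A, ``blue`` = lower, ``tie``), the coloring
    convention of the MA-format set plot.
    """
    matched, unmatched = match_gene_set(gene_set, norm)
    ma = ma_values(norm).set_index("gene_id").loc[matched]
    m = ma["m_value"]
    n_up, n_down, n_tied = classify_directions(m, epsilon)
    p = binomial_skew_test(n_up, n_down)
    result = SkewResult(
        set_name=gene_set.name, n_matched=len(matched),
        n_up=n_up, n_down=n_down, n_tied=n_tied, p_two_sided=p,
    )
    direction = np.where(m > epsilon, "red", np.where(m < -epsilon, "blue", "tie"))
    table = pd.DataFrame({
        "gene_id": matched,
        "a_value": ma["a_value"].to_numpy(),
        "m_value": m.to_numpy(),
        "direction": direction,
    })
    return result, table
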