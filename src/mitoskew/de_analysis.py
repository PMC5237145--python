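"""Per-gene two-group testing, signed fold change, DE calling and MA values.

The default caller is deliberately simple and matches the original design:
a pooled-variance Student t-test on log2 quantile-normalized RPM, strict
thresholds (p < alpha and |linear fold| > fc_threshold) and NO
multiple-testing correction unless explicitly requested — single-gene
p-values feed downstream set-level and clustering analyses, where the
genome-wide view rather than any single call carries the inference.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import DataError
from .normalize_filter import NormalizedTable

log = logging.getLogger("mitoskew")

#: DERecord column order used by every writer.
DE_COLUMNS = [
    "gene_id", "mean_a", "mean_b", "m_value", "a_value",
    "t_stat", "p_value", "fold_linear", "is_de",
]


def _group_arrays(norm: NormalizedTable) -> tuple[np.ndarray, np.ndarray]:
    a, b = norm.group_levels
    xa = norm.values[norm.samples_in(a)].to_numpy(dtype=float)
    xb = norm.values[norm.samples_in(b)].to_numpy(dtype=float)
    if xa.shape[1] < 2 or xb.shape[1] < 2:
        raise DataError("each group needs >= 2 samples for the t-test")
    return xa, xb


def two_group_ttest(norm: NormalizedTable, welch: bool = False) -> pd.DataFrame:
    """Two-sided two-sample t-test per gene (group A vs group B).

    Default is the Student pooled-variance statistic with n_A + n_B - 2
    degrees of freedom; ``welch=True`` switches to the unequal-variance
    statistic with Welch–Satterthwaite degrees of freedom.  When both group
    variances are zero the test degenerates: equal means give t = 0, p = 1;
    unequal means give p = 0 with a logged warning.
    """
    xa, xb = _group_arrays(norm)
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    diff = ma - mb

    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = va / na + vb / nb
            t = diff / np.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = np.full_like(diff, float(na + nb - 2))
        p = 2.0 * stats.t.sf(np.abs(t), df)

    degenerate = (va == 0) & (vb == 0)
    if degenerate.any():
        same = degenerate & (diff == 0)
        differ = degenerate & (diff != 0)
        t[same], p[same] = 0.0, 1.0
        t[differ] = np.sign(diff[differ]) * np.inf
        p[differ] = 0.0
        if differ.any():
            log.warning("two_group_ttest: %d gene(s) with zero variance in both "
                        "groups but unequal means (p set to 0)", int(differ.sum()))
    return pd.DataFrame(
        {"gene_id": norm.gene_ids, "t_stat": t, "p_value": p}
    )


def signed_fold_change(m_value):
    """Map a log2 difference to the signed linear fold convention.

    2^m for m >= 0, else -2^(-m): a doubling is +2, a halving is -2, no
    change is +1.  This is a bijection between the reals and
    (-inf, -1] U [1, inf); accepts scalars or arrays.
    """
    m = np.asarray(m_value, dtype=float)
    out = np.where(m >= 0, np.exp2(m), -np.exp2(-m))
    return float(out) if np.isscalar(m_value) else out


def ma_values(norm: NormalizedTable) -> pd.DataFrame:
    """Per-gene MA coordinates: M = mean_A - mean_B, A = grand mean."""
    xa, xb = _group_arrays(norm)
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    grand = np.hstack([xa, xb]).mean(axis=1)
    return pd.DataFrame({
        "gene_id": norm.gene_ids,
        "mean_a": ma,
        "mean_b": mb,
        "m_value": ma - mb,
        "a_value": grand,
    })


def call_de(records: pd.DataFrame, alpha: float = 0.05,
            fc_threshold: float = 1.3, fdr: str = "none") -> tuple[pd.DataFrame, int]:
    """Flag DE genes: p < alpha AND |linear fold| > fc_threshold, both strict.

    ``fdr="bh"`` applies Benjamini–Hochberg to the p-values before
    thresholding; the default ``"none"`` applies no correction.
    Returns the updated records plus the DE count.
    """
    if alpha <= 0 or fc_threshold <= 0:
        raise DataError("alpha and fc_threshold must be > 0")
    if fdr not in ("none", "bh"):
        raise DataError(f"unknown fdr option {fdr!r}")
    records = records.copy()
    p = records["p_value"].to_numpy()
    p_eff = stats.false_discovery_control(p, method="bh") if fdr == "bh" else p
    records["is_de"] = (p_eff < alpha) & (np.abs(records["fold_linear"]) > fc_threshold)
    n_de = int(records["is_de"].sum())
    log.info("call_de: %d DE gene(s) of %d (alpha %g, fold > %g, fdr=%s)",
             n_de, len(records), alpha, fc_threshold, fdr)
    return records, n_de


def de_table(norm: NormalizedTable, alpha: float = 0.05, fc_threshold: float = 1.3,
             welch: bool = False, fdr: str = "none") -> pd.DataFrame:
    """Full per-gene DE records: means, M/A, t, p, signed fold, DE flag."""
    ma = ma_values(norm)
    tt = two_group_ttest(norm, welch=welch)
    records = ma.merge(tt, on="gene_id")
    records["fold_linear"] = signed_fold_change(records["m_value"].to_numpy())
    records, _ = call_de(records, alpha=alpha, fc_threshold=fc_threshold, fdr=fdr)
    return records[DE_COLUMNS]


def sort_de_table(records: pd.DataFrame) -> pd.DataFrame:
    """Order for reporting: ascending p, then |fold| descending, then gene id."""
    key = records.assign(_absfold=records["fold_linear"].abs())
    return (
        key.sort_values(["p_value", "_absfold", "gene_id"],
                        ascending=[True, False, True])
        .drop(columns="_absfold")
        .reset_index(drop=True)
    )
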