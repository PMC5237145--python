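"""2^-ddCt relative quantification and RNA-seq vs qPCR sign concordance.

Technical replicates are averaged on the Ct scale, each sample's target Ct
is referenced to its internal-control Ct (dCt), the group contrast is
ddCt = mean dCt(group A) - mean dCt(group B), and relative expression is
2^-ddCt, reported with the signed fold convention (a halving is -2).
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .data_io import CtTable, DataError


def ddct_fold_change(ct: CtTable) -> pd.DataFrame:
    """Per-gene signed linear fold change from a replicate-level Ct table.

    Returns columns gene_id, delta_delta_ct, fold (signed convention:
    2^-ddCt if >= 1, else its negative reciprocal).
    """
    cell = (
        ct.data.groupby(["gene_id", "sample_id"])[["ct_target", "ct_reference"]]
        .mean()
        .reset_index()
    )
    cell["dct"] = cell["ct_target"] - cell["ct_reference"]
    cell["group"] = ct.groups.loc[cell["sample_id"]].to_numpy()
    a, b = ct.group_levels
    rows = []
    for gene, sub in cell.groupby("gene_id", sort=True):
        in_a, in_b = sub["group"] == a, sub["group"] == b
        if not in_a.any() or not in_b.any():
            raise DataError(f"gene {gene!r} lacks Ct measurements in both groups")
        ddct = sub.loc[in_a, "dct"].mean() - sub.loc[in_b, "dct"].mean()
        raw = 2.0 ** (-ddct)
        fold = raw if raw >= 1.0 else -1.0 / raw
        rows.append({"gene_id": gene, "delta_delta_ct": ddct, "fold": fold})
    return pd.DataFrame(rows)


def sign_concordance(pairs: pd.DataFrame) -> tuple[int, int, pd.DataFrame]:
    """Score direction agreement between RNA-seq and qPCR fold changes.

    ``pairs`` needs columns gene_id, rnaseq_fold, qpcr_fold (signed folds;
    zero is outside the convention and rejected).  Returns the concordant
    and discordant counts plus the per-gene table with a ``concordant`` flag.
    """
    for col in ("gene_id", "rnaseq_fold", "qpcr_fold"):
        if col not in pairs.columns:
            raise DataError(f"pairs table lacks column {col!r}")
    r = pairs["rnaseq_fold"].to_numpy(dtype=float)
    q = pairs["qpcr_fold"].to_numpy(dtype=float)
    if (r == 0).any() or (q == 0).any():
        raise DataError("zero fold change: the signed convention excludes 0")
    out = pairs.copy()
    out["concordant"] = np.sign(r) == np.sign(q)
    n_con = int(out["concordant"].sum())
    return n_con, len(out) - n_con, out


def load_validation_panel() -> pd.DataFrame:
    """The packaged 20-gene broiler (PeM) vs Barred Plymouth Rock validation
    panel: published linear fold changes by RNA-seq and by qPCR for the same
    genes, used to exercise the concordance scoring end to end."""
    with resources.files("mitoskew.data").joinpath("qpcr_validation_panel.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
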