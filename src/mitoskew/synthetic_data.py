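"""Two-group negative-binomial count simulator with planted DE and set skew.

Emulates the statistical structure the downstream analysis assumes: a
gene-by-sample raw count matrix for two groups of n birds each, log-normal
gene abundances, sample-specific library sizes, overdispersed counts, a
planted fraction of truly differential genes with Gaussian log2 effects,
and a designated gene set whose true effect directions are biased away
from 50:50.  A matching replicate-level qPCR Ct table can be derived from
the same ground truth.

Defaults approximate the motivating study design: 6 samples per group,
~9,500 expressed genes, tens of millions of reads per sample, ~27% of
genes differential, and a 699-gene set with 70% of its true effects
pointing down in group A.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .data_io import CountTable, CtTable, DataError, GeneSet

# fixed substream order: changing one stage's draws never perturbs another's
_STREAMS = ("abundance", "libsize", "de", "geneset", "direction", "effect",
            "counts", "ct")


@dataclass
class SynthConfig:
    """Knobs of the count simulator; all rates are per-gene probabilities.

    ``baseline_log_mean``/``baseline_log_sd`` parameterize the natural-log
    normal distribution of true gene abundances (expected raw counts at the
    reference library size); ``dispersion`` is the negative-binomial size
    parameter (between-sample CV^2 ~ 1/dispersion + 1/mean);
    ``libsize_log_sd`` scales sample library factors; ``de_log2_effect_sd``
    is the spread of planted log2 effects (group A minus group B);
    ``geneset_down_fraction`` is the probability that a set member's
    planted effect points down in group A.
    """

    n_genes: int = 9500
    n_per_group: int = 6
    baseline_log_mean: float = 6.5
    baseline_log_sd: float = 2.0
    dispersion: float = 15.0
    libsize_log_sd: float = 0.15
    de_fraction: float = 0.27
    de_log2_effect_sd: float = 1.2
    geneset_size: int = 699
    geneset_down_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise DataError("n_genes and n_per_group must be positive")
        for name in ("baseline_log_sd", "dispersion", "libsize_log_sd",
                     "de_log2_effect_sd"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be > 0")
        for name in ("de_fraction", "geneset_down_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise DataError(f"{name} must lie in [0, 1]")
        if self.geneset_size < 0 or self.geneset_size > self.n_genes:
            raise DataError("geneset_size must lie in [0, n_genes]")

    def to_dict(self) -> dict:
        return asdict(self)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _sample_ids(n_per_group: int) -> tuple[list[str], pd.Series]:
    ids = [f"A{i}" for i in range(1, n_per_group + 1)] + \
          [f"B{i}" for i in range(1, n_per_group + 1)]
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=ids)
    return ids, groups


def generate_counts(
    config: SynthConfig,
) -> tuple[CountTable, pd.DataFrame, GeneSet | None]:
    """Draw a seeded two-group count matrix with its ground truth.

    Returns the CountTable, a truth table (gene_id, is_de, log2_effect,
    in_geneset, planted_direction) and the GeneSet naming the designated
    member genes (None when ``geneset_size`` is 0).  Identical config and
    seed give bit-identical output.
    """
    rng = _rngs(config.seed)
    genes = _gene_ids(config.n_genes)
    sample_ids, groups = _sample_ids(config.n_per_group)

    mu = rng["abundance"].lognormal(config.baseline_log_mean,
                                    config.baseline_log_sd, config.n_genes)
    lib = rng["libsize"].lognormal(0.0, config.libsize_log_sd, len(sample_ids))
    is_de = rng["de"].random(config.n_genes) < config.de_fraction

    member_idx = rng["geneset"].choice(config.n_genes, size=config.geneset_size,
                                       replace=False)
    in_set = np.zeros(config.n_genes, dtype=bool)
    in_set[member_idx] = True

    down_prob = np.where(in_set, config.geneset_down_fraction, 0.5)
    is_down = rng["direction"].random(config.n_genes) < down_prob
    magnitude = np.abs(rng["effect"].normal(0.0, config.de_log2_effect_sd,
                                            config.n_genes))
    log2_effect = np.where(is_de, np.where(is_down, -magnitude, magnitude), 0.0)

    # mean(gene, sample) = abundance * library factor * 2^effect (group A only)
    in_a = (groups.to_numpy() == "A").astype(float)
    mean = mu[:, None] * lib[None, :] * np.exp2(log2_effect[:, None] * in_a[None, :])
    r = config.dispersion
    counts = rng["counts"].negative_binomial(r, r / (r + mean))

    table = CountTable(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        groups=groups,
        group_levels=("A", "B"),
    )
    direction = np.where(is_de, np.where(is_down, "down", "up"), "none")
    truth = pd.DataFrame({
        "gene_id": genes,
        "is_de": is_de,
        "log2_effect": log2_effect,
        "in_geneset": in_set,
        "planted_direction": direction,
    })
    gene_set = (GeneSet(name="synthetic_set",
                        symbols=frozenset(np.array(genes)[in_set]))
                if config.geneset_size else None)
    return table, truth, gene_set


def _ct_panel(truth: pd.DataFrame, n_panel: int) -> list[str]:
    """Panel of the most extreme planted effects, half up and half down,
    padded with arbitrary genes when the truth has too few DE genes."""
    de = truth.loc[truth["is_de"]]
    k = n_panel // 2
    up = de.nlargest(k, "log2_effect")["gene_id"].tolist()
    down = de.nsmallest(n_panel - k, "log2_effect")["gene_id"].tolist()
    panel = list(dict.fromkeys(up + down))
    for gid in truth["gene_id"]:
        if len(panel) >= min(n_panel, len(truth)):
            break
        if gid not in panel:
            panel.append(gid)
    return panel


def generate_ct_table(
    truth: pd.DataFrame,
    config: SynthConfig,
    genes: list[str] | None = None,
    n_panel: int = 20,
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    base_ct_mean: float = 24.0,
    base_ct_sd: float = 2.0,
    reference_ct: float = 15.0,
) -> CtTable:
    """Replicate-level qPCR Ct measurements consistent with the truth table.

    Each selected gene's target Ct is base - log2_effect in group A samples
    (one planted doubling lowers Ct by one cycle) plus Gaussian replicate
    noise; the reference gene's Ct is constant across groups plus noise.
    """
    if noise_sd < 0:
        raise DataError("noise_sd must be nonnegative")
    rng = _rngs(config.seed)["ct"]
    if genes is None:
        genes = _ct_panel(truth, n_panel)
    effects = truth.set_index("gene_id")["log2_effect"]
    unknown = [g for g in genes if g not in effects.index]
    if unknown:
        raise DataError(f"gene(s) not in truth table: {unknown}")
    sample_ids, groups = _sample_ids(config.n_per_group)
    base = pd.Series(rng.normal(base_ct_mean, base_ct_sd, len(genes)), index=genes)

    rows = []
    for gene in genes:
        for sample in sample_ids:
            shift = effects[gene] if groups[sample] == "A" else 0.0
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "gene_id": gene,
                    "sample_id": sample,
                    "replicate": rep,
                    "ct_target": base[gene] - shift + rng.normal(0.0, noise_sd)
                    if noise_sd else base[gene] - shift,
                    "ct_reference": reference_ct + rng.normal(0.0, noise_sd)
                    if noise_sd else reference_ct,
                })
    return CtTable(data=pd.DataFrame(rows), groups=groups, group_levels=("A", "B"))
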