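import numpy as np
import pandas as pd
import pytest

from mitoskew import DataError, SynthConfig, generate_counts, generate_ct_table
from mitoskew.synthetic_data import _rngs


class TestConfigValidation:
    def test_geneset_larger_than_genome_rejected(self):
        with pytest.raises(DataError):
            SynthConfig(n_genes=100, geneset_size=200)

    @pytest.mark.parametrize("field,value", [
        ("de_fraction", 1.5), ("dispersion", 0.0), ("n_genes", 0),
        ("geneset_down_fraction", -0.1),
    ])
    def test_out_of_range_fields_rejected(self, field, value):
        with pytest.raises(DataError):
            SynthConfig(**{field: value})


class TestGenerateCounts:
    def test_same_seed_bit_identical(self):
        cfg = SynthConfig(n_genes=300, geneset_size=50, seed=42)
        t1, truth1, gs1 = generate_counts(cfg)
        t2, truth2, gs2 = generate_counts(cfg)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        pd.testing.assert_frame_equal(truth1, truth2)
        assert gs1.symbols == gs2.symbols

    def test_different_seed_differs(self):
        t1, _, _ = generate_counts(SynthConfig(n_genes=300, geneset_size=50, seed=1))
        t2, _, _ = generate_counts(SynthConfig(n_genes=300, geneset_size=50, seed=2))
        assert not t1.counts.equals(t2.counts)

    def test_null_config_has_no_de(self):
        _, truth, _ = generate_counts(
            SynthConfig(n_genes=200, geneset_size=30, de_fraction=0.0, seed=3))
        assert not truth["is_de"].any()
        assert (truth["planted_direction"] == "none").all()
        assert (truth["log2_effect"] == 0).all()

    def test_truth_direction_consistent_with_effect_sign(self):
        _, truth, gene_set = generate_counts(
            SynthConfig(n_genes=500, geneset_size=100, de_fraction=0.5, seed=4))
        de = truth[truth["is_de"]]
        assert ((de["planted_direction"] == "down") == (de["log2_effect"] < 0)).all()
        assert (truth.loc[~truth["is_de"], "planted_direction"] == "none").all()
        assert truth["in_geneset"].sum() == 100
        assert set(gene_set.symbols) == set(truth.loc[truth["in_geneset"], "gene_id"])

    def test_marginal_means_match_drawn_abundances(self):
        """With many samples and a near-constant library size, per-gene
        empirical means track the drawn abundances within 3 standard errors."""
        cfg = SynthConfig(n_genes=400, n_per_group=100, libsize_log_sd=1e-3,
                          de_fraction=0.0, geneset_size=10, seed=5)
        table, _, _ = generate_counts(cfg)
        mu = _rngs(cfg.seed)["abundance"].lognormal(
            cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
        counts = table.counts.to_numpy()
        emp_mean = counts.mean(axis=1)
        se = counts.std(axis=1, ddof=1) / np.sqrt(counts.shape[1])
        within = np.abs(emp_mean - mu) <= 3 * se
        assert within.mean() >= 0.99


def test_planted_down_bias_recovered_among_significant_calls():
    """With a 700-gene set planted 65% down among DE genes (30% of the
    genome differential), the down fraction estimated from the set's
    significant-direction calls tracks the planted truth within 0.05 on
    average and points the right way in at least 95% of 100 seeds."""
    from mitoskew import NormalizedTable, de_table, normalize_counts, skew_report

    diffs, recovered = [], 0
    for seed in range(100):
        cfg = SynthConfig(n_genes=8000, geneset_size=700, de_fraction=0.3,
                          geneset_down_fraction=0.65, seed=seed)
        table, truth, gene_set = generate_counts(cfg)
        norm, _ = normalize_counts(table)
        records = de_table(norm)
        called = records.loc[records["is_de"], "gene_id"]
        sig = NormalizedTable(values=norm.values.loc[called],
                              groups=norm.groups, group_levels=norm.group_levels)
        result, _ = skew_report(gene_set, sig)
        members = truth[truth["in_geneset"] & truth["is_de"]]
        diffs.append(result.down_fraction - (members["log2_effect"] < 0).mean())
        recovered += result.down_fraction > 0.5
    assert abs(np.mean(diffs)) <= 0.05
    assert recovered >= 95, recovered


class TestGenerateCtTable:
    def test_zero_noise_construction(self):
        truth = pd.DataFrame({"gene_id": ["G00001"], "is_de": [True],
                              "log2_effect": [1.0], "in_geneset": [False],
                              "planted_direction": ["up"]})
        cfg = SynthConfig(n_genes=1, geneset_size=0, seed=6)
        ct = generate_ct_table(truth, cfg, genes=["G00001"], noise_sd=0.0)
        cell = ct.data.groupby("sample_id")["ct_target"].mean()
        a_samples = ct.groups.index[ct.groups == "A"]
        b_samples = ct.groups.index[ct.groups == "B"]
        # group A target Ct is exactly one cycle lower for a planted doubling
        assert cell[a_samples].to_numpy() == pytest.approx(
            cell[b_samples].to_numpy() - 1.0)
        assert ct.data.groupby(["gene_id", "sample_id"]).size().eq(3).all()

    def test_unknown_gene_rejected(self):
        truth = pd.DataFrame({"gene_id": ["G00001"], "is_de": [False],
                              "log2_effect": [0.0], "in_geneset": [False],
                              "planted_direction": ["none"]})
        with pytest.raises(DataError, match="G09999"):
            generate_ct_table(truth, SynthConfig(n_genes=1, geneset_size=0, seed=1),
                              genes=["G09999"])

    def test_panel_prefers_extreme_de_genes(self):
        _, truth, _ = generate_counts(
            SynthConfig(n_genes=300, geneset_size=50, de_fraction=0.5, seed=8))
        ct = generate_ct_table(truth, SynthConfig(n_genes=300, geneset_size=50, seed=8))
        panel = ct.gene_ids
        assert len(panel) == 20
        effects = truth.set_index("gene_id")["log2_effect"]
        assert (effects[panel] != 0).all()
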