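"""EcoP15I bias profile, replicate correlation, length-vs-TPM, mapping stats."""

import numpy as np
import pandas as pd
import pytest

import fivedge as f
from fivedge.counting import TagArray, compute_tpm
from fivedge.qc import (
    ecop15i_bias_profile,
    estimate_suppression_factor,
    length_vs_tpm,
    mapping_stats,
    profile_flatness_pvalue,
    replicate_correlation,
    stochastic_error_at_tpm,
)
from fivedge.regions import GeneModel


def tags_from_truth(truth_hits, lengths, tag_length=25):
    """TagArray built directly from simulator truth positions."""
    tags = TagArray.zeros(lengths)
    for (scaf, strand), grp in truth_hits.groupby(["scaffold", "strand"]):
        pos = np.where(
            grp["strand"] == "-", grp["position"], grp["position"] + tag_length - 1
        )
        np.add.at(tags.get(scaf, strand), np.asarray(pos, dtype=np.int64), 1.0)
    tags.total_mapped = float(len(truth_hits))
    return tags


class TestBiasProfile:
    def test_uniform_tags_give_flat_profile(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 100_000))
        tags = TagArray.zeros({"s1": 100_000})
        np.add.at(
            tags.get("s1", "-"), rng.integers(0, 100_000, size=200_000), 1.0
        )
        profiles = ecop15i_bias_profile([("s1", seq)], tags, window_bp=100)
        for motif, prof in profiles.items():
            assert profile_flatness_pvalue(prof) > 0.01
            factor = estimate_suppression_factor(prof)
            assert 0.8 < factor < 1.25

    def test_zero_motif_genome_gives_empty_profile(self):
        seq = "AT" * 5_000  # contains neither CAGCAG nor CTGCTG
        tags = TagArray.zeros({"s1": 10_000})
        with pytest.warns(UserWarning, match="no occurrences"):
            profiles = ecop15i_bias_profile([("s1", seq)], tags, window_bp=50)
        assert profiles["CAGCAG"].n_sites == 0
        assert profiles["CAGCAG"].weights.sum() == 0.0

    def test_simulated_suppression_recovered(self):
        """3x suppression over 20 bp 3' of CTGCTG recovered within [2, 4]."""
        genome, models = f.make_toy_genome(
            1, 40, mean_gene_len=3_000, mean_gap=400, seed=21, max_exons=1
        )
        truth = f.assign_expression_profiles(
            models, fraction_null=1.0, seed=22, tss_peak_weight=0.0,
            decay_scale=1e9,
        )
        params = f.LibraryParams(
            depth=400_000, color_error_rate=0.0, ecop15i_bias=(3.0, 20)
        )
        _, th = f.simulate_tags(genome, models, truth, params, "t0", seed=23)
        tags = tags_from_truth(th, genome.lengths)
        profiles = ecop15i_bias_profile(genome.scaffolds, tags, window_bp=100)
        factor = estimate_suppression_factor(profiles["CTGCTG"])
        assert 2.0 <= factor <= 4.0


class TestReplicateCorrelation:
    def make_tpm(self, seed=0, depth=5_000_000, n_genes=400):
        rng = np.random.default_rng(seed)
        true = 10.0 ** rng.uniform(-0.5, 2.5, size=n_genes)
        true = true / true.sum() * 1e6
        cols = {}
        for s in ("rep1", "rep2"):
            counts = rng.poisson(depth * true / 1e6)
            cols[s] = compute_tpm(counts.astype(float), depth)
        return pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])

    def test_identical_samples_r2_one(self):
        tpm = self.make_tpm()
        tpm["rep2"] = tpm["rep1"]
        assert replicate_correlation(tpm, "rep1", "rep2") == pytest.approx(1.0)

    def test_technical_duplicates_highly_correlated(self):
        """Poisson resampling of one truth: R^2 >= 0.9 at depth 5e6, >=1 TPM."""
        tpm = self.make_tpm(seed=1)
        r2 = replicate_correlation(tpm, "rep1", "rep2", min_tpm=1.0)
        assert r2 >= 0.9

    def test_permuted_labels_destroy_correlation(self):
        tpm = self.make_tpm(seed=2)
        rng = np.random.default_rng(3)
        tpm["rep2"] = tpm["rep2"].to_numpy()[rng.permutation(len(tpm))]
        r2 = replicate_correlation(tpm, "rep1", "rep2")
        assert r2 < 0.1

    def test_symmetry(self):
        tpm = self.make_tpm(seed=4)
        assert replicate_correlation(tpm, "rep1", "rep2") == pytest.approx(
            replicate_correlation(tpm, "rep2", "rep1")
        )

    def test_too_few_genes_rejected(self):
        tpm = pd.DataFrame({"a": [0.1, 0.2], "b": [0.1, 0.2]})
        with pytest.raises(ValueError, match="fewer than 3"):
            replicate_correlation(tpm, "a", "b")


class TestLengthVsTpm:
    def make_models(self, n):
        return [
            GeneModel(f"g{i:04d}", "chr1", "+", i * 1_000, i * 1_000 + 100 + i)
            for i in range(n)
        ]

    def test_three_full_bins(self):
        models = self.make_models(30)
        tpm = pd.Series(1.0, index=[m.gene_id for m in models])
        out = length_vs_tpm(models, tpm, bin_size_genes=10)
        assert len(out) == 3
        assert (~out["partial"]).all()
        assert (out["n_genes"] == 10).all()

    def test_partial_last_bin_flagged(self):
        models = self.make_models(25)
        tpm = pd.Series(1.0, index=[m.gene_id for m in models])
        out = length_vs_tpm(models, tpm, bin_size_genes=10)
        assert len(out) == 3
        assert out.iloc[-1]["partial"] and out.iloc[-1]["n_genes"] == 5

    def test_length_independent_tpm_gives_equal_medians(self):
        rng = np.random.default_rng(5)
        models = self.make_models(300)
        tpm = pd.Series(
            rng.exponential(10.0, size=300), index=[m.gene_id for m in models]
        )
        out = length_vs_tpm(models, tpm, bin_size_genes=100)
        med = out["tpm_median"]
        assert med.max() / med.min() < 2.0  # sampling noise only

    def test_bins_sorted_by_length(self):
        models = self.make_models(30)
        tpm = pd.Series(1.0, index=[m.gene_id for m in models])
        out = length_vs_tpm(models, tpm, bin_size_genes=10)
        assert (out["length_min"].diff().dropna() > 0).all()


class TestMappingStats:
    def test_basic_percentages(self):
        s = mapping_stats(100, 0, 50, 40)
        assert s["pct_mapped"] == pytest.approx(50.0)
        assert s["pct_unique_of_mapped"] == pytest.approx(80.0)

    def test_zero_mapped_gives_na(self):
        s = mapping_stats(100, 100, 0, 0)
        assert s["pct_mapped"] is None
        assert s["pct_unique_of_mapped"] is None

    def test_error_free_unique_genome_maps_100_percent_unique(self, toy, toy_index):
        from fivedge.mapping import map_reads
        from fivedge.pipeline import _count_unique

        params = f.LibraryParams(depth=2_000, color_error_rate=0.0)
        batch, _ = f.simulate_tags(
            toy["genome"], toy["models"], toy["truth"], params, "t0", seed=30
        )
        hits = map_reads(batch, toy_index)
        stats = mapping_stats(len(batch), 0, hits.mapped_read_count,
                              _count_unique(hits))
        assert stats["pct_unique_of_mapped"] == pytest.approx(100.0, abs=0.5)


class TestStochasticError:
    def test_matches_poisson_theory(self):
        """Relative error at lambda tags is ~1/sqrt(lambda)."""
        err = stochastic_error_at_tpm(100.0, 1_000_000, n_replicates=5_000, seed=0)
        assert err == pytest.approx(0.1, rel=0.1)

    def test_one_tpm_at_16m_tags_in_20_30_band(self):
        err = stochastic_error_at_tpm(1.0, 16_000_000, n_replicates=5_000, seed=1)
        assert 0.20 <= err <= 0.30
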