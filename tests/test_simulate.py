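"""Toy genome generation, digestion, truth assignment and tag simulation."""

import logging

import numpy as np
import pandas as pd
import pytest

import fivedge as f
from fivedge.counting import accumulate_tags
from fivedge.mapping import ColorIndex, map_reads
from fivedge.reference import concatenate_reference
from fivedge.simulate import digest_ecop15i


class TestToyGenome:
    def test_forced_gap_is_exact(self):
        _, models = f.make_toy_genome(1, 2, fixed_gap=8_000, seed=7)
        a, b = sorted(models, key=lambda m: m.start)
        assert b.start - a.end == 8_000

    def test_seeded_determinism_byte_identical(self, tmp_path):
        outs = []
        for run in range(2):
            genome, models = f.make_toy_genome(2, 100, seed=1)
            fa = tmp_path / f"g{run}.fa"
            genome.write_fasta(fa)
            outs.append(fa.read_bytes())
            assert models == f.make_toy_genome(2, 100, seed=1)[1]
        assert outs[0] == outs[1]

    def test_invariants(self):
        genome, models = f.make_toy_genome(3, 40, seed=2)
        for name, seq in genome.scaffolds:
            assert len(seq) >= 10_000
            assert set(seq) <= set("ACGT")
        strands = {m.strand for m in models}
        assert strands == {"+", "-"}
        by_group = {}
        for m in models:
            by_group.setdefault((m.scaffold, m.strand), []).append(m)

    def test_genes_that_do_not_fit_raise(self):
        with pytest.raises(ValueError, match="do not fit"):
            f.make_toy_genome(1, 50, mean_gene_len=5_000, scaffold_length=20_000, seed=3)


class TestExpressionProfiles:
    def test_all_null_means_flat(self):
        _, models = f.make_toy_genome(1, 10, seed=4)
        truth = f.assign_expression_profiles(models, fraction_null=1.0, seed=5)
        assert (truth.labels == "null").all()
        norm = truth.tpm.div(truth.tpm.sum(axis=0), axis=1)
        # flat in composition: every gene keeps the same share at every time
        assert np.allclose(norm.to_numpy(), norm.to_numpy()[:, [0]])

    def test_exactly_three_patterns_present(self):
        _, models = f.make_toy_genome(2, 300, seed=6)
        truth = f.assign_expression_profiles(
            models, n_patterns=3, fraction_null=0.4, seed=7
        )
        non_null = truth.labels[truth.labels != "null"]
        assert set(non_null) == {"p0", "p1", "p2"}

    def test_per_sample_tpm_sums_to_million(self):
        _, models = f.make_toy_genome(1, 50, seed=8)
        truth = f.assign_expression_profiles(models, seed=9)
        assert np.allclose(truth.tpm.sum(axis=0), 1e6)

    def test_effect_fold_is_max_over_min(self):
        """With mostly-null genes the per-sample renormalization is nearly
        constant, so non-null genes keep their 4-fold dynamic range."""
        _, models = f.make_toy_genome(2, 200, seed=10)
        truth = f.assign_expression_profiles(
            models, fraction_null=0.9, effect_fold=4.0, seed=11
        )
        de = truth.labels != "null"
        ratio = truth.tpm[de].max(axis=1) / truth.tpm[de].min(axis=1)
        assert np.allclose(ratio, 4.0, rtol=0.1)


class TestDigestion:
    def test_single_forward_site_yields_25bp_tag(self):
        cdna = "GGGG" + "CAGCAG" + "A" * 30
        tags = digest_ecop15i(cdna)
        assert len(tags) == 1
        t = tags[0]
        assert len(t.tag) == 25 and len(t.overhang) == 2
        assert t.orientation == "+" and t.site_position == 4
        assert t.tag == "A" * 25

    def test_reverse_site_tag_taken_in_site_orientation(self):
        cdna = "T" * 30 + "CTGCTG" + "GGGG"
        tags = digest_ecop15i(cdna)
        assert len(tags) == 1
        t = tags[0]
        assert t.orientation == "-" and len(t.tag) == 25
        assert t.tag == "A" * 25  # revcomp of the 25 T's 5' of the site

    def test_no_site_returns_empty(self):
        assert digest_ecop15i("ACGT" * 20) == []

    def test_site_too_close_to_end_dropped_with_warning(self, caplog):
        cdna = "GG" + "CAGCAG" + "A" * 26  # 26 < 27 nt downstream
        with caplog.at_level(logging.WARNING):
            tags = digest_ecop15i(cdna)
        assert tags == []
        assert "dropped" in caplog.text

    def test_exactly_27_downstream_is_cuttable(self):
        cdna = "GG" + "CAGCAG" + "A" * 27
        assert len(digest_ecop15i(cdna)) == 1


class TestSimulateTags:
    def test_peak_weight_one_puts_all_tags_on_tss(self, toy):
        genome, models = toy["genome"], toy["models"]
        truth = f.assign_expression_profiles(
            models, seed=12, tss_peak_weight=1.0
        )
        params = f.LibraryParams(depth=5_000, color_error_rate=0.0)
        _, th = f.simulate_tags(genome, models, truth, params, "t0", seed=13)
        tss = {m.gene_id: m.tss for m in models}
        for gid, grp in th.groupby("gene_id"):
            positions = set(grp["position"])
            assert len(positions) == 1
            m = next(mm for mm in models if mm.gene_id == gid)
            expected_window = m.tss if m.strand == "+" else m.tss - 24
            assert positions == {expected_window}

    def test_poisson_counts_within_4_sigma(self):
        """A gene at 100 TPM and depth 1e6 yields 100 +- 4*10 tags."""
        genome, models = f.make_toy_genome(1, 4, seed=14)
        tpm = pd.DataFrame(
            {"t0": [100.0, 400_000.0, 300_000.0, 299_900.0]},
            index=pd.Index([m.gene_id for m in models], name="gene_id"),
        )
        truth = f.SimTruth(
            tpm=tpm,
            labels=pd.Series("null", index=tpm.index),
            tss_peak_weight=pd.Series(0.6, index=tpm.index),
            decay_scale=pd.Series(500.0, index=tpm.index),
        )
        params = f.LibraryParams(depth=1_000_000, color_error_rate=0.0)
        inside = 0
        n_runs = 20
        for seed in range(n_runs):
            _, th = f.simulate_tags(genome, models, truth, params, "t0", seed=seed)
            count = (th["gene_id"] == models[0].gene_id).sum()
            if abs(count - 100) <= 40:
                inside += 1
        assert inside >= int(0.99 * n_runs) - 1  # 4 sigma: essentially always

    def test_reads_are_antisense_to_transcript(self, toy, small_library):
        _, th = small_library
        strand_of = {m.gene_id: m.strand for m in toy["models"]}
        mapped = th["strand"]
        gene_strand = th["gene_id"].map(strand_of)
        assert (mapped != gene_strand).all()

    def test_error_free_reads_roundtrip_to_truth_positions(self, toy):
        """Simulate -> map recovers each read's recorded origin."""
        genome, models = toy["genome"], toy["models"]
        params = f.LibraryParams(depth=3_000, color_error_rate=0.0)
        batch, th = f.simulate_tags(
            genome, models, toy["truth"], params, "t0", seed=15
        )
        index = ColorIndex(toy["reference"])
        hits = map_reads(batch, index)
        truth_by_read = {
            r.read_id: (r.scaffold, r.position, r.strand)
            for r in th.itertuples()
        }
        found = 0
        for i, rows in hits.iter_read_hits():
            rid = batch.ids[i]
            zero_mm = [
                j for j in rows if hits.mismatches[j] == 0
            ]
            locs = set()
            for j in zero_mm:
                scaf, local = toy["reference"].to_local(int(hits.gpos[j]))
                locs.add((scaf, local, "+-"[int(hits.strand[j])]))
            assert truth_by_read[rid] in locs
            found += 1
        assert found == len(batch)

    def test_determinism(self, toy):
        params = f.LibraryParams(depth=2_000)
        a, tha = f.simulate_tags(
            toy["genome"], toy["models"], toy["truth"], params, "t0", seed=16
        )
        b, thb = f.simulate_tags(
            toy["genome"], toy["models"], toy["truth"], params, "t0", seed=16
        )
        assert a.ids == b.ids
        assert np.array_equal(a.colors, b.colors)
        pd.testing.assert_frame_equal(tha, thb)

    def test_low_information_fixture_reads(self, toy):
        params = f.LibraryParams(depth=1_000)
        batch, _ = f.simulate_tags(
            toy["genome"], toy["models"], toy["truth"], params, "t0",
            seed=17, n_low_information=5,
        )
        zero_rows = (batch.colors != 0).sum(axis=1) == 0
        assert zero_rows.sum() == 5


class TestExpressionMatrix:
    def test_step_patterns_hit_exact_fold(self):
        tpm, truth, times = f.simulate_expression_matrix(
            n_genes=50, fraction_de=1.0, effect_fold=4.0, rep_sd_log2=0.0, seed=18
        )
        profiles = tpm.T.groupby(pd.Series(times)).mean().T
        ratio = profiles.max(axis=1) / profiles.min(axis=1)
        assert np.allclose(ratio, 4.0)

    def test_null_fraction_and_labels(self):
        tpm, truth, times = f.simulate_expression_matrix(
            n_genes=200, fraction_de=0.1, seed=19
        )
        assert truth["de"].sum() == 20
        assert set(truth.loc[truth["de"], "pattern"]) == {"p0", "p1", "p2"}
        assert (truth.loc[~truth["de"], "pattern"] == "null").all()
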