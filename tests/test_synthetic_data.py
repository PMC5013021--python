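"""Generator contracts: spacing, determinism, truth consistency, realism."""

import numpy as np
import pandas as pd
import pytest

from helptag_dm.differential import loci_t_test
from helptag_dm.scoring_qc import compute_scores
from helptag_dm.synthetic_data import (ConfigError, SimulationConfig,
                                       SizingError, generate_annotation,
                                       generate_counts, generate_ct_table,
                                       generate_gene_sets, generate_loci)


class TestGenerateLoci:
    def test_mean_gap_matches_configured_spacing(self):
        cfg = SimulationConfig(n_loci=10_000, n_chromosomes=1,
                               chromosome_length=40_000_000, seed=1)
        loci = generate_loci(cfg)
        gaps = np.diff(loci["start"].values)
        assert abs(gaps.mean() - 2000) / 2000 < 0.05

    def test_single_locus_degenerate(self):
        cfg = SimulationConfig(n_loci=1, n_chromosomes=1,
                               chromosome_length=100_000, seed=2)
        loci = generate_loci(cfg)
        assert len(loci) == 1
        assert 0 < loci["start"].iloc[0] < 100_000

    def test_same_seed_identical(self):
        cfg = SimulationConfig(n_loci=500, n_chromosomes=2,
                               chromosome_length=3_000_000, seed=5)
        pd.testing.assert_frame_equal(generate_loci(cfg), generate_loci(cfg))

    def test_sorted_within_chromosome(self, small_dataset):
        loci, _, _ = small_dataset
        for _, sub in loci.groupby("chrom"):
            assert sub["start"].is_monotonic_increasing

    def test_chromosome_too_short_raises(self):
        cfg = SimulationConfig(n_loci=1000, n_chromosomes=1,
                               chromosome_length=10_000, seed=1)
        with pytest.raises(SizingError):
            generate_loci(cfg)


class TestGenerateCounts:
    def test_no_differential_config_gives_empty_truth(self):
        cfg = SimulationConfig(n_loci=300, n_chromosomes=1,
                               chromosome_length=2_000_000,
                               frac_differential=0.0, n_dmr_blocks=0,
                               n_shared_spikes=0, seed=3)
        loci = generate_loci(cfg)
        _, truth = generate_counts(cfg, loci)
        assert truth.empty

    def test_invalid_frac_differential_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(frac_differential=1.5)

    def test_counts_nonnegative_integers(self, small_dataset):
        _, counts, _ = small_dataset
        assert (counts.hpaii.values >= 0).all()
        assert (counts.mspi.values >= 0).all()
        assert counts.hpaii.values.dtype.kind == "i"

    def test_spiked_effect_recovered_in_scores(self, default_dataset):
        # UN is a hypermethylation group: Con mean minus UN mean at spiked
        # loci should sit near +30 (score decrease in UN).
        _, loci, counts, truth = default_dataset
        mat = compute_scores(counts)
        un_ids = truth.loc[truth["group"] == "UN", "locus_id"]
        con = [s for s in mat.samples if mat.groups[s] == "Con"]
        un = [s for s in mat.samples if mat.groups[s] == "UN"]
        sub = mat.scores.loc[un_ids]
        diff = (sub[con].mean(axis=1) - sub[un].mean(axis=1)).mean()
        assert diff == pytest.approx(30.0, abs=2.0)

    def test_truth_deltas_match_config(self, small_dataset, small_config):
        _, _, truth = small_dataset
        assert set(np.abs(truth["true_delta"])) == {small_config.effect_size}

    def test_dmr_block_loci_flagged_and_contiguous(self, small_dataset,
                                                   small_config):
        loci, _, truth = small_dataset
        pos = loci.set_index("locus_id")
        blocks = truth.dropna(subset=["dmr_block"])
        assert not blocks.empty
        for (_, block_id), sub in blocks.groupby(["group", "dmr_block"]):
            assert len(sub) == small_config.dmr_block_span
            p = pos.loc[sub["locus_id"]]
            assert p["chrom"].nunique() == 1
            assert np.diff(np.sort(p["start"].values)).max() <= 10_000
            # uniform direction within a block
            assert sub["true_delta"].nunique() == 1

    def test_zero_inflated_sample_has_most_zero_loci(self):
        cfg = SimulationConfig(n_loci=2000, n_chromosomes=1,
                               chromosome_length=10_000_000,
                               zero_inflation_sample="ON2", seed=9)
        loci = generate_loci(cfg)
        counts, _ = generate_counts(cfg, loci)
        zero_frac = (counts.hpaii == 0).mean(axis=0)
        assert zero_frac.idxmax() == "ON2"
        assert zero_frac["ON2"] > zero_frac.drop("ON2").max() + 0.1

    def test_null_locus_sd_near_score_sd(self, default_dataset):
        # per-group realized score SD at unspiked loci within 20% of 10
        cfg, _, counts, truth = default_dataset
        mat = compute_scores(counts)
        null = mat.scores.drop(index=set(truth["locus_id"]), errors="ignore")
        for g, _ in cfg.groups:
            cols = [s for s in mat.samples if mat.groups[s] == g]
            sd = null[cols].std(axis=1).mean()
            assert abs(sd - cfg.score_sd) / cfg.score_sd < 0.2

    def test_spiked_group_mean_shift_at_least_half_effect(self, default_dataset):
        cfg, _, counts, truth = default_dataset
        mat = compute_scores(counts)
        con = [s for s in mat.samples if mat.groups[s] == "Con"]
        for g in ("UN", "Old"):
            ids = truth.loc[truth["group"] == g, "locus_id"]
            cols = [s for s in mat.samples if mat.groups[s] == g]
            sub = mat.scores.loc[ids]
            shift = (sub[cols].mean(axis=1) - sub[con].mean(axis=1)).abs()
            # sampling SD of the mean difference is ~6 score units at
            # n=5/6, so ~1% of spiked loci can fall under half-effect
            assert (shift >= cfg.effect_size / 2).mean() > 0.95

    def test_determinism(self, small_config):
        def build():
            rng = np.random.default_rng(small_config.seed)
            loci = generate_loci(small_config, rng)
            return generate_counts(small_config, loci, rng)
        t1, truth1 = build()
        t2, truth2 = build()
        pd.testing.assert_frame_equal(t1.hpaii, t2.hpaii)
        pd.testing.assert_frame_equal(t1.mspi, t2.mspi)
        pd.testing.assert_frame_equal(truth1, truth2)


class TestAnnotation:
    def test_site_counts_match_bruteforce_window_scan(self, small_dataset,
                                                      small_config):
        from helptag_dm.gene_mapping import build_windows
        loci, _, _ = small_dataset
        genes = generate_annotation(small_config, loci)
        windows = build_windows(genes)
        for _, g in windows.sample(25, random_state=0).iterrows():
            on_chrom = loci[loci["chrom"] == g["chrom"]]
            hits = ((on_chrom["end"] > g["window_start"])
                    & (on_chrom["start"] < g["window_end"])).sum()
            assert hits == g["n_hpaii_sites"]

    def test_site_counts_span_order_of_magnitude(self, small_dataset,
                                                 small_config):
        loci, _, _ = small_dataset
        genes = generate_annotation(small_config, loci)
        positive = genes.loc[genes["n_hpaii_sites"] > 0, "n_hpaii_sites"]
        assert positive.max() / positive.min() >= 10

    def test_gene_with_no_overlapping_loci_counts_zero(self):
        from helptag_dm.gene_mapping import build_windows, map_loci
        loci = pd.DataFrame({"locus_id": ["L1"], "chrom": ["chr1"],
                             "start": [1_000_000], "end": [1_000_004]})
        genes = pd.DataFrame({"gene_id": ["G1"], "chrom": ["chr1"],
                              "start": [10_000], "end": [20_000],
                              "strand": ["+"]})
        assoc = map_loci(loci, build_windows(genes))
        assert assoc.empty

    def test_deterministic_gtf(self, small_dataset, small_config, tmp_path):
        from helptag_dm import io as io_mod
        loci, _, _ = small_dataset
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        io_mod.write_gtf(generate_annotation(small_config, loci), p1)
        io_mod.write_gtf(generate_annotation(small_config, loci), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_gtf_roundtrip(self, small_dataset, small_config, tmp_path):
        from helptag_dm import io as io_mod
        loci, _, _ = small_dataset
        genes = generate_annotation(small_config, loci)
        path = tmp_path / "genes.gtf"
        io_mod.write_gtf(genes, path)
        back = io_mod.read_gtf(path)
        pd.testing.assert_frame_equal(
            back, genes[back.columns].reset_index(drop=True))


class TestCtTable:
    def test_triplicates_per_animal_gene(self, small_config):
        ct = generate_ct_table(small_config)
        sizes = ct.groupby(["animal_id", "gene"]).size()
        assert (sizes == 3).all()

    def test_unit_fold_gives_zero_ddct(self):
        cfg = SimulationConfig(
            ct_target_folds={"GeneX": {}}, ct_animal_sd=0.0,
            ct_replicate_sd=0.0, seed=4)
        ct = generate_ct_table(cfg)
        target = ct[ct["gene"] == "GeneX"].groupby("animal_id")["ct"].mean()
        ref = ct[ct["gene"] == "Rps3"].groupby("animal_id")["ct"].mean()
        dct = target - ref
        ddct = dct - dct[[a for a in dct.index if a.startswith("Con")]].mean()
        assert np.allclose(ddct, 0.0, atol=1e-9)

    def test_configured_fold_recovered(self):
        from helptag_dm.expression import ddct_fold_change
        cfg = SimulationConfig(
            ct_target_folds={"GeneX": {"UN": 4.0}}, seed=6)
        ct = generate_ct_table(cfg)
        res = ddct_fold_change(ct, "GeneX", "Rps3", "Con")
        row = res.group_stats.set_index("group")
        assert row.loc["UN", "mean_fold"] == pytest.approx(
            4.0, abs=3 * row.loc["UN", "sem_fold"])
        assert row.loc["Con", "mean_fold"] == pytest.approx(1.0)


class TestGeneSets:
    def test_sets_are_subsets_of_universe(self, small_dataset, small_config):
        loci, _, _ = small_dataset
        genes = generate_annotation(small_config, loci)
        sets = generate_gene_sets(small_config, genes)
        universe = set(genes["gene_id"])
        assert sets
        for members in sets.values():
            assert set(members) <= universe
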