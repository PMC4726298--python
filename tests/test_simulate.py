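"""Generator determinism, planted structure and label consistency."""

import numpy as np
import pytest

from telolnc.models import TIME_POINTS
from telolnc.simulate import (
    PlacementError,
    SimulationConfig,
    _mixed_partner_profile,
    simulate_annotation,
    simulate_candidates,
    simulate_dataset,
    write_dataset,
)


class TestAnnotation:
    def test_no_genes_leaves_chrom_intergenic(self):
        cfg = SimulationConfig(
            n_genes=0, n_known_ncrnas=0, n_gene_overlapping=0,
            n_utr_overlapping=0, n_gene_extension=0, n_known_duplicate=0,
            n_truly_novel=0, n_tml=0, stage_specific_counts=(0,) * 5,
            n_down_decoys=0, pair_r_targets=(),
        )
        ann, genome = simulate_annotation(cfg)
        assert ann.genes == [] and ann.known_ncrnas == []
        assert len(genome["chr1"]) == cfg.chrom_length

    def test_deterministic_given_seed(self):
        a1, g1 = simulate_annotation(SimulationConfig(seed=5))
        a2, g2 = simulate_annotation(SimulationConfig(seed=5))
        assert [(t.id, t.interval) for t in a1.genes] == \
               [(t.id, t.interval) for t in a2.genes]
        assert g1 == g2

    def test_gene_placement_has_no_pairwise_overlap(self):
        ann, _ = simulate_annotation(SimulationConfig(seed=2, n_genes=50,
                                                      chrom_length=500_000))
        genes = ann.genes
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                assert a.interval.overlap_length(b.interval) == 0

    def test_known_ncrnas_are_intergenic(self):
        ann, _ = simulate_annotation(SimulationConfig(seed=3))
        for k in ann.known_ncrnas:
            for g in ann.genes:
                assert k.interval.overlap_length(ann.gene_with_utrs(g)) == 0

    def test_infeasible_packing_raises(self):
        with pytest.raises(PlacementError, match="chrom_length"):
            simulate_annotation(SimulationConfig(n_genes=100, chrom_length=30_000))


class TestCandidates:
    def test_category_counts_by_construction(self):
        cfg = SimulationConfig(seed=1)
        ann, _ = simulate_annotation(cfg)
        candidates, truth = simulate_candidates(ann, cfg)
        counts = truth.candidates["category"].value_counts().to_dict()
        assert counts["truly_novel"] == cfg.n_truly_novel
        assert counts["gene_overlapping"] == cfg.n_gene_overlapping
        assert counts["utr_overlapping"] == cfg.n_utr_overlapping
        assert counts["known_ncRNA_duplicate"] == cfg.n_known_duplicate
        assert counts["gene_extension"] == cfg.n_gene_extension
        assert len(candidates) == cfg.n_candidates

    def test_duplicate_labels_follow_end_rule(self):
        cfg = SimulationConfig(seed=4)
        ann, _ = simulate_annotation(cfg)
        _, truth = simulate_candidates(ann, cfg)
        dups = truth.candidates.query("category == 'known_ncRNA_duplicate'")
        for row in dups.itertuples():
            both_close = row.d5 <= 50 and row.d3 <= 50
            expected = "rejected_known_ncRNA_match" if both_close else "novel"
            assert row.expected_verdict == expected

    def test_truly_novel_clear_of_annotation_and_knowns(self):
        cfg = SimulationConfig(seed=6)
        ann, _ = simulate_annotation(cfg)
        candidates, truth = simulate_candidates(ann, cfg)
        novel_ids = {
            r.transcript_id for r in truth.candidates.itertuples()
            if r.category == "truly_novel"
        }
        for t in candidates:
            if t.id not in novel_ids:
                continue
            for g in ann.genes:
                assert t.interval.overlap_length(ann.gene_with_utrs(g)) == 0
            for k in ann.known_ncrnas:
                d5 = abs(t.interval.start - k.interval.start)
                d3 = abs(t.interval.end - k.interval.end)
                assert t.chrom != k.chrom or max(d5, d3) > 50


class TestExpression:
    def test_zero_noise_fold_gives_exact_de(self, zero_noise_dataset):
        ds = zero_noise_dataset
        expr = ds.expression
        folds = ds.truth.fold_log2
        tid = sorted(ds.truth.tml_ids())[0]
        means = expr.replicate_means(tid)
        ratio = np.log2(means["mut"].to_numpy() / means["wt"].to_numpy())
        assert np.allclose(ratio, folds.loc[tid].to_numpy(), atol=1e-9)

    def test_planted_tml_profiles_satisfy_definition(self, default_dataset):
        folds = default_dataset.truth.fold_log2
        for tid in default_dataset.truth.tml_ids():
            f = folds.loc[tid].to_numpy()
            assert (f >= 0).all() and (f >= 2).any()

    def test_stage_specific_detected_only_in_stage(self, zero_noise_dataset):
        ds = zero_noise_dataset
        cands = ds.truth.candidates
        stage_rows = cands[cands["profile_class"] == "stage_specific"]
        threshold = ds.config.detection_threshold
        for row in stage_rows.itertuples():
            stage = int(row.stage_set)
            means = ds.expression.replicate_means(row.transcript_id)["mut"]
            for tp in TIME_POINTS:
                if tp == stage:
                    assert means.loc[tp] >= threshold
                else:
                    assert means.loc[tp] < threshold

    def test_mixed_profile_hits_target_correlation_exactly(self):
        rng = np.random.default_rng(0)
        base = np.array([2.5, 0.0, 3.0, 0.0, 1.5])
        for r_target in (1.0, 0.9, -0.96, 0.0):
            g = _mixed_partner_profile(base, r_target, 1.0, rng)
            r = np.corrcoef(base, g)[0, 1]
            assert r == pytest.approx(r_target, abs=1e-9)

    def test_mean_sample_correlation_near_target_over_replicates(self):
        # 200 regenerations of a planted r=0.9 pair under mild measurement
        # noise: the mean sample r stays within +/-0.05 of the target
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(200):
            base = np.zeros(5)
            ups = rng.random(5) < 0.6
            if not ups.any():
                ups[rng.integers(5)] = True
            base[ups] = rng.uniform(2.0, 4.5, ups.sum())
            g = _mixed_partner_profile(base, 0.9, 1.0, rng)
            noise = 0.05
            x = base + rng.normal(0, noise, 5)
            y = g + rng.normal(0, noise, 5)
            rs.append(np.corrcoef(x, y)[0, 1])
        assert abs(np.mean(rs) - 0.9) < 0.05

    def test_planted_pairs_unique_and_adjacent(self, default_dataset):
        pairs = default_dataset.truth.pairs
        assert pairs["gene_id"].is_unique
        assert pairs["lncrna_id"].is_unique
        assert len(pairs) == len(default_dataset.config.pair_r_targets)


class TestDatasetOutput:
    def test_write_dataset_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(seed=9)
        for d in ("d1", "d2"):
            write_dataset(simulate_dataset(cfg), tmp_path / d)
        for name in ("genes.gtf", "known_ncrnas.gtf", "candidates.gtf",
                     "genome.fa", "transcripts.fa", "expression.tsv",
                     "utr_extents.tsv", "terms.tsv", "truth_candidates.tsv",
                     "truth_pairs.tsv", "truth_folds.tsv"):
            b1 = (tmp_path / "d1" / name).read_bytes()
            b2 = (tmp_path / "d2" / name).read_bytes()
            assert b1 == b2, name

    def test_emitted_files_round_trip_through_io(self, tmp_path, default_dataset):
        from telolnc import io_formats

        write_dataset(default_dataset, tmp_path / "ds")
        ann = io_formats.read_annotation(
            tmp_path / "ds" / "genes.gtf",
            tmp_path / "ds" / "known_ncrnas.gtf",
            tmp_path / "ds" / "utr_extents.tsv",
        )
        assert len(ann.genes) == len(default_dataset.annotation.genes)
        cands = io_formats.read_transcripts_gtf(tmp_path / "ds" / "candidates.gtf")
        assert {t.id for t in cands} == {t.id for t in default_dataset.candidates}
        expr = io_formats.read_expression_tsv(tmp_path / "ds" / "expression.tsv")
        assert len(expr) == len(default_dataset.expression)

    def test_noncoding_candidates_carry_no_long_orf(self, default_dataset):
        from telolnc.coding import find_longest_orf

        ds = default_dataset
        for row in ds.truth.candidates.itertuples():
            if row.category in ("truly_novel", "known_ncRNA_duplicate"):
                orf, _, _ = find_longest_orf(ds.sequences[row.transcript_id], frames=3)
                assert orf < ds.config.min_orf_nt


class TestConfigValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=-1)

    def test_overfull_structure_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_truly_novel=3, n_tml=8)

    def test_bad_correlation_target_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(pair_r_targets=(1.5,))
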