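"""Adjacency, Pearson correlation with small-n p-values, pair tables and
the clustered genome-wide correlation matrix."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telolnc.correlation import (
    NeighborPair,
    ZeroVarianceError,
    find_adjacent,
    genome_wide_matrix,
    neighbor_correlation_table,
    pearson_with_p,
)
from telolnc.expression import DifferentialProfile
from telolnc.models import AnnotationSet, GenomicInterval, Source, TranscriptModel


def tx(tid, start, end, chrom="chr1", strand="+", source=Source.ANNOTATED_GENE):
    return TranscriptModel(tid, GenomicInterval(chrom, start, end, strand), source=source)


def prof(tid, de):
    de = np.asarray(de, dtype=float)
    return DifferentialProfile(tid, de, np.ones(len(de), bool),
                               np.ones(len(de)), np.ones(len(de)))


class TestFindAdjacent:
    def test_two_sided_example(self):
        ann = AnnotationSet(genes=[tx("gL", 0, 1000), tx("gR", 3000, 4000)])
        lnc = tx("lnc", 1500, 2000, source=Source.ASSEMBLED)
        left, right = find_adjacent(lnc, ann)
        assert (left.gene_id, left.gap, left.side) == ("gL", 500, "5p")
        assert (right.gene_id, right.gap, right.side) == ("gR", 1000, "3p")

    def test_first_feature_on_chrom_has_only_downstream_neighbor(self):
        ann = AnnotationSet(genes=[tx("g", 3000, 4000)])
        left, right = find_adjacent(tx("lnc", 100, 500, source=Source.ASSEMBLED), ann)
        assert left is None
        assert right.gene_id == "g"

    def test_overlapping_gene_violates_precondition(self):
        ann = AnnotationSet(genes=[tx("g", 0, 1000)])
        with pytest.raises(ValueError, match="overlaps"):
            find_adjacent(tx("lnc", 900, 1200, source=Source.ASSEMBLED), ann)

    def test_matches_bruteforce_on_random_layouts(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            starts = np.sort(rng.choice(np.arange(0, 50_000, 100), 20, replace=False))
            genes = [tx(f"g{i}", int(s), int(s) + 80) for i, s in enumerate(starts)]
            ann = AnnotationSet(genes=genes)
            pos = int(rng.integers(0, 49_000))
            lnc = tx("lnc", pos, pos + 50, source=Source.ASSEMBLED)
            if any(lnc.interval.overlap_length(g.interval) for g in genes):
                continue
            left, right = find_adjacent(lnc, ann)
            lefts = [g for g in genes if g.interval.end <= lnc.interval.start]
            rights = [g for g in genes if g.interval.start >= lnc.interval.end]
            if lefts:
                expect = min(lefts, key=lambda g: lnc.interval.start - g.interval.end)
                assert left.gene_id == expect.id
            else:
                assert left is None
            if rights:
                expect = min(rights, key=lambda g: g.interval.start - lnc.interval.end)
                assert right.gene_id == expect.id
            else:
                assert right is None


class TestPearsonWithP:
    def test_perfect_linear_relation(self):
        n, r, r2, p = pearson_with_p([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert (n, r, r2) == (5, 1.0, 1.0)
        assert p == 0.0  # limiting value at |r| = 1

    def test_worked_small_sample_value(self):
        n, r, r2, p = pearson_with_p([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert r == pytest.approx(0.9)
        assert p == pytest.approx(0.0374, abs=5e-4)

    def test_orthogonal_vectors_give_r_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # sum((x-xbar)*(y-ybar)) = 0
        n, r, r2, p = pearson_with_p(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert pearson_with_p(x, y) == pearson_with_p(y, x)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(size=6)
        _, r0, _, _ = pearson_with_p(x, y)
        _, r_pos, _, _ = pearson_with_p(a * x + b, y)
        _, r_neg, _, _ = pearson_with_p(-a * x + b, y)
        assert r_pos == pytest.approx(r0, abs=1e-9)
        assert r_neg == pytest.approx(-r0, abs=1e-9)

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroVarianceError):
            pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])

    def test_tracks_exact_permutation_null_without_bias(self):
        # Two-sided t-transform p vs exhaustive permutation over 5! orderings.
        # At n=5 the two differ case by case (the permutation null is lumpy),
        # but the t transform must track it with no systematic bias and near
        # perfect rank agreement.
        from scipy.stats import spearmanr

        rng = np.random.default_rng(8)
        pts, perms_p = [], []
        for _ in range(30):
            x, y = rng.normal(size=5), rng.normal(size=5)
            _, r_obs, _, p_t = pearson_with_p(x, y)
            count = sum(
                1 for perm in itertools.permutations(range(5))
                if abs(pearson_with_p(x, y[list(perm)])[1]) >= abs(r_obs) - 1e-12
            )
            pts.append(p_t)
            perms_p.append(count / 120)
        assert abs(np.mean(np.array(pts) - np.array(perms_p))) <= 0.03
        assert spearmanr(pts, perms_p).statistic >= 0.95


class TestNeighborCorrelationTable:
    def make_profiles(self, pairs_de):
        return {tid: prof(tid, de) for tid, de in pairs_de.items()}

    def test_perfectly_correlated_pair_is_significant(self):
        profiles = self.make_profiles({
            "lnc": [0, 1, 2, 3, 4], "g": [0, 2, 4, 6, 8],
        })
        table = neighbor_correlation_table(
            profiles, [NeighborPair("lnc", "g", "5p", 100)]
        )
        row = table.iloc[0]
        assert row.r2 == pytest.approx(1.0)
        assert bool(row.significant)
        assert row.sign == "positive"

    def test_anticorrelated_planted_pair(self, zero_noise_dataset):
        from telolnc.expression import profiles_for

        ds = zero_noise_dataset
        neg = ds.truth.pairs.query("r_target < 0")
        assert len(neg) > 0
        ids = list(neg["lncrna_id"]) + list(neg["gene_id"])
        profiles = profiles_for(ds.expression, ids, pseudocount=0.0)
        pairs = [NeighborPair(r.lncrna_id, r.gene_id, r.side, r.gap)
                 for r in neg.itertuples()]
        table = neighbor_correlation_table(profiles, pairs)
        merged = table.merge(neg, on=["lncrna_id", "gene_id"])
        assert (merged["sign"] == "negative").all()
        # pseudocount-free profiles reproduce the planted correlation exactly
        assert np.allclose(merged["r"], merged["r_target"], atol=1e-9)

    def test_missing_profile_skips_pair(self):
        profiles = self.make_profiles({"lnc": [0, 1, 2, 3, 4]})
        table = neighbor_correlation_table(
            profiles, [NeighborPair("lnc", "absent", "5p", 10)]
        )
        assert len(table) == 0

    def test_strong_flag_monotone_in_band_width(self):
        rng = np.random.default_rng(4)
        profiles = {f"x{i}": prof(f"x{i}", rng.normal(size=5)) for i in range(20)}
        pairs = [NeighborPair(f"x{i}", f"x{i+10}", "5p", 1) for i in range(10)]
        narrow = neighbor_correlation_table(profiles, pairs, strong_band=(0.85, 0.95))
        wide = neighbor_correlation_table(profiles, pairs, strong_band=(0.5, 1.0))
        assert narrow["strong"].sum() <= wide["strong"].sum()

    def test_replicates_mode_uses_ten_observations(self, default_dataset):
        from telolnc.expression import profiles_for

        ds = default_dataset
        pair = ds.truth.pairs.iloc[0]
        ids = [pair.lncrna_id, pair.gene_id]
        profiles = profiles_for(ds.expression, ids)
        table = neighbor_correlation_table(
            profiles, [NeighborPair(pair.lncrna_id, pair.gene_id, pair.side, pair.gap)],
            mode="replicates", expr=ds.expression,
        )
        assert table.iloc[0]["n"] == 10


class TestGenomeWideMatrix:
    def test_identical_profiles_are_adjacent_with_unit_correlation(self):
        lnc = {"a": prof("a", [0, 1, 2, 1, 0]), "b": prof("b", [0, 1, 2, 1, 0]),
               "c": prof("c", [3, -1, 0, 2, 5])}
        genes = {"g1": prof("g1", [1, 0, 2, 4, 1]), "g2": prof("g2", [5, 4, 3, 2, 1])}
        matrix, row_order, _ = genome_wide_matrix(lnc, genes)
        assert np.allclose(matrix.loc["a"], matrix.loc["b"])
        ia, ib = row_order.index("a"), row_order.index("b")
        assert abs(ia - ib) == 1

    def test_profile_against_itself_has_unit_correlation(self):
        shared = [0.0, 1.5, -2.0, 0.5, 3.0]
        lnc = {"a": prof("a", shared), "b": prof("b", [1, 0, 0, 2, 1])}
        genes = {"a_as_gene": prof("a_as_gene", shared),
                 "g": prof("g", [2, 2, 1, 0, 4])}
        matrix, _, _ = genome_wide_matrix(lnc, genes)
        assert matrix.loc["a", "a_as_gene"] == pytest.approx(1.0)

    def test_three_item_linkage_matches_manual_average_linkage(self):
        # hand-executed average linkage on 1 - r distances
        vecs = {
            "a": np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
            "b": np.array([0.1, 1.2, 1.9, 3.2, 3.8]),   # ~r=1 with a
            "c": np.array([4.0, 1.0, 3.0, 0.0, 2.0]),   # unrelated
        }
        ids = sorted(vecs)
        d = {}
        for u, v in itertools.combinations(ids, 2):
            r = np.corrcoef(vecs[u], vecs[v])[0, 1]
            d[(u, v)] = 1 - r
        first_merge = min(d, key=d.get)
        assert first_merge == ("a", "b")  # manual: closest pair merges first
        lnc = {k: prof(k, v) for k, v in vecs.items()}
        genes = {"g1": prof("g1", [1, 2, 0, 1, 3]), "g2": prof("g2", [0, 2, 2, 0, 1])}
        _, row_order, _ = genome_wide_matrix(lnc, genes)
        ia, ib = row_order.index("a"), row_order.index("b")
        assert abs(ia - ib) == 1

    def test_zero_variance_profile_dropped(self):
        lnc = {"a": prof("a", [1, 1, 1, 1, 1]), "b": prof("b", [0, 1, 0, 2, 1]),
               "c": prof("c", [5, 0, 3, 1, 2])}
        genes = {"g1": prof("g1", [1, 0, 2, 4, 1]), "g2": prof("g2", [5, 4, 3, 2, 1])}
        matrix, _, _ = genome_wide_matrix(lnc, genes)
        assert "a" not in matrix.index

    def test_entries_within_unit_interval(self, zero_noise_dataset):
        from telolnc.expression import profiles_for

        ds = zero_noise_dataset
        lnc_ids = sorted(ds.truth.lncrna_ids())[:6]
        # planted partner genes carry non-constant noise-free profiles
        gene_ids = sorted(ds.truth.pairs["gene_id"])
        lnc = profiles_for(ds.expression, lnc_ids)
        genes = profiles_for(ds.expression, gene_ids)
        matrix, _, _ = genome_wide_matrix(lnc, genes)
        assert ((matrix.values >= -1) & (matrix.values <= 1)).all()
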