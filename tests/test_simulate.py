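"""Synthetic-data generators: determinism, planted marginals, truth consistency."""

import math

import numpy as np
import pandas as pd
import pytest

from metamotif.ingest import PADJ_CUTOFFS, filter_and_rank
from metamotif.simulate import (
    MetaSimConfig,
    PromoterSimConfig,
    simulate_meta_tables,
    simulate_ppi_edges,
    simulate_promoter_corpus,
    simulate_pwm_library,
)


class TestMetaTables:
    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            MetaSimConfig(penetrance=1.5)
        with pytest.raises(ValueError):
            MetaSimConfig(n_genes=100, n_true_up=80, n_true_down=40)

    def test_determinism(self):
        cfg = MetaSimConfig(n_genes=300, n_studies=4, n_true_up=20, n_true_down=20, seed=5)
        t1, tr1 = simulate_meta_tables(cfg)
        t2, tr2 = simulate_meta_tables(cfg)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.table, b.table)
        assert tr1.true_up_genes == tr2.true_up_genes

    def test_true_degs_pass_filter_at_penetrance_rate(self):
        cfg = MetaSimConfig(
            n_genes=5000, n_studies=10, n_true_up=100, n_true_down=0,
            penetrance=0.7, missing_rate=0.0, seed=1,
        )
        tables, truth = simulate_meta_tables(cfg)
        passes = 0
        for t in tables:
            up, _ = filter_and_rank(t, truth.gene_biotypes)
            passes += len(truth.true_up_genes & set(up.genes))
        # Binomial(100 genes x 10 studies, 0.7): mean 700, 3 sd ~ 43
        assert abs(passes - 700) <= 3 * np.sqrt(1000 * 0.7 * 0.3)

    def test_null_tables_pass_rate_matches_marginals(self):
        cfg = MetaSimConfig(
            n_genes=8000, n_studies=2, n_true_up=0, n_true_down=0,
            missing_rate=0.0, noncoding_fraction=0.0, platform_mix=0.0, seed=3,
        )
        tables, truth = simulate_meta_tables(cfg)
        # P(pass) = P(U < 0.05) * P(|N(0,0.15)| > log2 1.25)
        p_fc = 2 * (1 - 0.5 * (1 + math.erf(np.log2(1.25) / 0.15 / np.sqrt(2))))
        expected = 0.05 * p_fc
        for t in tables:
            up, down = filter_and_rank(t, truth.gene_biotypes)
            frac = (len(up) + len(down)) / 8000
            assert abs(frac - expected) <= 3 * np.sqrt(expected * (1 - expected) / 8000)

    def test_missingness_recorded_in_universe(self):
        cfg = MetaSimConfig(n_genes=1000, n_studies=3, missing_rate=0.2,
                            n_true_up=10, n_true_down=10, seed=9)
        tables, truth = simulate_meta_tables(cfg)
        for t in tables:
            assert set(t.table["gene_id"]) == set(t.measured_universe)
            assert abs(len(t.measured_universe) - 800) <= 3 * np.sqrt(1000 * 0.2 * 0.8)
        # every true DEG appears in at least one study
        measured_anywhere = set().union(*(t.measured_universe for t in tables))
        assert truth.true_up_genes <= measured_anywhere

    def test_platform_mix(self):
        cfg = MetaSimConfig(n_genes=100, n_studies=10, n_true_up=5, n_true_down=5,
                            platform_mix=0.3, seed=2)
        tables, _ = simulate_meta_tables(cfg)
        assert sum(t.platform == "microarray" for t in tables) == 3
        assert all(t.platform in PADJ_CUTOFFS for t in tables)


class TestPromoterCorpus:
    def test_planted_prevalence_and_truth_consistency(self, pwm_library):
        cfg = PromoterSimConfig(n_deg=300, n_ref=100, planted_prevalence=0.4,
                                background_prevalence=0.0, seed=4)
        corpus, truth = simulate_promoter_corpus(cfg, pwm_library)
        planted_deg = [k for k in truth.planted_site_coordinates if k.startswith("DEGP")]
        assert abs(len(planted_deg) - 120) <= 3 * np.sqrt(300 * 0.4 * 0.6)
        by_id = {p.matrix_id: p for p in pwm_library}
        for pid, intervals in truth.planted_site_coordinates.items():
            seq = corpus.all[pid]
            for start, end, mid, strand in intervals:
                assert 0 <= start < end <= len(seq)
                assert end - start == by_id[mid].length

    def test_zero_prevalence_plants_nothing(self, pwm_library):
        cfg = PromoterSimConfig(n_deg=50, n_ref=50, planted_prevalence=0.0,
                                background_prevalence=0.0, seed=4)
        _, truth = simulate_promoter_corpus(cfg, pwm_library)
        assert truth.planted_site_coordinates == {}

    def test_gc_content_of_background(self, pwm_library):
        cfg = PromoterSimConfig(n_deg=0, n_ref=200, gc_content=0.5,
                                background_prevalence=0.0, seed=4)
        corpus, _ = simulate_promoter_corpus(cfg, pwm_library)
        joined = "".join(corpus.ref.values())
        n = len(joined)
        gc = (joined.count("G") + joined.count("C")) / n
        assert abs(gc - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_motif_longer_than_promoter_rejected(self, pwm_library):
        cfg = PromoterSimConfig(n_deg=5, n_ref=0, promoter_length=4, seed=4)
        with pytest.raises(ValueError, match="shorter than"):
            simulate_promoter_corpus(cfg, pwm_library)

    def test_determinism(self, pwm_library):
        cfg = PromoterSimConfig(n_deg=20, n_ref=20, seed=8)
        c1, t1 = simulate_promoter_corpus(cfg, pwm_library)
        c2, t2 = simulate_promoter_corpus(cfg, pwm_library)
        assert c1.all == c2.all
        assert t1.planted_site_coordinates == t2.planted_site_coordinates


class TestPwmLibrary:
    def test_sizes_and_lengths(self):
        pwms = simulate_pwm_library(5, length_range=(8, 8), seed=1)
        assert len(pwms) == 5
        assert all(p.length == 8 for p in pwms)
        assert all((p.counts > 0).all() for p in pwms)

    def test_entropy_extremes(self):
        pwms = simulate_pwm_library(4, seed=1)
        def mean_entropy(p):
            pr = p.probabilities
            return float(-(pr * np.log2(pr)).sum(axis=1).mean())
        assert mean_entropy(pwms[0]) < mean_entropy(pwms[-1])

    def test_determinism(self):
        a = simulate_pwm_library(3, seed=6)
        b = simulate_pwm_library(3, seed=6)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.counts, y.counts)

    def test_length_below_four_rejected(self):
        with pytest.raises(ValueError):
            simulate_pwm_library(2, length_range=(3, 5), seed=0)


class TestPpiEdges:
    def test_disjoint_triangles(self):
        edges, truth = simulate_ppi_edges([3, 3], p_within=1.0, p_between=0.0, seed=0)
        assert len(edges) == 6  # two complete triangles
        groups = {}
        for n, c in truth.planted_clusters.items():
            groups.setdefault(c, set()).add(n)
        for _, row in edges.iterrows():
            assert truth.planted_clusters[row.node_a] == truth.planted_clusters[row.node_b]

    def test_complete_graph(self):
        edges, _ = simulate_ppi_edges([5], p_within=1.0, p_between=0.0, seed=0)
        assert len(edges) == 10

    def test_requires_assortativity(self):
        with pytest.raises(ValueError):
            simulate_ppi_edges([3, 3], p_within=0.2, p_between=0.5, seed=0)

    def test_determinism(self):
        e1, _ = simulate_ppi_edges([4, 4], p_within=0.8, p_between=0.1, seed=3)
        e2, _ = simulate_ppi_edges([4, 4], p_within=0.8, p_between=0.1, seed=3)
        pd.testing.assert_frame_equal(e1, e2)
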