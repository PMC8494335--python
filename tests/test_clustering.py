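"""Window and HMM cluster callers, summaries, and genotype comparisons."""

from dataclasses import replace
from itertools import product

import numpy as np
import pytest

from irmut.clustering import (
    ClusterCall,
    HmmParams,
    _geometric_logpmf,
    _viterbi_two_state,
    call_clusters_hmm,
    call_clusters_window,
    cluster_input_positions,
    clustering_dose_model,
    compare_clustering,
    summarize_clusters,
    write_clusters_bed,
)
from irmut.io_formats import SampleMeta
from irmut.synthetic_data import default_wildtype_config, simulate_experiment


def linkage_oracle(positions, window):
    """O(n^2) transitive linkage: clusters = connected components of |pi-pj|<=w."""
    pos = sorted(positions)
    n = len(pos)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(pos[i] - pos[j]) <= window:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(pos[i])
    return sorted(tuple(sorted(c)) for c in comps.values() if len(c) >= 2)


class TestWindowCaller:
    def test_single_linked_pair(self):
        calls = call_clusters_window({"c": np.array([100, 600, 1_000_000])})
        assert len(calls) == 1
        assert calls[0].positions == (100, 600) and calls[0].span_bp == 500

    def test_chain_links_transitively(self):
        calls = call_clusters_window({"c": np.array([1, 901, 1801, 2701])})
        assert len(calls) == 1 and calls[0].n == 4

    def test_empty_input(self):
        assert call_clusters_window({}) == []
        assert call_clusters_window({"c": np.array([], dtype=int)}) == []

    def test_matches_linkage_oracle_on_random_instances(self):
        rng = np.random.default_rng(314)
        for _ in range(25):
            n = int(rng.integers(2, 200))
            pos = np.unique(rng.integers(1, 200_000, size=n))
            calls = call_clusters_window({"c": pos})
            got = sorted(c.positions for c in calls)
            assert got == linkage_oracle(pos.tolist(), 1000)

    def test_translation_invariance(self):
        rng = np.random.default_rng(99)
        pos = np.unique(rng.integers(1, 100_000, 50))
        a = call_clusters_window({"c": pos})
        b = call_clusters_window({"c": pos + 12345})
        assert [tuple(p - 12345 for p in c.positions) for c in b] == [c.positions for c in a]

    def test_no_cross_chromosome_clusters(self):
        calls = call_clusters_window({"c1": np.array([100]), "c2": np.array([150])})
        assert calls == []

    def test_each_position_in_at_most_one_cluster(self):
        rng = np.random.default_rng(7)
        pos = np.unique(rng.integers(1, 50_000, 300))
        calls = call_clusters_window({"c": pos})
        members = [p for c in calls for p in c.positions]
        assert len(members) == len(set(members))


class TestHmmCaller:
    def test_far_gaps_yield_no_clusters(self):
        pos = {"c": np.array([1, 2_000_000, 4_000_000, 6_000_000])}
        assert call_clusters_hmm(pos, genome_length=10_000_000) == []

    def test_close_pair_amid_megabase_gaps_called(self):
        pos = {"c": np.array([100, 1_000_000, 1_000_005, 3_000_000])}
        calls = call_clusters_hmm(pos, genome_length=5_000_000)
        assert [c.positions for c in calls] == [(1_000_000, 1_000_005)]

    def test_viterbi_equals_exhaustive_enumeration(self):
        params = HmmParams()

        def brute(gaps, bg):
            T = len(gaps)
            lt = np.log([[1 - params.p_enter, params.p_enter],
                         [params.p_exit, 1 - params.p_exit]])
            pi1 = params.p_enter / (params.p_enter + params.p_exit)
            ls = np.log([1 - pi1, pi1])
            emit = np.stack([_geometric_logpmf(gaps, bg),
                             _geometric_logpmf(gaps, params.mean_gap_clustered)], axis=1)
            best, best_lp = None, -np.inf
            for path in product([0, 1], repeat=T):
                lp = ls[path[0]] + emit[0, path[0]]
                for t in range(1, T):
                    lp += lt[path[t - 1]][path[t]] + emit[t, path[t]]
                if lp > best_lp:
                    best_lp, best = lp, path
            return np.array(best)

        rng = np.random.default_rng(11)
        for _ in range(60):
            T = int(rng.integers(1, 12))
            gaps = rng.choice([2, 5, 20, 80, 400, 2000, 50_000], size=T).astype(float)
            assert np.array_equal(_viterbi_two_state(gaps, params, 20_000.0),
                                  brute(gaps, 20_000.0))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HmmParams(p_enter=0.0)
        with pytest.raises(ValueError):
            HmmParams(mean_gap_clustered=float("inf"))


class TestSummaries:
    def _metas(self):
        return [SampleMeta(f"s{d}_{r}", "wild-type", float(d), r)
                for d in (0, 40, 80) for r in (1, 2)]

    def test_no_clusters(self):
        metas = self._metas()
        s = summarize_clusters({m.sample_id: [] for m in metas},
                               {m.sample_id: 10 for m in metas}, metas)["wild-type"]
        assert s.prop_clustered == 0.0
        assert s.clusters_per_80gy_per_genome == 0.0

    def test_prop_clustered_halves_when_burden_doubles(self):
        metas = self._metas()
        calls = {m.sample_id: [ClusterCall("c", (100, 110), m.sample_id)] for m in metas}
        sparse = summarize_clusters(calls, {m.sample_id: 40 for m in metas}, metas)
        dense = summarize_clusters(calls, {m.sample_id: 80 for m in metas}, metas)
        assert dense["wild-type"].prop_clustered == pytest.approx(
            sparse["wild-type"].prop_clustered / 2)

    def test_planted_fraction_recovered(self, wildtype_experiment):
        _, records, metas, _, _ = wildtype_experiment
        by_sample: dict[str, list] = {m.sample_id: [] for m in metas}
        for r in records:
            by_sample[r.sample_id].append(r)
        calls, eligible = {}, {}
        for m in metas:
            pos = cluster_input_positions(by_sample[m.sample_id])
            calls[m.sample_id] = call_clusters_window(pos, sample_id=m.sample_id)
            eligible[m.sample_id] = sum(len(p) for p in pos.values())
        s = summarize_clusters(calls, eligible, metas)["wild-type"]
        assert abs(s.prop_clustered - 0.06) < 0.03
        assert 2 <= s.size_median <= 3
        assert 5 <= s.span_median <= 40

    def test_bed_output_is_zero_based_half_open(self, tmp_path):
        p = tmp_path / "c.bed"
        write_clusters_bed([ClusterCall("chrI", (100, 115), "s")], p)
        assert p.read_text() == "chrI\t99\t115\t2\n"


class TestDoseModel:
    def test_constant_response_slope_zero(self):
        fit = clustering_dose_model([0, 0, 40, 40, 80, 80], [0.05] * 6)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        doses = [0, 20, 40, 60, 80]
        fit = clustering_dose_model(doses, [0.001 * d for d in doses])
        assert fit.slope == pytest.approx(0.001)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(8)
        d = np.repeat([0.0, 20, 40, 60, 80], 3)
        y = 0.01 + 0.0005 * d + rng.normal(0, 0.01, d.size)
        fit = clustering_dose_model(d, y)
        X = np.column_stack([np.ones_like(d), d])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0])
        assert fit.slope == pytest.approx(beta[1])

    def test_too_few_dose_levels(self):
        with pytest.raises(ValueError):
            clustering_dose_model([0, 0, 80, 80], [0.1, 0.2, 0.3, 0.4])


def _cluster_rate(cfg, genome=None):
    records, metas, genome = simulate_experiment(cfg, genome=genome)
    by_sample: dict[str, list] = {m.sample_id: [] for m in metas}
    for r in records:
        by_sample[r.sample_id].append(r)
    calls, eligible = {}, {}
    for m in metas:
        pos = cluster_input_positions(by_sample[m.sample_id])
        calls[m.sample_id] = call_clusters_window(pos, sample_id=m.sample_id)
        eligible[m.sample_id] = sum(len(p) for p in pos.values())
    s = summarize_clusters(calls, eligible, metas)
    g = next(iter(s))
    return s[g].clusters_per_80gy_per_genome, s[g].se_clusters_per_80gy


class TestCompareClustering:
    def test_equal_rates_z_zero(self):
        res = compare_clustering({"wild-type": (1.2, 0.2), "mut": (1.2, 0.2)})
        assert res[0].z == 0.0 and res[0].q == pytest.approx(1.0)

    def test_missing_wildtype_is_error(self):
        with pytest.raises(ValueError):
            compare_clustering({"mut": (1.0, 0.1)})

    def test_null_calibration_identical_clustering(self, small_genome_config):
        """Genotypes with identical planted clustering rarely reach q<0.05."""
        significant = 0
        n_runs = 15
        for rep in range(n_runs):
            cfg = replace(small_genome_config, seed=600 + rep)
            r_wt, se_wt = _cluster_rate(cfg)
            cfg2 = replace(cfg, seed=9000 + rep)
            r_g, se_g = _cluster_rate(cfg2)
            if se_wt > 0 and se_g > 0:
                res = compare_clustering({"wild-type": (r_wt, se_wt), "mut": (r_g, se_g)})
                significant += res[0].q < 0.05
        assert significant <= 1

    def test_planted_excess_clustering_detected(self, small_genome_config):
        cfg_wt = replace(small_genome_config, seed=41, replicates_per_dose=6)
        r_wt, se_wt = _cluster_rate(cfg_wt)
        cfg_mut = replace(small_genome_config, seed=42, replicates_per_dose=6,
                          cluster_fraction=0.30)
        r_mut, se_mut = _cluster_rate(cfg_mut)
        res = compare_clustering({"wild-type": (r_wt, se_wt), "mut": (r_mut, se_mut)})
        assert res[0].direction == "up" and res[0].q < 0.05
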