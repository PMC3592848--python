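import itertools
import math

import numpy as np
import pytest

from pathassoc.artp import (
    ArtpResult,
    PermutationPValueMatrix,
    TruncationSet,
    artp_combine,
    build_permutation_matrix,
    pathway_analysis,
    rtp_statistic,
)
from pathassoc.association import ModelSpec, trend_p_matrix
from pathassoc.synthetic_cohort import BlockSpec, CohortConfig, EffectSpec, simulate_cohort
from tests.conftest import make_dataset


class TestRtpStatistic:
    def test_all_ones_is_zero(self):
        assert rtp_statistic([1.0, 1.0, 1.0], 2) == 0.0

    def test_two_smallest_product(self):
        assert rtp_statistic([0.1, 0.5], 2) == pytest.approx(math.log(0.05))

    def test_nonincreasing_in_truncation(self, rng):
        p = rng.uniform(1e-6, 1, 10)
        stats = [rtp_statistic(p, j) for j in range(1, 11)]
        assert all(b <= a for a, b in zip(stats, stats[1:]))

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            rtp_statistic([0.0, 0.5], 1)


class TestTruncationSet:
    def test_capped_at_group_size(self):
        J = TruncationSet((1, 3, 5, 10))
        assert J.capped(4) == (1, 3)
        assert J.capped(20) == (1, 3, 5, 10)

    def test_unordered_rejected(self):
        with pytest.raises(ValueError):
            TruncationSet((3, 1))


def artp_oracle(values: np.ndarray, member_idx: list[int], pts: list[int]):
    """Literal two-step ARTP definition in plain loops: per-row RTP
    statistics, rank-estimated significances, adaptive minimum, and the
    final rank of the observed row."""
    B1 = values.shape[0]
    min_p = []
    for b in range(B1):
        ps = sorted(values[b, j] for j in member_idx)
        s_js = []
        for j in pts:
            w_b = sum(math.log(x) for x in ps[:j])
            count = 0
            for b2 in range(B1):
                if b2 == b:
                    continue
                ps2 = sorted(values[b2, jj] for jj in member_idx)
                w2 = sum(math.log(x) for x in ps2[:j])
                if w2 <= w_b:
                    count += 1
            s_js.append((1 + count) / B1)
        min_p.append(min(s_js))
    group_p = (1 + sum(1 for b in range(1, B1) if min_p[b] <= min_p[0])) / B1
    return group_p, min_p


class TestArtpCombine:
    def test_single_member_group_reduces_to_marginal(self, rng):
        B = 99
        vals = np.clip(rng.uniform(size=(B + 1, 1)), 1 / (B + 1), 1)
        M = PermutationPValueMatrix(vals, ("a",), seed=0, B=B)
        res, _ = artp_combine(M, {"g": ["a"]}, TruncationSet((1,)))
        # with j=1 the statistic is monotone in the member p, so the group p
        # is the observed p's permutation rank
        expect = (1 + np.sum(vals[1:, 0] <= vals[0, 0])) / (B + 1)
        assert res["g"].p == pytest.approx(expect)

    def test_matches_literal_definition(self, rng):
        B = 60
        vals = np.clip(rng.uniform(size=(B + 1, 5)), 1 / (B + 1), 1)
        M = PermutationPValueMatrix(vals, tuple("abcde"), seed=0, B=B)
        res, next_M = artp_combine(M, {"g": list("abcde")}, TruncationSet((1, 2, 5)))
        want_p, want_min = artp_oracle(vals, [0, 1, 2, 3, 4], [1, 2, 5])
        assert res["g"].p == pytest.approx(want_p, abs=1e-12)
        assert np.allclose(next_M.values[:, 0], want_min, atol=1e-12)

    def test_result_in_lattice_bounds(self, rng):
        B = 40
        vals = np.clip(rng.uniform(size=(B + 1, 3)), 1 / (B + 1), 1)
        M = PermutationPValueMatrix(vals, ("a", "b", "c"), seed=0, B=B)
        res, next_M = artp_combine(M, {"g": ["a", "b", "c"]})
        assert 1 / (B + 1) <= res["g"].p <= 1.0
        assert np.all(next_M.values >= 1 / (B + 1)) and np.all(next_M.values <= 1.0)

    def test_empty_group_rejected(self, rng):
        M = PermutationPValueMatrix(np.full((3, 1), 0.5), ("a",), seed=0, B=2)
        with pytest.raises(ValueError):
            artp_combine(M, {"g": []})


class TestBuildPermutationMatrix:
    def test_deterministic_given_seed(self, balanced_dataset):
        a = build_permutation_matrix(balanced_dataset, B=30, seed=5,
                                     adjusted_in_permutations=False)
        b = build_permutation_matrix(balanced_dataset, B=30, seed=5,
                                     adjusted_in_permutations=False)
        assert np.array_equal(a.values, b.values)
        assert a.observed is not None and a.values.shape == (31, 4)

    def test_row0_is_observed_labels(self, balanced_dataset):
        M = build_permutation_matrix(balanced_dataset, B=10, seed=1,
                                     adjusted_in_permutations=False)
        G = balanced_dataset.genotypes.values()
        P0 = trend_p_matrix(balanced_dataset.status[None, :].astype(float), G)
        assert np.allclose(M.values[0], np.clip(P0[0], 1 / 11, 1))

    def test_observed_rank_uniform_under_null(self, rng):
        # exchangeability: the observed row's rank among permutations is
        # uniform for null data; pool ranks over many SNPs
        n, k, B = 80, 30, 49
        G = rng.binomial(2, 0.4, size=(n, k)).astype(float)
        status = np.tile([0, 1], n // 2)
        ds = make_dataset(G, status, regions=["R"] * k)
        M = build_permutation_matrix(ds, B=B, seed=8, adjusted_in_permutations=False)
        ranks = (M.values[1:] < M.values[0]).sum(axis=0)
        # mean rank should be near B/2
        se = B / math.sqrt(12 * k)
        assert abs(ranks.mean() - B / 2) < 4 * se


class TestExhaustiveOracle:
    """On an n=8 fixture every case-label assignment can be enumerated, so
    the permutation two-step ARTP has an exact brute-force value."""

    def _fixture(self):
        G = np.array([
            [0, 0], [1, 0], [2, 1], [1, 2],
            [0, 1], [1, 1], [2, 0], [0, 2],
        ], dtype=float)
        y_obs = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        return G, y_obs

    def test_group_p_matches_brute_force(self):
        G, y_obs = self._fixture()
        assignments = [a for a in itertools.combinations(range(8), 4)]
        Y = np.zeros((len(assignments), 8))
        for i, a in enumerate(assignments):
            Y[i, list(a)] = 1.0
        # row 0 of the matrix must be the observed assignment
        obs_idx = assignments.index(tuple(np.flatnonzero(y_obs)))
        order = [obs_idx] + [i for i in range(len(assignments)) if i != obs_idx]
        P = trend_p_matrix(Y[order], G)
        B = len(assignments) - 1
        P = np.clip(P, 1 / (B + 1), 1)
        M = PermutationPValueMatrix(P, ("s1", "s2"), seed=None, B=B)
        res, _ = artp_combine(M, {"g": ["s1", "s2"]}, TruncationSet((1, 2)))
        want_p, _ = artp_oracle(P, [0, 1], [1, 2])
        assert res["g"].p == pytest.approx(want_p, abs=1e-12)


class TestPathwayAnalysis:
    def test_degenerate_hierarchy_same_p_at_all_levels(self, rng):
        n = 40
        g = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        status = np.tile([0, 1], n // 2)
        ds = make_dataset(g, status, regions=["R1"], pathway_map={"R1": {"P1"}})
        res = pathway_analysis(ds, B=200, seed=3, adjusted_in_permutations=False,
                               J_region=TruncationSet((1,)), J_pathway=TruncationSet((1,)))
        p_region = res.region_results["R1"].p
        p_pathway = res.pathway_results["P1"].p
        # single-member chains: identical within the rank-estimate convention
        assert abs(p_region - p_pathway) <= 2 / 201
        assert abs(res.overall.p - p_pathway) <= 2 / 201

    def test_overlap_removal_gene_counts(self, rng):
        n = 40
        g = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        status = np.tile([0, 1], n // 2)
        ds = make_dataset(g, status, regions=["R1", "R2"],
                          pathway_map={"R1": {"A", "B"}, "R2": {"A"}})
        res_with = pathway_analysis(ds, B=50, seed=1, adjusted_in_permutations=False)
        res_without = pathway_analysis(ds, B=50, seed=1, overlap="without",
                                       adjusted_in_permutations=False)
        assert res_with.n_genes_per_pathway == {"A": 2, "B": 1}
        assert res_without.n_genes_per_pathway == {"A": 1}
        assert res_without.not_estimable == ("B",)

    def test_signal_localises_to_causal_pathway(self):
        blocks = [
            BlockSpec("GENE_A", np.array([[1], [0]]), np.array([0.35, 0.65])),
            BlockSpec("GENE_B", np.array([[1], [0]]), np.array([0.35, 0.65])),
        ]
        from pathassoc.data_model import PathwayMap
        pmap = PathwayMap({"GENE_A": frozenset({"pwA"}), "GENE_B": frozenset({"pwB"})})
        cfg = CohortConfig(n_cases=150, n_controls=150, blocks=blocks,
                           effects=[EffectSpec("GENE_A_snp0", math.log(2.0))],
                           male_log_or=0.0, comorbidity_log_or=0.0,
                           baseline_log_odds=-0.6)
        wins = 0
        reps = 20
        for s in range(reps):
            ds = simulate_cohort(cfg, seed=300 + s, pathway_map=pmap)
            res = pathway_analysis(ds, B=400, seed=s, adjusted_in_permutations=False)
            if res.pathway_results["pwA"].p < res.pathway_results["pwB"].p:
                wins += 1
        assert wins >= int(0.9 * reps)

    def test_mc_standard_error_reported(self):
        r = ArtpResult("x", p=0.05, selected_truncation=1, B=100)
        assert r.mc_standard_error == pytest.approx(math.sqrt(0.05 * 0.95 / 100))
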