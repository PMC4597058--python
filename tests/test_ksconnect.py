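"""KS enrichment, connectivity scoring, permutation significance, star bins."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drugconnect.io import DiseaseSignature
from drugconnect.ksconnect import (
    ConnectivityResult,
    EnrichmentInput,
    NoOverlapError,
    PermutationConfig,
    connectivity_score,
    ks_enrichment,
    permutation_p,
    rank_candidates,
    star_rating,
)
from drugconnect.mapbuild import DrugProfile


def ranked_list(t):
    return [f"g{i:03d}" for i in range(1, t + 1)]


def es_at(positions, t):
    ranked = ranked_list(t)
    return ks_enrichment(EnrichmentInput(ranked, {ranked[p - 1] for p in positions}))


def brute_force_es(positions, n, t):
    """Explicit-loop evaluation of both max expressions."""
    v = sorted(positions)
    a = max(j / n - v[j - 1] / t for j in range(1, n + 1))
    b = max(v[j - 1] / t - (j - 1) / n for j in range(1, n + 1))
    return a if a > b else -b


class TestKsEnrichment:
    def test_single_gene_at_top(self):
        assert es_at([1], 100) == pytest.approx(0.99)

    def test_single_gene_at_bottom(self):
        assert es_at([100], 100) == pytest.approx(-1.0)

    @pytest.mark.parametrize("n", [1, 3, 10, 50])
    def test_full_list_tagged(self, n):
        assert es_at(range(1, n + 1), n) == pytest.approx(-1.0 / n)

    def test_no_overlap_raises(self):
        with pytest.raises(NoOverlapError):
            EnrichmentInput(ranked_list(5), {"absent"})

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(1000):
            t = int(rng.integers(2, 200))
            n = int(rng.integers(1, t + 1))
            positions = sorted(rng.choice(t, size=n, replace=False) + 1)
            fast = es_at(positions, t)
            slow = brute_force_es(positions, n, t)
            assert fast == pytest.approx(slow, abs=1e-12)

    def test_reversal_relation(self):
        rng = np.random.default_rng(29)
        # n = 1: exact discrete-grid relation es(rev) = -es - 1/t
        for _ in range(200):
            t = int(rng.integers(2, 150))
            v = int(rng.integers(1, t + 1))
            if t / 2 <= v <= t / 2 + 1:
                # center band: both orientations take the same max branch,
                # so the antisymmetry relation does not apply
                continue
            assert es_at([t + 1 - v], t) == pytest.approx(
                -es_at([v], t) - 1.0 / t, abs=1e-12)
        # n > 1: a one-sided (top-concentrated) tag set flips sign under
        # reversal; symmetric sets with genes at both extremes need not
        for _ in range(100):
            t = int(rng.integers(9, 150))
            n = int(rng.integers(2, max(t // 3, 2) + 1))
            pos = sorted(rng.choice(t // 3, size=min(n, t // 3),
                                    replace=False) + 1)
            es = es_at(pos, t)
            assert es > 0
            rev = [t + 1 - p for p in pos]
            assert es_at(rev, t) < 0


@given(st.data())
@settings(max_examples=300, deadline=None, derandomize=True)
def test_es_bounds_property(data):
    t = data.draw(st.integers(1, 60))
    n = data.draw(st.integers(1, t))
    positions = data.draw(
        st.lists(st.integers(1, t), min_size=n, max_size=n, unique=True))
    es = es_at(positions, t)
    assert -1.0 <= es <= 1.0


class TestConnectivityScore:
    @staticmethod
    def _profile(t):
        ranked = ranked_list(t)
        scores = {g: float(t - i) for i, g in enumerate(ranked)}
        return DrugProfile.from_scores("drug", scores)

    def test_same_sign_yields_zero(self):
        # up tag at position 1 and down tag at position 2 of 10: both es > 0
        prof = self._profile(10)
        es_up, es_down, score = connectivity_score(
            prof, DiseaseSignature("z", {"g001"}, {"g002"}))
        assert es_up > 0 and es_down > 0
        assert score == 0.0

    def test_treatment_pattern_minus_one(self):
        # es_up = -0.6 (single up gene at 12/20), es_down = +0.4
        # (down genes at 2 and 13/20) -> score = -1.0
        prof = self._profile(20)
        sig = DiseaseSignature("z", {"g012"}, {"g002", "g013"})
        es_up, es_down, score = connectivity_score(prof, sig)
        assert es_up == pytest.approx(-0.6)
        assert es_down == pytest.approx(0.4)
        assert score == pytest.approx(-1.0)

    def test_anti_treatment_pattern(self):
        # es_up = +0.7 (up gene at 6/20); es_down = -0.2 (down genes evenly
        # at 4, 8, 12, 16, 20) -> score = +0.9
        prof = self._profile(20)
        sig = DiseaseSignature(
            "z", {"g006"}, {"g004", "g008", "g012", "g016", "g020"})
        es_up, es_down, score = connectivity_score(prof, sig)
        assert es_up == pytest.approx(0.7)
        assert es_down == pytest.approx(-0.2)
        assert score == pytest.approx(0.9)

    def test_same_sign_rule_on_random_cases(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            t = int(rng.integers(6, 60))
            prof = self._profile(t)
            genes = ranked_list(t)
            picked = rng.choice(t, size=min(8, t), replace=False)
            up = {genes[i] for i in picked[:4]}
            down = {genes[i] for i in picked[4:]}
            if not up or not down:
                continue
            es_up, es_down, score = connectivity_score(
                prof, DiseaseSignature("z", up, down))
            if np.sign(es_up) == np.sign(es_down):
                assert score == 0.0
            else:
                assert score == pytest.approx(es_up - es_down)


class TestPermutationP:
    @staticmethod
    def _pool(n, t=10, genes_prefix="x"):
        # profiles over private genes: never overlap the signature
        return [
            DrugProfile.from_scores(
                f"pool{i}", {f"{genes_prefix}{i}_{j}": 1.0 for j in range(t)})
            for i in range(n)
        ]

    def test_add_one_floor(self):
        # all permuted scores are 0 (no signature overlap in the pool)
        sig = DiseaseSignature("z", {"g001"}, {"g002"})
        cfg = PermutationConfig(n_permutations=200, seed=1, pool=self._pool(20))
        p = permutation_p(-1.5, cfg, sig)
        assert p == pytest.approx(1 / 201)

    def test_observed_zero_with_null_zeros(self):
        sig = DiseaseSignature("z", {"g001"}, {"g002"})
        cfg = PermutationConfig(n_permutations=200, seed=1, pool=self._pool(20))
        assert permutation_p(0.0, cfg, sig) == pytest.approx(1.0)

    def test_small_pool_rejected(self):
        sig = DiseaseSignature("z", {"g001"}, {"g002"})
        cfg = PermutationConfig(n_permutations=10, seed=1, pool=self._pool(1))
        with pytest.raises(ValueError):
            permutation_p(-1.0, cfg, sig)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        pool = [
            DrugProfile.from_scores(
                f"d{i}", {f"g{rng.integers(30):03d}": float(rng.normal())
                          for _ in range(8)})
            for i in range(12)
        ]
        sig = DiseaseSignature("z", {"g001", "g005"}, {"g010", "g020"})
        cfg = PermutationConfig(n_permutations=100, seed=42, pool=pool)
        assert permutation_p(-0.5, cfg, sig) == permutation_p(-0.5, cfg, sig)


class TestStarRating:
    # Additional-File-2 legend bins, exhaustively
    GRID = [
        (-0.35, 0.01, 5), (-0.25, 0.01, 4), (-0.15, 0.01, 3),
        (-0.05, 0.01, 2), (0.0, 0.01, 1), (0.2, 0.01, 1),
        (-0.35, 0.2, 1), (-0.25, 0.2, 1), (-0.15, 0.2, 1),
        (-0.05, 0.2, 1), (0.0, 0.2, 1), (0.2, 0.2, 1),
    ]

    @pytest.mark.parametrize("score,p,stars", GRID)
    def test_legend_bins(self, score, p, stars):
        assert star_rating(score, p) == stars

    def test_boundary_values(self):
        assert star_rating(-0.3, 0.01) == 4    # -0.3 <= s < -0.2
        assert star_rating(-0.2, 0.01) == 3
        assert star_rating(-0.1, 0.01) == 2
        assert star_rating(-0.5, 0.05) == 1    # p >= 0.05 overrides


class TestRankCandidates:
    def test_identical_profiles_adjacent_id_order(self):
        ranked = ranked_list(10)
        scores = {g: float(10 - i) for i, g in enumerate(ranked)}
        profiles = [DrugProfile.from_scores(d, scores) for d in ("b", "a", "c")]
        sig = DiseaseSignature("z", {"g009"}, {"g001"})
        results = rank_candidates(
            profiles, sig, PermutationConfig(n_permutations=50, seed=0,
                                             pool=list(profiles)))
        assert [r.drug_id for r in results] == ["a", "b", "c"]
        assert len({r.score for r in results}) == 1

    def test_disjoint_signature_empty(self):
        profiles = [
            DrugProfile.from_scores("a", {"p1": 1.0, "p2": -1.0}),
            DrugProfile.from_scores("b", {"p3": 1.0, "p4": -1.0}),
        ]
        sig = DiseaseSignature("z", {"q1"}, {"q2"})
        assert rank_candidates(profiles, sig) == []

    def test_scores_sorted_ascending(self, synth_default):
        sig = synth_default["signatures"][0]
        results = rank_candidates(
            synth_default["profiles"], sig,
            PermutationConfig(n_permutations=50, seed=0,
                              pool=list(synth_default["profiles"])))
        scores = [r.score for r in results]
        assert scores == sorted(scores)

    def test_planted_treatment_drugs_rank_high(self, synth_default):
        truth = synth_default["truth"]
        profiles = synth_default["profiles"]
        for sig in synth_default["signatures"]:
            planted = {d for d, z in truth.true_indications
                       if z == sig.disease_id}
            results = rank_candidates(
                profiles, sig,
                PermutationConfig(n_permutations=50, seed=0,
                                  pool=list(profiles)))
            order = [r.drug_id for r in results]
            cutoff = max(1, round(0.1 * len(profiles)))
            top = set(order[:cutoff])
            # every planted treatment drug lands in the top decile
            assert planted <= top
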