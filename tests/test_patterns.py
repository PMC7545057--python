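"""Model-profile enumeration, selection, assignment, significance."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from lactoseq.expression import compute_rpkm, stage_mean_rpkm
from lactoseq.patterns import (
    ModelProfile,
    _profile_distance,
    assign_genes,
    cluster_significant_profiles,
    enumerate_candidate_profiles,
    profile_significance,
    select_model_profiles,
    summarize_pattern_direction,
)
from lactoseq.simulate import SimulationConfig, simulate_counts


class TestEnumeration:
    @pytest.mark.parametrize("t", [2, 3, 4, 5])
    @pytest.mark.parametrize("c", [1, 2, 3])
    def test_candidate_count_formula(self, t, c):
        assert len(enumerate_candidate_profiles(t, c)) == (2 * c + 1) ** (t - 1)

    def test_two_point_listing(self):
        profiles = enumerate_candidate_profiles(2, 2)
        assert [p.levels for p in profiles] == [(0, -2), (0, -1), (0, 0), (0, 1), (0, 2)]

    def test_profiles_start_at_zero_with_bounded_steps(self):
        for p in enumerate_candidate_profiles(4, 2):
            assert p.levels[0] == 0
            assert all(abs(b - a) <= 2 for a, b in zip(p.levels, p.levels[1:]))

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidate_profiles(1, 2)


class TestSelection:
    def test_no_selection_needed_when_m_covers_all(self):
        cands = enumerate_candidate_profiles(3, 2)
        assert select_model_profiles(cands, 25) == sorted(cands, key=lambda p: p.id)

    def test_exactly_twenty_representatives(self):
        # the pipeline default: 20 model profiles from the 25 candidates
        assert len(select_model_profiles(enumerate_candidate_profiles(3, 2), 20)) == 20

    def test_greedy_matches_exhaustive_max_min(self):
        cands = enumerate_candidate_profiles(3, 1)
        greedy = select_model_profiles(cands, 3)
        flat = next(p for p in cands if p.is_flat)
        best = None
        for combo in combinations(cands, 3):
            if flat not in combo:
                continue
            dmin = min(_profile_distance(a.levels, b.levels) for a, b in combinations(combo, 2))
            ids = tuple(sorted(p.id for p in combo))
            if best is None or dmin > best[0] + 1e-12 or (abs(dmin - best[0]) <= 1e-12 and ids < best[1]):
                best = (dmin, ids)
        assert tuple(p.id for p in greedy) == best[1]

    def test_selection_is_deterministic(self):
        cands = enumerate_candidate_profiles(3, 2)
        assert select_model_profiles(cands, 12) == select_model_profiles(cands, 12)


class TestAssignment:
    def test_exact_template_gets_correlation_one(self):
        profiles = enumerate_candidate_profiles(3, 2)
        means = pd.DataFrame({"L": [1.0], "D": [4.0], "NP": [16.0]}, index=["g"])
        out = assign_genes(means, profiles, pseudocount=0.0)
        chosen = next(p for p in profiles if p.id == out["profile_id"].iloc[0])
        assert out["correlation"].iloc[0] == pytest.approx(1.0)
        # trajectory (0, 2, 4) is proportional to (0, 1, 2): lowest-id class member wins
        assert chosen.levels in ((0, 1, 2), (0, 2, 4))
        assert chosen.id == min(p.id for p in profiles if p.levels in ((0, 1, 2), (0, 2, 4)))

    def test_constant_gene_goes_to_flat_profile(self):
        profiles = enumerate_candidate_profiles(3, 2)
        flat_id = next(p.id for p in profiles if p.is_flat)
        means = pd.DataFrame({"L": [3.0], "D": [3.0], "NP": [3.0]}, index=["g"])
        out = assign_genes(means, profiles, pseudocount=0.0)
        assert out["profile_id"].iloc[0] == flat_id

    def test_gene_order_invariance(self, rng):
        profiles = select_model_profiles(enumerate_candidate_profiles(3, 2), 20)
        means = pd.DataFrame(rng.lognormal(2, 1, size=(40, 3)), columns=["L", "D", "NP"],
                             index=[f"g{i}" for i in range(40)])
        a = assign_genes(means, profiles)
        b = assign_genes(means.sample(frac=1, random_state=0), profiles).loc[a.index]
        pd.testing.assert_frame_equal(a, b)

    def test_planted_templates_recovered(self):
        profiles = select_model_profiles(enumerate_candidate_profiles(3, 2), 20)
        cfg = SimulationConfig(n_genes=200, frac_de=1.0, nb_dispersion=0.005,
                               baseline_log_mean=6.0, baseline_log_sd=0.5, seed=3)
        ds = simulate_counts(cfg)
        means = stage_mean_rpkm(compute_rpkm(ds.counts, ds.lengths))
        out = assign_genes(means, profiles)
        by_levels = {p.levels: p.id for p in profiles}
        truth_ids = ds.truth.genes["profile_template"].map(
            lambda s: by_levels[tuple(int(v) for v in s.split(","))]
        )
        assert (out["profile_id"].to_numpy() == truth_ids.to_numpy()).mean() >= 0.9


class TestSignificance:
    def test_counts_are_conserved(self, rng):
        profiles = select_model_profiles(enumerate_candidate_profiles(3, 2), 20)
        means = pd.DataFrame(rng.lognormal(2, 1, size=(60, 3)), columns=["L", "D", "NP"])
        sig = profile_significance(means, profiles)
        assert sig["observed"].sum() == 60
        assert sig["expected"].sum() == pytest.approx(60)

    def test_single_template_extremely_significant(self, rng):
        # stage means built directly on one template: a whole-transcriptome
        # shift would cancel under relative normalization, so this probes
        # the significance machinery itself
        profiles = select_model_profiles(enumerate_candidate_profiles(3, 2), 20)
        baseline = rng.lognormal(4, 0.5, size=150)
        noise = rng.lognormal(0, 0.05, size=(150, 3))
        means = pd.DataFrame(
            baseline[:, None] * np.power(2.0, 2.0 * np.array([0, 1, 0])) * noise,
            columns=["L", "D", "NP"],
        )
        sig = profile_significance(means, profiles).set_index("levels")
        assert sig.loc["0,1,0", "significant"]
        assert sig.loc["0,1,0", "p"] < 1e-6

    def test_too_many_stages_rejected(self, rng):
        profiles = enumerate_candidate_profiles(7, 1)
        means = pd.DataFrame(rng.lognormal(2, 1, size=(10, 7)))
        with pytest.raises(ValueError, match="at most"):
            profile_significance(means, profiles)

    def test_clustering_groups_correlated_significant_profiles(self):
        profiles = enumerate_candidate_profiles(3, 2)
        sig = pd.DataFrame({
            "profile_id": [p.id for p in profiles],
            "significant": [p.levels in ((0, 1, 2), (0, 2, 4), (0, -1, -2)) for p in profiles],
        })
        clusters = cluster_significant_profiles(sig, profiles, corr_threshold=0.7)
        id_of = {p.levels: p.id for p in profiles}
        assert clusters[id_of[(0, 1, 2)]] == clusters[id_of[(0, 2, 4)]]  # r = 1
        assert clusters[id_of[(0, 1, 2)]] != clusters[id_of[(0, -1, -2)]]  # r = -1
        assert clusters[id_of[(0, 0, 0)]] == -1  # not significant


class TestDirection:
    @pytest.mark.parametrize(
        "levels,pair,expected",
        [((0, 2, 1), (0, 1), "up"), ((0, 0, -1), (0, 1), "flat"), ((0, 2, 1), (1, 2), "down")],
    )
    def test_examples(self, levels, pair, expected):
        profile = ModelProfile(id=0, levels=levels)
        assert summarize_pattern_direction(profile, *pair) == expected

    def test_partition_over_profile_set(self):
        profiles = enumerate_candidate_profiles(3, 2)
        tally = {"up": 0, "down": 0, "flat": 0}
        for p in profiles:
            tally[summarize_pattern_direction(p, 0, 1)] += 1
        assert sum(tally.values()) == len(profiles)
        assert tally["up"] == tally["down"] == 10  # symmetry of the step grid
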