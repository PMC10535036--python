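import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabolodiv.annotation_enrichment import (
    DEFAULT_ADDUCTS,
    AdductRule,
    CompoundDatabase,
    PathwayDatabase,
    annotate_features,
    candidate_neutral_masses,
    pathway_activity_counts,
    pathway_overrepresentation,
    pathway_prevalence,
    permutation_pathway_null,
    EnrichmentRow,
)
from metabolodiv.feature_io import FeatureKey
from metabolodiv.synthetic_data import (
    CommunityParams,
    full_design,
    generate_compound_db,
    simulate_feature_table,
)

PROTON = 1.007276466
M_PLUS_H = next(r for r in DEFAULT_ADDUCTS if r.name == "[M+H]+")
M_MINUS_H = next(r for r in DEFAULT_ADDUCTS if r.name == "[M-H]-")


def small_db(masses):
    return CompoundDatabase(
        pd.DataFrame(
            {
                "compound_id": [f"C{i:03d}" for i in range(len(masses))],
                "name": [f"c{i}" for i in range(len(masses))],
                "monoisotopic_mass": masses,
            }
        )
    )


class TestAdductArithmetic:
    def test_protonation_recovers_neutral_mass(self):
        # glucose-like mass: [M+H]+ observed at M + proton
        cands = candidate_neutral_masses(181.070664, "positive", [M_PLUS_H])
        (rule, m), = cands
        assert m == pytest.approx(181.070664 - PROTON, abs=1e-9)

    def test_both_polarities_agree_on_neutral_mass(self):
        m = 180.063388
        pos = candidate_neutral_masses(M_PLUS_H.observed_mz(m), "positive", [M_PLUS_H])
        neg = candidate_neutral_masses(M_MINUS_H.observed_mz(m), "negative", [M_MINUS_H])
        assert pos[0][1] == pytest.approx(neg[0][1], abs=1e-9)

    def test_negative_candidates_dropped(self):
        sodium = next(r for r in DEFAULT_ADDUCTS if r.name == "[M+Na]+")
        assert candidate_neutral_masses(10.0, "positive", [sodium]) == []

    def test_no_rule_for_mode_rejected(self):
        with pytest.raises(ValueError):
            candidate_neutral_masses(100.0, "negative", [M_PLUS_H])

    def test_forward_inverse_round_trip(self):
        """Applying a rule's forward transform to the recovered neutral mass
        reproduces the observed m/z to machine precision."""
        for rule in DEFAULT_ADDUCTS:
            mz = 423.187
            assert rule.observed_mz(rule.neutral_mass(mz)) == pytest.approx(mz, abs=1e-12)


class TestAnnotateFeatures:
    def test_outside_tolerance_unannotated(self):
        db = small_db([300.0])
        feat = FeatureKey.make(M_PLUS_H.observed_mz(300.0 * (1 + 25e-6)), 1.0, "positive")
        res = annotate_features([feat], db, [M_PLUS_H], ppm_tolerance=10)
        assert res.hits == [] and res.unannotated == [feat]

    def test_multiplicity_ordered_by_ppm_error(self):
        m = 400.0
        db = small_db([m * (1 - 2.5e-6), m * (1 + 2.5e-6)])
        feat = FeatureKey.make(M_PLUS_H.observed_mz(m * (1 + 1e-6)), 1.0, "positive")
        res = annotate_features([feat], db, [M_PLUS_H], ppm_tolerance=10)
        assert len(res.hits) == 2
        assert abs(res.hits[0].ppm_error) <= abs(res.hits[1].ppm_error)
        assert res.hits[0].compound_id == "C001"  # the closer (heavier) compound

    def test_empty_database_rejected(self):
        empty = CompoundDatabase(
            pd.DataFrame(columns=["compound_id", "name", "monoisotopic_mass"])
        )
        with pytest.raises(ValueError, match="empty"):
            annotate_features([], empty, [M_PLUS_H])

    def test_planted_features_recovered_and_decoys_silent(self):
        """All simulator-planted compound features annotate at 10 ppm against
        the generating database; no decoy feature annotates."""
        compounds, _ = generate_compound_db(n_compounds=40, n_pathways=3, seed=3)
        tables, truth = simulate_feature_table(
            full_design(2),
            CommunityParams(n_features_per_mode=120),
            compound_db=compounds,
            annotatable_fraction=0.5,
            ppm_noise_sd=2.0,
            seed=9,
        )
        for mode, table in tables.items():
            res = annotate_features(table.features, compounds, ppm_tolerance=10)
            annotatable = {k for k in truth.feature_to_compound if k.esi_mode == mode}
            hit_feats = {h.feature for h in res.hits}
            assert annotatable <= hit_feats
            assert not (hit_feats - annotatable)
            for k in annotatable:
                cids = {h.compound_id for h in res.hits if h.feature == k}
                assert truth.feature_to_compound[k][0] in cids


def brute_force_upper_tail(universe_size, pathway_size, n_hits, k_obs):
    """Exhaustive P(overlap >= k) over all n_hits-subsets of the universe."""
    total = 0
    good = 0
    universe = range(universe_size)
    pathway = set(range(pathway_size))
    for draw in itertools.combinations(universe, n_hits):
        total += 1
        if len(pathway & set(draw)) >= k_obs:
            good += 1
    return good / total


class TestOverrepresentation:
    def pw(self, members):
        return PathwayDatabase({"map1": ("p1", frozenset(members))})

    def test_matches_exhaustive_enumeration(self):
        universe = {f"C{i}" for i in range(20)}
        pathway = {f"C{i}" for i in range(5)}
        hits = {"C0", "C1", "C2", "C10", "C11"}  # overlap 3
        row, = pathway_overrepresentation(hits, self.pw(pathway), universe)
        assert row.k == 3 and row.K == 5
        assert row.p_fisher == pytest.approx(brute_force_upper_tail(20, 5, 5, 3))

    @pytest.mark.parametrize("universe_size,pathway_size,n_hits", [(10, 4, 3), (12, 6, 5), (8, 8, 2)])
    def test_hypergeometric_equals_brute_force_everywhere(self, universe_size, pathway_size, n_hits):
        universe = {f"C{i}" for i in range(universe_size)}
        pathway = {f"C{i}" for i in range(pathway_size)}
        hits = {f"C{i}" for i in range(n_hits)}
        row, = pathway_overrepresentation(hits, self.pw(pathway), universe)
        k = len(hits & pathway)
        assert row.p_fisher == pytest.approx(
            brute_force_upper_tail(universe_size, pathway_size, n_hits, k)
        )

    def test_zero_overlap_p_one(self):
        universe = {f"C{i}" for i in range(20)}
        row, = pathway_overrepresentation(
            {"C10", "C11"}, self.pw({"C0", "C1"}), universe
        )
        assert row.k == 0 and row.p_fisher == pytest.approx(1.0)

    def test_pathway_equals_universe_certain(self):
        universe = {f"C{i}" for i in range(6)}
        row, = pathway_overrepresentation({"C0", "C1"}, self.pw(universe), universe)
        assert row.k == 2 and row.p_fisher == pytest.approx(1.0)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            pathway_overrepresentation({"X"}, self.pw({"C0"}), {"C0"})


class TestPermutationNull:
    def test_fully_planted_pathway_minimal_p(self):
        universe = {f"C{i}" for i in range(30)}
        pathway = {f"C{i}" for i in range(6)}
        pw = PathwayDatabase({"map1": ("p1", frozenset(pathway))})
        p = permutation_pathway_null(universe, pathway, pw, n_permutations=500, seed=1)
        assert p["map1"] == pytest.approx(1 / 501)

    def test_deterministic_under_seed(self):
        universe = {f"C{i}" for i in range(25)}
        pw = PathwayDatabase({"map1": ("p1", frozenset({f"C{i}" for i in range(8)}))})
        hits = {f"C{i}" for i in range(3, 9)}
        a = permutation_pathway_null(universe, hits, pw, 200, seed=7)
        b = permutation_pathway_null(universe, hits, pw, 200, seed=7)
        assert a == b

    def test_converges_to_fisher_for_random_hits(self):
        universe = {f"C{i}" for i in range(40)}
        pathway = {f"C{i}" for i in range(10)}
        pw = PathwayDatabase({"map1": ("p1", frozenset(pathway))})
        rng = np.random.default_rng(0)
        hits = set(rng.choice(sorted(universe), size=12, replace=False).tolist())
        row, = pathway_overrepresentation(hits, pw, universe)
        p_perm = permutation_pathway_null(universe, hits, pw, 4000, seed=2)["map1"]
        assert p_perm == pytest.approx(row.p_fisher, abs=0.03)

    def test_null_p_values_valid_and_calibrated(self):
        """Hits drawn from the null give valid p-values: the overlap statistic
        is discrete, so p_perm is sub-uniform — the empirical CDF must not
        rise above the uniform CDF (one-sided KS), and the mean p must not
        fall below the uniform mean."""
        universe = sorted(f"C{i}" for i in range(30))
        pw = PathwayDatabase({"map1": ("p1", frozenset(universe[:10]))})
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(60):
            hits = set(rng.choice(universe, size=8, replace=False).tolist())
            ps.append(permutation_pathway_null(set(universe), hits, pw, 199, seed=11)["map1"])
        stat, p = stats.kstest(ps, "uniform", alternative="greater")
        assert p > 0.01  # no evidence of anti-conservative p-values
        assert np.mean(ps) >= 0.45

    def test_too_many_hits_rejected(self):
        pw = PathwayDatabase({"map1": ("p1", frozenset({"C0"}))})
        with pytest.raises(ValueError):
            permutation_pathway_null({"C0"}, {"C0", "C1"}, pw, 100, 0)


class TestPrevalenceAndActivity:
    def row(self, pid, k, K, p):
        return EnrichmentRow(pid, k, K, 20, 5, p)

    def test_strictly_more_than_half(self):
        enr = {f"c{i}": [self.row("map1", 2, 5, 0.01)] for i in range(5)}
        enr.update({f"d{i}": [self.row("map1", 0, 5, 1.0)] for i in range(3)})
        assert pathway_prevalence(enr, 0.5) == ["map1"]  # 5 of 8 -> 0.625

    def test_exactly_half_excluded(self):
        enr = {f"c{i}": [self.row("map1", 1, 5, 0.01)] for i in range(4)}
        enr.update({f"d{i}": [self.row("map1", 0, 5, 1.0)] for i in range(4)})
        assert pathway_prevalence(enr, 0.5) == []

    def test_nothing_enriched_empty(self):
        enr = {"c1": [self.row("map1", 1, 5, 0.9)]}
        assert pathway_prevalence(enr) == []

    def test_activity_counts_k_of_K(self):
        pw = PathwayDatabase(
            {
                "map1": ("p1", frozenset({"c1", "c2", "c3", "c4", "c5"})),
                "map2": ("p2", frozenset({"x1", "x2"})),
            }
        )
        df = pathway_activity_counts({"contrast1": {"c1", "c2"}}, pw)
        assert df.loc[df["pathway_id"] == "map1", "activity"].iloc[0] == "2 of 5"
        # map2 has no hit in any contrast -> dropped
        assert "map2" not in set(df["pathway_id"])

    def test_fully_hit_planted_pathway(self):
        members = {f"c{i}" for i in range(6)}
        pw = PathwayDatabase({"map1": ("p1", frozenset(members))})
        df = pathway_activity_counts({"c": members}, pw)
        assert df["activity"].iloc[0] == "6 of 6"
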